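"""Linear measurements, generalized Procrustes analysis and shape PCA.

The six head landmarks (upper-jaw apex, dorsal/ventral/posterior gill-plate,
maxillary bone, eye) are superimposed by iterative GPA — translation removed
by centering, size by scaling to unit centroid size, orientation by
rotation-only (no reflection) Procrustes fits against an iteratively
re-estimated mean shape.  Shape variation is then summarised by a PCA of the
aligned coordinates, with per-group 95% confidence ellipses under a
multivariate t assumption.

Kype length and height are plain Euclidean distances between dedicated
measurement points that are deliberately excluded from the superimposition
(mouth opening moves them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import LandmarkConfiguration, N_GPA_LANDMARKS


class DegenerateShapeError(ValueError):
    """All landmarks of a configuration coincide; names the specimen."""


# ---------------------------------------------------------------------------
# linear measurements
# ---------------------------------------------------------------------------

def point_distance(p: np.ndarray, q: np.ndarray, scale: float = 1.0) -> float:
    """Euclidean distance between two planar points, scale-corrected to cm."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.hypot(*(p - q)) * scale)


def vertical_projection(peak: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """The point directly beneath ``peak`` on the segment a-b.

    Used as the fallback lower endpoint of the kype-height measure when no
    curvature onset is discernible on the lower jaw.
    """
    peak, a, b = (np.asarray(v, dtype=float) for v in (peak, seg_a, seg_b))
    if np.isclose(a[0], b[0]):
        return np.array([a[0], min(a[1], b[1])])
    t = (peak[0] - a[0]) / (b[0] - a[0])
    t = float(np.clip(t, 0.0, 1.0))
    return a + t * (b - a)


def measure_kype(config: LandmarkConfiguration) -> tuple[float | None, float | None]:
    """Kype length and height (cm) from a configuration's measurement points.

    Kype length runs from the anterior lower-jaw point to the bottom of the
    gill plate (points 7-8); kype height from the dorsal hook peak to the
    curvature-onset point (points 9-10).  When the hook pair is absent (mouth
    obscured on the photograph) kype height is ``None``; when only the peak
    is usable the fallback is the vertical projection onto the lower-jaw
    segment.
    """
    jaw = config.jaw_points
    hook = config.hook_points
    kl = point_distance(jaw[0], jaw[1]) if jaw is not None else None
    if hook is None:
        return kl, None
    if len(hook) == 2:
        peak, curv = hook
    else:
        peak = hook[0]
        if jaw is None:
            return kl, None
        curv = vertical_projection(peak, jaw[0], jaw[1])
    kh = point_distance(peak, curv)
    return kl, kh


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

@dataclass
class AlignedShape:
    """One specimen after superimposition: dimensionless coordinates with
    centroid at the origin and unit centroid size, plus the original size."""

    specimen_id: str
    coords: np.ndarray       # (6, 2), Procrustes units
    centroid_size: float     # cm


@dataclass
class GpaResult:
    shapes: list[AlignedShape]
    mean_shape: np.ndarray
    iterations: int
    objective_trace: np.ndarray  # summed squared distance to the mean, per iteration

    @property
    def coordinates(self) -> np.ndarray:
        return np.stack([s.coords for s in self.shapes])


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances from the landmark centroid."""
    c = points - points.mean(axis=0)
    return float(np.sqrt(np.sum(c ** 2)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (determinant +1, reflections excluded) minimising
    ||source R - target||."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


def gpa(configs: list[LandmarkConfiguration], tol: float = 1e-8,
        max_iter: int = 100) -> GpaResult:
    """Generalized Procrustes superimposition of the six head landmarks.

    Each configuration is centered, scaled to unit centroid size and rotated
    to the running mean shape; the mean is re-estimated and re-normalised
    until it moves by less than ``tol``.  The summed squared distance to the
    mean is non-increasing across iterations.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    pre = []
    for cfg in configs:
        pts = np.asarray(cfg.gpa_landmarks, dtype=float)
        if pts.shape[0] != N_GPA_LANDMARKS:
            raise ValueError(f"{cfg.specimen_id}: expected {N_GPA_LANDMARKS} landmarks")
        cs = centroid_size(pts)
        if cs < 1e-12:
            raise DegenerateShapeError(f"{cfg.specimen_id}: all landmarks coincide")
        pre.append(((pts - pts.mean(axis=0)) / cs, cs))
    X = np.stack([p for p, _ in pre])
    mean = X[0].copy()
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        cs = centroid_size(new_mean)
        if cs < 1e-12:
            raise DegenerateShapeError("mean shape degenerated")
        new_mean /= cs
        trace.append(float(np.sum((X - new_mean[None]) ** 2)))
        if np.sqrt(np.sum((new_mean - mean) ** 2)) < tol:
            mean = new_mean
            break
        mean = new_mean
    shapes = [AlignedShape(cfg.specimen_id, X[i], pre[i][1])
              for i, cfg in enumerate(configs)]
    return GpaResult(shapes=shapes, mean_shape=mean, iterations=it,
                     objective_trace=np.asarray(trace))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared distance between two aligned shapes."""
    return float(np.sqrt(np.sum((np.asarray(a) - np.asarray(b)) ** 2)))


# ---------------------------------------------------------------------------
# shape PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapePca:
    mean: np.ndarray              # (12,) flattened mean of aligned coordinates
    components: np.ndarray        # (k, 12) orthonormal loadings, rows
    scores: np.ndarray            # (n, k)
    variance_proportions: np.ndarray

    def reconstruct(self, i: int) -> np.ndarray:
        """Inverse transform of specimen i from all retained components."""
        return (self.mean + self.scores[i] @ self.components).reshape(-1, 2)


def shape_pca(aligned: GpaResult | list[AlignedShape]) -> ShapePca:
    """PCA of the covariance of the flattened aligned coordinates."""
    shapes = aligned.shapes if isinstance(aligned, GpaResult) else aligned
    if len(shapes) < 3:
        raise ValueError("shape PCA needs at least 3 aligned shapes")
    flat = np.stack([s.coords.ravel() for s in shapes])
    mean = flat.mean(axis=0)
    centered = flat - mean
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = svals ** 2 / (len(shapes) - 1)
    total = float(eigvals.sum())
    props = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = centered @ Vt.T
    return ShapePca(mean=mean, components=Vt, scores=scores,
                    variance_proportions=props)


# ---------------------------------------------------------------------------
# confidence ellipses
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceEllipse:
    center: np.ndarray
    axes: np.ndarray       # half-axis lengths, descending
    angle: float           # radians, orientation of the major axis
    level: float
    df: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        return np.sum((local / self.axes) ** 2, axis=1) <= 1.0

    def polygon(self, n: int = 200) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n)
        unit = np.stack([self.axes[0] * np.cos(t), self.axes[1] * np.sin(t)], axis=1)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return unit @ rot.T + self.center


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95,
                       df: float | None = None) -> ConfidenceEllipse:
    """Confidence ellipse for a group's 2-D scores under a multivariate t.

    The sample mean and covariance are scaled by the multivariate-t quantile
    sqrt(2 F^{-1}(level; 2, df)) with df = n - 1 by default.
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    n = pts.shape[0]
    df = float(n - 1) if df is None else float(df)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.cond(cov) > 1e12 or np.linalg.det(cov) <= 0:
        raise ValueError("singular 2x2 covariance")
    radius = np.sqrt(2.0 * stats.f.ppf(level, 2, df))
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    angle = float(np.arctan2(V[1, 0], V[0, 0]))
    return ConfidenceEllipse(center=pts.mean(axis=0), axes=radius * np.sqrt(w),
                             angle=angle, level=level, df=df)


def plot_pca(pca: ShapePca, groups, ax=None, level: float = 0.95):
    """Score scatter on PC1/PC2 with per-group confidence ellipses."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        sc = pca.scores[sel, :2]
        ax.scatter(sc[:, 0], sc[:, 1], s=12, label=str(g), alpha=0.7)
        if sel.sum() >= 3:
            try:
                poly = confidence_ellipse(sc, level=level).polygon()
                ax.plot(poly[:, 0], poly[:, 1], lw=1)
            except ValueError:
                pass
    p1, p2 = pca.variance_proportions[:2] * 100
    ax.set_xlabel(f"PC1 ({p1:.1f}%)")
    ax.set_ylabel(f"PC2 ({p2:.1f}%)")
    ax.legend(fontsize=8)
    return ax
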