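"""Variance-component QTL linkage scan over the SNP panel.

At each panel marker the phenotype is modelled twice:

    model 0:  y = X B + a + e            a ~ N(0, sigma2_a G)
    model 1:  y = X B + a + q + e        q ~ N(0, sigma2_q Z_m)

where ``X`` carries the fixed effects (tank, strain, sea-winter age), ``G``
is the pedigree additive-relationship (kinship) matrix and ``Z_m`` the
locus-specific expected-IBD matrix at marker m, estimated from the panel
genotypes and the pedigree.  Both models are fitted by the same restricted-
likelihood machinery as the strain/age mixed models; the locus test is the
likelihood-ratio statistic LRT = 2(logL1 - logL0), clipped at zero, with
p-values from the 50:50 chi-square boundary mixture.  The share of
phenotypic variance attributed to a locus is sigma2_q / (sigma2_q +
sigma2_a + sigma2_e).

IBD at a marker is the single-marker conditional expectation: for each
offspring and parent the transmitted parental chromosome is inferred where
the parental genotype is informative (heterozygous with distinguishable
transmission), and each uninformative meiosis contributes the full-sib prior
1/2.  No multipoint smoothing over flanking markers is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design
from .io import GenotypeMatrix, Pedigree
from .reml import RemlFit, RemlProblem, boundary_lrt_pvalue, _partition_blocks


class MendelianError(ValueError):
    """Offspring allele impossible given its parents; names trio and marker."""


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def pedigree_kinship(pedigree: Pedigree, ids: list[str]) -> pd.DataFrame:
    """Additive relationship matrix by the recursive tabular method.

    Founders are assumed unrelated and non-inbred; each individual's
    relationship row is the parental average, and the diagonal is
    1 + half the parents' relationship.  The result is restricted to ``ids``.
    """
    order = pedigree.topological_order
    missing = set(ids) - set(order)
    if missing:
        raise ValueError(f"ids not in pedigree: {sorted(missing)[:5]}")
    idx = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    t = pedigree.table.set_index("individual_id")
    for ind in order:
        i = idx[ind]
        sire, dam = t.loc[ind, "sire_id"], t.loc[ind, "dam_id"]
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        if si is None and di is None:
            A[i, i] = 1.0
        else:
            row = np.zeros(n)
            if si is not None:
                row += 0.5 * A[si]
            if di is not None:
                row += 0.5 * A[di]
            A[i, :i] = row[:i]
            A[:i, i] = row[:i]
            A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    sel = [idx[i] for i in ids]
    return pd.DataFrame(A[np.ix_(sel, sel)], index=ids, columns=ids)


# ---------------------------------------------------------------------------
# transmission inference / IBD
# ---------------------------------------------------------------------------

def _transmission_states(geno: GenotypeMatrix, pedigree: Pedigree,
                         ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Infer, per offspring and marker, which parental chromosome (0/1) was
    transmitted by each parent; NaN where the meiosis is uninformative.

    Returns (sire_states, dam_states), each (n_ids, n_markers) float arrays.
    Raises :class:`MendelianError` when an offspring is incompatible with its
    parents at a marker.
    """
    t = pedigree.table.set_index("individual_id")
    m = geno.n_markers
    marker_ids = geno.marker_map.marker_ids
    parents = t.loc[ids, ["sire_id", "dam_id"]].to_numpy(dtype=object)
    own = np.array([geno._index[i] for i in ids])
    O = geno.calls[own].astype(np.int16)                       # (n, m, 2)

    def parent_calls(col):
        out = np.full((len(ids), m, 2), -1, dtype=np.int16)
        for i, pid in enumerate(parents[:, col]):
            if pid is not None:
                out[i] = geno.calls[geno._index[pid]]
        return out

    SG, DG = parent_calls(0), parent_calls(1)
    o1, o2 = O[:, :, 0], O[:, :, 1]
    omiss = (o1 < 0) | (o2 < 0)

    def carries(pg, allele):
        return ((pg[:, :, 0] < 0) | (pg[:, :, 1] < 0)
                | (pg[:, :, 0] == allele) | (pg[:, :, 1] == allele))

    ok1 = carries(SG, o1) & carries(DG, o2)                    # o1 paternal
    ok2 = carries(SG, o2) & carries(DG, o1)                    # o2 paternal
    bad = ~omiss & ~ok1 & ~ok2
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise MendelianError(
            f"offspring {ids[i]!r} (sire {parents[i, 0]!r}, dam {parents[i, 1]!r}) "
            f"incompatible at marker {marker_ids[j]!r}")
    out_states = []
    for pg, allele_ok1, allele_ok2 in ((SG, o1, o2), (DG, o2, o1)):
        het = (pg[:, :, 0] >= 0) & (pg[:, :, 1] >= 0) & (pg[:, :, 0] != pg[:, :, 1])
        # transmitted allele is determined when only one assignment is
        # compatible, or both assignments transmit the same allele state
        allele = np.where(ok1, allele_ok1, allele_ok2)
        ambiguous = ok1 & ok2 & (allele_ok1 != allele_ok2)
        informative = het & ~omiss & ~ambiguous & (ok1 | ok2) & (allele >= 0)
        states = np.where(allele == pg[:, :, 1], 1.0, 0.0)
        out_states.append(np.where(informative, states, np.nan))
    return out_states[0], out_states[1]


def _phase_states(states: np.ndarray, parent_groups: np.ndarray,
                  map_table: pd.DataFrame) -> np.ndarray:
    """Align transmission-state labels to a consistent parental phase.

    State indices refer to the parent's unordered genotype slots, which are
    not phased across markers; within each linkage group adjacent markers are
    re-labelled (flipped) whenever more than half of the meioses informative
    at both markers appear recombinant, a min-recombinant phasing that is
    essentially exact with a handful of informative offspring.
    """
    out = states.copy()
    for parent in pd.unique(parent_groups):
        if parent == "":
            continue
        rows = np.where(parent_groups == parent)[0]
        T = out[rows]
        for _, grp in map_table.groupby("linkage_group"):
            idx = grp.index.to_numpy()
            orient = np.zeros(len(idx), dtype=bool)
            for jj, (a, b) in enumerate(zip(idx[:-1], idx[1:])):
                both = ~np.isnan(T[:, a]) & ~np.isnan(T[:, b])
                recomb = (float(np.mean(T[both, a] != T[both, b])) > 0.5
                          if both.sum() >= 2 else False)
                orient[jj + 1] = orient[jj] ^ recomb
            for jj in np.where(orient)[0]:
                T[:, idx[jj]] = 1.0 - T[:, idx[jj]]
        out[rows] = T
    return out


def _transmission_posteriors(states: np.ndarray, map_table: pd.DataFrame) -> np.ndarray:
    """P(chromosome-1 transmitted) at every marker for each (phased) meiosis.

    Conditional on the nearest informative flanking markers the underlying
    transmission process is Markov, so the posterior uses the Haldane
    transition probabilities to the left and right observations; a meiosis
    with no informative marker on the group stays at the prior 1/2.
    """
    from .simulate import haldane_fraction

    P = np.full(states.shape, 0.5)
    for _, grp in map_table.groupby("linkage_group"):
        idx = grp.index.to_numpy()
        pos = grp["position_cm"].to_numpy()
        sub = states[:, idx]
        for i in range(sub.shape[0]):
            informative = ~np.isnan(sub[i])
            if not informative.any():
                continue
            src = np.where(informative)[0]
            s_obs = sub[i, src]
            for jj in range(len(idx)):
                if informative[jj]:
                    P[i, idx[jj]] = sub[i, jj]
                    continue
                left = src[src < jj]
                right = src[src > jj]
                like1 = like0 = 1.0
                if len(left):
                    l = left[-1]
                    r = haldane_fraction(pos[jj] - pos[l])
                    like1 *= r if s_obs[src == l][0] == 0.0 else 1.0 - r
                    like0 *= r if s_obs[src == l][0] == 1.0 else 1.0 - r
                if len(right):
                    rr = right[0]
                    r = haldane_fraction(pos[rr] - pos[jj])
                    like1 *= r if s_obs[src == rr][0] == 0.0 else 1.0 - r
                    like0 *= r if s_obs[src == rr][0] == 1.0 else 1.0 - r
                P[i, idx[jj]] = like1 / (like1 + like0)
    return P


@dataclass
class IbdMatrix:
    marker_id: str
    values: pd.DataFrame

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy()


def _pair_prob(states: np.ndarray, share: np.ndarray) -> np.ndarray:
    """P(same parental allele transmitted) per pair from inferred states.

    ``states``: (n,) with NaN for uninformative meioses; ``share``: boolean
    (n, n) mask of pairs sharing that parent.  Uninformative meioses
    contribute the prior 1/2; pairs not sharing the parent contribute 0.
    """
    informative = ~np.isnan(states)
    both = np.outer(informative, informative)
    eq = (states[:, None] == states[None, :]).astype(float)
    P = np.where(both, eq, 0.5)
    return np.where(share, P, 0.0)


def _pair_prob_posterior(p: np.ndarray, share: np.ndarray) -> np.ndarray:
    """P(same parental allele) from per-meiosis posteriors p = P(state 1).

    Meioses are independent given the marker data, so the pair probability is
    p_i p_j + (1 - p_i)(1 - p_j); the single-marker rule is the special case
    p in {0, 1, 1/2}.
    """
    P = np.outer(p, p) + np.outer(1.0 - p, 1.0 - p)
    return np.where(share, P, 0.0)


def locus_ibd(genotypes: GenotypeMatrix, pedigree: Pedigree, marker: str,
              ids: list[str] | None = None, multipoint: bool = False) -> IbdMatrix:
    """Expected proportion of alleles IBD among offspring at one marker.

    For a pair of sibs the expectation averages the paternal and maternal
    meioses: fully informative identical transmissions give 1, opposite
    transmissions 0, and uninformative meioses (homozygous, missing or
    ambiguous parents) the prior 1/2 each.  Unrelated pairs get 0 and the
    diagonal is 1.  With ``multipoint`` the uninformative meioses are
    replaced by posteriors conditioned on the flanking informative markers
    of the linkage group (Haldane transitions, phased parents).
    """
    t = pedigree.table
    if ids is None:
        ids = list(t.loc[t["family_id"].notna(), "individual_id"])
    j = genotypes.marker_column(marker)
    S, D = _transmission_states(genotypes, pedigree, ids)
    tt = t.set_index("individual_id")
    sires = np.array([tt.loc[i, "sire_id"] or "" for i in ids], dtype=object)
    dams = np.array([tt.loc[i, "dam_id"] or "" for i in ids], dtype=object)
    share_s = (sires[:, None] == sires[None, :]) & (sires[:, None] != "")
    share_d = (dams[:, None] == dams[None, :]) & (dams[:, None] != "")
    if multipoint:
        mp = genotypes.marker_map.table
        PS = _transmission_posteriors(_phase_states(S, sires, mp), mp)
        PD = _transmission_posteriors(_phase_states(D, dams, mp), mp)
        Z = 0.5 * (_pair_prob_posterior(PS[:, j], share_s)
                   + _pair_prob_posterior(PD[:, j], share_d))
    else:
        Z = 0.5 * (_pair_prob(S[:, j], share_s) + _pair_prob(D[:, j], share_d))
    np.fill_diagonal(Z, 1.0)
    return IbdMatrix(marker_id=marker, values=pd.DataFrame(Z, index=ids, columns=ids))


def marker_average_kinship(genotypes: GenotypeMatrix, pedigree: Pedigree,
                           ids: list[str] | None = None) -> pd.DataFrame:
    """Marker-based relationship: the mean locus IBD fraction over the panel.

    The expected IBD fraction equals the additive relationship for non-inbred
    pairs (full sibs: 0.5, half sibs: 0.25), so the marker average is a
    drop-in alternative to the pedigree kinship.
    """
    t = pedigree.table
    if ids is None:
        ids = list(t.loc[t["family_id"].notna(), "individual_id"])
    acc = np.zeros((len(ids), len(ids)))
    for mk in genotypes.marker_map.marker_ids:
        acc += locus_ibd(genotypes, pedigree, mk, ids).as_array()
    G = acc / genotypes.n_markers
    np.fill_diagonal(G, 1.0)
    return pd.DataFrame(G, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

def fit_qtl_models(y: np.ndarray, fixed_design: np.ndarray, G: np.ndarray,
                   Z: np.ndarray, blocks=None,
                   start0=None, start1=None) -> tuple[RemlFit, RemlFit]:
    """REML fits of the no-QTL (polygenic) and QTL models at one locus."""
    for name, M in (("G", G), ("Z", Z)):
        w = np.linalg.eigvalsh((M + M.T) / 2)
        if w.min() < -1e-6 * max(w.max(), 1.0):
            raise ValueError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    p0 = RemlProblem(y, fixed_design, [G], names=["polygenic"], blocks=blocks)
    fit0 = p0.fit(start=start0)
    p1 = RemlProblem(y, fixed_design, [G, Z], names=["polygenic", "qtl"], blocks=blocks)
    s1 = start1 if start1 is not None else [max(fit0.gamma[0], 0.01), 0.05]
    fit1 = p1.fit(start=s1)
    if fit1.loglik < fit0.loglik - 1e-6:
        # model 1 nests model 0; retry from the boundary if the optimiser
        # wandered off
        fit1b = p1.fit(start=[fit0.gamma[0], 0.0], extra_starts=False)
        if fit1b.loglik > fit1.loglik:
            fit1 = fit1b
    return fit0, fit1


def qtl_variance_proportion(fit1: RemlFit) -> float:
    """sigma2_q / (sigma2_q + sigma2_a + sigma2_e) from a model-1 fit."""
    s2 = fit1.sigma2_components
    total = float(s2.sum() + fit1.sigma2_e)
    return float(s2[-1] / total) if total > 0 else 0.0


@dataclass
class QtlScanResults:
    """Per-marker likelihood-ratio scan results, ordered along the genome."""

    table: pd.DataFrame
    phenotype: str
    n: int

    def best(self) -> pd.Series:
        return self.table.loc[self.table["LRT"].idxmax()]

    def significant(self, alpha: float = 0.05, bonferroni: bool = False) -> pd.DataFrame:
        thr = alpha / len(self.table) if bonferroni else alpha
        return self.table[self.table["p"] < thr]

    def plot(self, ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = self.table.reset_index(drop=True)
        for g, grp in t.groupby("linkage_group"):
            ax.plot(grp.index, grp["LRT"], marker=".", lw=0.8)
        ax.set_xlabel("marker (by linkage group)")
        ax.set_ylabel("LRT")
        ax.set_title(f"QTL scan: {self.phenotype}")
        return ax


class QtlScan:
    """Genome scan of one phenotype over every mapped marker.

    Statsmodels-style model object: construct with phenotype values and the
    cohort structures, call :meth:`fit` for the full scan.
    """

    def __init__(self, phenotype: pd.Series, fixed: pd.DataFrame,
                 genotypes: GenotypeMatrix, pedigree: Pedigree,
                 fixed_terms: tuple = (("tank",), ("strain",), ("sea_winters",)),
                 multipoint: bool = False):
        """``phenotype`` is indexed by offspring id; ``fixed`` holds the
        design columns (tank, strain, sea-winter age) for the same ids.
        ``multipoint`` conditions each meiosis on flanking informative
        markers (the default); setting it False uses the marker's own
        genotypes only.
        """
        self.ids = list(phenotype.index)
        self.y = phenotype.to_numpy(dtype=float)
        self.phenotype_name = phenotype.name or "trait"
        fixed = fixed.loc[self.ids]
        fixed = fixed.copy()
        fixed["sea_winters"] = fixed["sea_winters"].astype(int)
        self.X, self.design_info = build_design(fixed, fixed_terms)
        self.genotypes = genotypes
        self.pedigree = pedigree
        self.multipoint = multipoint
        self.G = pedigree_kinship(pedigree, self.ids).to_numpy()
        S, D = _transmission_states(genotypes, pedigree, self.ids)
        tt = pedigree.table.set_index("individual_id")
        sires = np.array([tt.loc[i, "sire_id"] or "" for i in self.ids], dtype=object)
        dams = np.array([tt.loc[i, "dam_id"] or "" for i in self.ids], dtype=object)
        self._share_s = (sires[:, None] == sires[None, :]) & (sires[:, None] != "")
        self._share_d = (dams[:, None] == dams[None, :]) & (dams[:, None] != "")
        if multipoint:
            mp = genotypes.marker_map.table
            self._PS = _transmission_posteriors(_phase_states(S, sires, mp), mp)
            self._PD = _transmission_posteriors(_phase_states(D, dams, mp), mp)
        self._S, self._D = S, D
        self.blocks = _partition_blocks([self.G], len(self.ids))

    def ibd_at(self, marker: str) -> np.ndarray:
        """Expected-IBD matrix at one marker, assembled block by block
        (between-family entries are structurally zero)."""
        j = self.genotypes.marker_column(marker)
        n = len(self.ids)
        Z = np.zeros((n, n))
        for b in self.blocks:
            ix = np.ix_(b, b)
            if self.multipoint:
                Z[ix] = 0.5 * (_pair_prob_posterior(self._PS[b, j], self._share_s[ix])
                               + _pair_prob_posterior(self._PD[b, j], self._share_d[ix]))
            else:
                Z[ix] = 0.5 * (_pair_prob(self._S[b, j], self._share_s[ix])
                               + _pair_prob(self._D[b, j], self._share_d[ix]))
        np.fill_diagonal(Z, 1.0)
        return Z

    def fit(self, markers: list[str] | None = None) -> QtlScanResults:
        """Fit models 0 and 1 at each marker; results ordered by linkage
        group and position."""
        mp = self.genotypes.marker_map.table.set_index("marker_id")
        markers = markers if markers is not None else list(mp.index)
        fit0 = RemlProblem(self.y, self.X, [self.G], names=["polygenic"],
                           blocks=self.blocks).fit()
        rows = []
        warm = [max(fit0.gamma[0], 0.01), 0.05]
        p1 = RemlProblem(self.y, self.X, [self.G, np.zeros_like(self.G)],
                         names=["polygenic", "qtl"], blocks=self.blocks)
        for mk in markers:
            Z = self.ibd_at(mk)
            p1.update_component(1, Z)
            f1 = p1.fit(start=warm, extra_starts=False, ftol=1e-10, gtol=1e-7)
            if f1.loglik < fit0.loglik - 1e-6:
                f1b = p1.fit(start=[fit0.gamma[0], 0.0], extra_starts=False)
                if f1b.loglik > f1.loglik:
                    f1 = f1b
            lrt = max(2.0 * (f1.loglik - fit0.loglik), 0.0)
            s2 = f1.sigma2_components
            row = mp.loc[mk]
            rows.append({
                "marker": mk, "linkage_group": int(row["linkage_group"]),
                "position_cm": float(row["position_cm"]), "LRT": lrt,
                "p": boundary_lrt_pvalue(lrt),
                "var_qtl": float(s2[1]), "var_polygenic": float(s2[0]),
                "var_residual": float(f1.sigma2_e),
                "qtl_proportion": qtl_variance_proportion(f1)})
            warm = [max(f1.gamma[0], 0.01), max(f1.gamma[1], 0.02)]
        table = pd.DataFrame(rows).sort_values(
            ["linkage_group", "position_cm"]).reset_index(drop=True)
        return QtlScanResults(table=table, phenotype=self.phenotype_name, n=len(self.y))


# ---------------------------------------------------------------------------
# haplotype contrast
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeContrast:
    parent_id: str
    marker: str
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_sizes: tuple[int, int]
    t: float
    df: int
    p: float


def haplotype_contrast(phenotype: pd.Series, genotypes: GenotypeMatrix,
                       pedigree: Pedigree, parent_id: str,
                       marker: str) -> HaplotypeContrast:
    """Split a parent's offspring by the transmitted parental haplotype at a
    marker and compare phenotype means with a pooled-variance t test."""
    t = pedigree.table
    off = t[(t["sire_id"] == parent_id) | (t["dam_id"] == parent_id)]
    ids = [i for i in off["individual_id"] if i in phenotype.index]
    if not ids:
        raise ValueError(f"parent {parent_id!r} has no phenotyped offspring")
    S, D = _transmission_states(genotypes, pedigree, ids)
    j = genotypes.marker_column(marker)
    is_sire = off.set_index("individual_id").loc[ids, "sire_id"] == parent_id
    states = np.where(is_sire.to_numpy(), S[:, j], D[:, j])
    if np.all(np.isnan(states)):
        raise ValueError(f"parent {parent_id!r} is uninformative at {marker!r}")
    vals = phenotype.loc[ids].to_numpy(dtype=float)
    g1, g2 = vals[states == 0.0], vals[states == 1.0]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two informative offspring per haplotype")
    m1, m2 = float(g1.mean()), float(g2.mean())
    s1, s2 = float(g1.std(ddof=1)), float(g2.std(ddof=1))
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tstat = (m1 - m2) / se if se > 0 else 0.0
    df = n1 + n2 - 2
    p = 2.0 * float(stats.t.sf(abs(tstat), df))
    return HaplotypeContrast(parent_id=parent_id, marker=marker,
                             group_means=(m1, m2), group_sds=(s1, s2),
                             group_sizes=(n1, n2), t=float(tstat), df=df, p=p)
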