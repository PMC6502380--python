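"""Allometric size adjustment and gonadosomatic residuals.

Both kype traits scale allometrically with body size, so raw comparisons
between strains or ages would largely reflect fork length.  Each trait is
regressed on fork length on the log10-log10 scale by ordinary least squares
— one pooled regression over all strains and sea-winter classes — and the
residuals are the size-adjusted traits AKL (adjusted kype length) and AKH
(adjusted kype height).  The gonadosomatic residual (GSR) is the analogous
residual of log10 milt weight on log10 total wet weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import PhenotypeRecord, records_to_frame


@dataclass
class AllometricFit:
    """OLS fit of log10(y) on log10(x): slope, intercept, fit statistics and
    per-fish residuals (log10 units)."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    n: int
    residuals: pd.Series        # indexed by fish id
    slope_se: float
    intercept_se: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats
        t = stats.t.ppf(0.5 + level / 2.0, self.df_den)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se

    def summary(self) -> str:
        return (f"log10(y) = {self.intercept:.4f} + {self.slope:.4f} log10(x), "
                f"R^2 = {self.r_squared:.3f}, F({self.df_num},{self.df_den}) = "
                f"{self.f_statistic:.1f}, n = {self.n}")


def loglog_fit(x, y, ids=None) -> AllometricFit:
    """Ordinary least squares of log10(y) on log10(x).

    Pairs with a null y are excluded pairwise before calling; non-positive
    values are an error naming the offending fish.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ids is None:
        ids = pd.RangeIndex(len(x))
    ids = pd.Index(ids)
    if len(x) != len(y) or len(x) != len(ids):
        raise ValueError("x, y and ids must have equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    for name, arr in (("x", x), ("y", y)):
        bad = ~(arr > 0)
        if bad.any():
            raise ValueError(f"non-positive {name} value for fish {ids[bad][0]!r}")
    lx, ly = np.log10(x), np.log10(y)
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    resid = pd.Series(model.resid, index=ids)
    return AllometricFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), f_statistic=float(model.fvalue),
        df_num=1, df_den=int(model.df_resid), n=len(x), residuals=resid,
        slope_se=float(model.bse[1]), intercept_se=float(model.bse[0]))


def _usable(records, trait: str) -> pd.DataFrame:
    df = records_to_frame(records)
    df = df[df[trait].notna() & df["fork_length"].notna()]
    return df


def size_adjust(records: list[PhenotypeRecord], trait: str) -> tuple[pd.Series, AllometricFit]:
    """Fork-length-adjusted trait values (AKL or AKH) per fish.

    One global log-log regression pooled over strains and sea-winter classes;
    the adjusted value of a fish is its residual.  Fish with a null trait are
    excluded pairwise (the kype-height subset is smaller than the
    kype-length subset).
    """
    if trait not in ("kype_length", "kype_height"):
        raise ValueError(f"trait must be kype_length or kype_height, got {trait!r}")
    df = _usable(records, trait)
    if df.empty:
        raise ValueError(f"no records with non-null {trait}")
    fit = loglog_fit(df["fork_length"], df[trait], ids=df["fish_id"])
    return fit.residuals, fit


def gonadosomatic_residuals(records: list[PhenotypeRecord]) -> tuple[pd.Series, AllometricFit]:
    """GSR per fish: residuals of log10 milt weight on log10 wet weight.

    Fish missing either weight are excluded (no imputation).
    """
    df = records_to_frame(records)
    df = df[df["milt_weight"].notna() & df["wet_weight"].notna()]
    if df.empty:
        raise ValueError("no records with both milt and wet weight")
    fit = loglog_fit(df["wet_weight"], df["milt_weight"], ids=df["fish_id"])
    return fit.residuals, fit


def adjusted_trait_table(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Per-fish table of AKL, AKH and GSR (NaN where the input trait is null)."""
    df = records_to_frame(records).set_index("fish_id")
    out = pd.DataFrame(index=df.index)
    akl, _ = size_adjust(records, "kype_length")
    out["AKL"] = akl
    try:
        akh, _ = size_adjust(records, "kype_height")
        out["AKH"] = akh
    except ValueError:
        out["AKH"] = np.nan
    try:
        gsr, _ = gonadosomatic_residuals(records)
        out["GSR"] = gsr
    except ValueError:
        out["GSR"] = np.nan
    return out.reset_index()
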