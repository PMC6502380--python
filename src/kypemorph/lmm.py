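"""REML linear mixed models for the size-adjusted kype traits.

The full model for each adjusted trait has fixed effects for sea-winter age,
strain and the gonadosomatic residual (plus all two-way interactions) and
random intercepts for family-within-strain, sire and dam:

    AKL ~ SW*strain + SW*GSR + strain*GSR + (1|strain:family) + (1|sire) + (1|dam)

Model reduction follows the usual automatic backward elimination: random
terms are dropped by boundary-corrected REML likelihood-ratio tests
(alpha = 0.1 by default), then fixed terms by type-III F tests with
Satterthwaite denominator degrees of freedom (alpha = 0.05), respecting
marginality.  Estimated marginal means average the fitted surface over the
other factors with equal weights, and pairwise differences are adjusted with
the studentized-range (Tukey) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import (FormulaError, ModelSpec, build_design, parse_formula,
                     random_structure)
from .reml import RemlFit, RemlProblem, boundary_lrt_pvalue


class MixedModel:
    """A Gaussian linear mixed model specified by a formula over a DataFrame.

    Statsmodels-style: construct from data, call :meth:`fit`, inspect the
    returned :class:`MixedModelResults`.
    """

    def __init__(self, spec: ModelSpec | str, data: pd.DataFrame):
        self.spec = parse_formula(spec) if isinstance(spec, str) else spec
        if self.spec.response not in data.columns:
            raise FormulaError(f"response {self.spec.response!r} not in data")
        cols = [self.spec.response] + sorted({v for t in (*self.spec.fixed, *self.spec.random)
                                              for v in t})
        self.data = data[cols].dropna().reset_index(drop=True)
        self.y = np.asarray(self.data[self.spec.response], dtype=float)
        self.X, self.design_info = build_design(self.data, self.spec.fixed)
        self.v_components = random_structure(self.data, self.spec.random)
        self.random_names = [":".join(t) for t in self.spec.random]

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "MixedModel":
        return cls(formula, data)

    def fit(self, start=None, extra_starts: bool = True) -> "MixedModelResults":
        problem = RemlProblem(self.y, self.X, self.v_components, names=self.random_names)
        fit = problem.fit(start=start, extra_starts=extra_starts)
        return MixedModelResults(self, fit)


@dataclass
class MixedModelResults:
    model: MixedModel
    reml: RemlFit

    @property
    def loglik(self) -> float:
        return self.reml.loglik

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self.reml.beta, index=self.model.design_info.column_names)

    @property
    def varcomp(self) -> pd.Series:
        """Variance components, one per random term plus the residual."""
        vals = list(self.reml.sigma2_components) + [self.reml.sigma2_e]
        return pd.Series(vals, index=self.model.random_names + ["residual"])

    @property
    def nobs(self) -> int:
        return self.model.X.shape[0]

    # -- inference ----------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Type-III tests per fixed term with Satterthwaite denominator df."""
        rows = []
        info = self.model.design_info
        p = self.model.X.shape[1]
        for term in self.model.spec.fixed:
            cols = info.term_slices.get(term, [])
            if not cols:
                continue
            L = np.zeros((len(cols), p))
            for i, c in enumerate(cols):
                L[i, c] = 1.0
            F, df1, df2, pval = self.reml.ftest(L)
            rows.append({"term": ":".join(term), "F": F, "df1": df1,
                         "df2": df2, "p": pval})
        return pd.DataFrame(rows)

    def _reference_grid(self) -> pd.DataFrame:
        info = self.model.design_info
        factors = list(info.factor_levels)
        if factors:
            grid = pd.MultiIndex.from_product(
                [info.factor_levels[f] for f in factors], names=factors
            ).to_frame(index=False)
        else:
            grid = pd.DataFrame(index=[0])
        for v, mean in info.covariate_means.items():
            grid[v] = mean
        return grid

    def emmeans(self, factor: str) -> "EmmResult":
        """Estimated marginal means for ``factor`` and Tukey-adjusted pairwise
        comparisons, with Satterthwaite df per comparison."""
        info = self.model.design_info
        if factor not in info.factor_levels:
            raise FormulaError(f"factor {factor!r} is not in the fitted model")
        grid = self._reference_grid()
        rows = info.encode_rows(grid)
        levels = info.factor_levels[factor]
        k = len(levels)
        level_rows = {}
        for lev in levels:
            mask = (grid[factor].astype(str) == lev).to_numpy()
            level_rows[lev] = rows[mask].mean(axis=0)
        means = []
        for lev in levels:
            r = level_rows[lev]
            est = float(r @ self.reml.beta)
            se = float(np.sqrt(r @ self.reml.cov_beta @ r))
            df = self.reml.contrast_df(r)
            means.append({"level": lev, "emmean": est, "se": se, "df": df})
        contrasts = []
        for i in range(k):
            for j in range(i + 1, k):
                d = level_rows[levels[i]] - level_rows[levels[j]]
                est = float(d @ self.reml.beta)
                se = float(np.sqrt(d @ self.reml.cov_beta @ d))
                df = self.reml.contrast_df(d)
                t = est / se if se > 0 else 0.0
                p_raw = 2.0 * float(stats.t.sf(abs(t), df))
                p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
                contrasts.append({"contrast": f"{levels[i]} - {levels[j]}",
                                  "estimate": est, "se": se, "df": df, "t": t,
                                  "p_raw": p_raw, "p_tukey": min(max(p_tukey, p_raw), 1.0)})
        return EmmResult(factor=factor,
                         means=pd.DataFrame(means),
                         contrasts=pd.DataFrame(contrasts))

    def summary(self) -> str:
        lines = [f"Linear mixed model (REML): {self.model.spec.formula()}",
                 f"n = {self.nobs}, REML log-likelihood = {self.loglik:.4f}", "",
                 "Variance components:"]
        for name, v in self.varcomp.items():
            lines.append(f"  {name:<24s} {v:.6g}")
        lines += ["", "Fixed effects:"]
        se = np.sqrt(np.diag(self.reml.cov_beta))
        for name, b, s in zip(self.model.design_info.column_names, self.reml.beta, se):
            lines.append(f"  {name:<24s} {b:+.5f}  (se {s:.5f})")
        an = self.anova()
        if len(an):
            lines += ["", "Type-III tests (Satterthwaite df):"]
            for r in an.itertuples():
                lines.append(f"  {r.term:<18s} F({r.df1:d}, {r.df2:.1f}) = {r.F:.3f}, p = {r.p:.4g}")
        return "\n".join(lines)


@dataclass
class EmmResult:
    factor: str
    means: pd.DataFrame
    contrasts: pd.DataFrame


@dataclass
class EliminationStep:
    step: int
    kind: str       # "random" | "fixed"
    term: str
    statistic: float
    p: float
    action: str     # "dropped" | "kept"


def backward_eliminate(spec: ModelSpec | str, data: pd.DataFrame,
                       alpha_random: float = 0.1,
                       alpha_fixed: float = 0.05):
    """Backward elimination of random then fixed terms.

    Random intercepts are tested by REML likelihood-ratio tests against the
    model without the term, with the boundary-corrected 50:50 chi-square
    mixture; the least significant term above ``alpha_random`` is dropped and
    the procedure repeats.  Fixed terms are then dropped by the largest
    type-III Satterthwaite p above ``alpha_fixed``, never removing a main
    effect while one of its interactions is retained.

    Returns ``(results, trace)`` where ``results`` is the fit of the final
    model and ``trace`` is a DataFrame of :class:`EliminationStep` rows.
    """
    spec = parse_formula(spec) if isinstance(spec, str) else spec
    trace: list[EliminationStep] = []
    step = 0
    fit = MixedModel(spec, data).fit()
    # --- random terms
    while spec.random:
        candidates = []
        for t in spec.random:
            keep = [i for i, u in enumerate(spec.random) if u != t]
            red = MixedModel(spec.drop_random(t), data).fit(
                start=fit.reml.gamma[keep], extra_starts=False)
            lrt = max(2.0 * (fit.loglik - red.loglik), 0.0)
            candidates.append((t, lrt, boundary_lrt_pvalue(lrt), red))
        t, lrt, p, red = max(candidates, key=lambda c: c[2])
        step += 1
        if p > alpha_random:
            trace.append(EliminationStep(step, "random", ":".join(t), lrt, p, "dropped"))
            spec = spec.drop_random(t)
            fit = red
        else:
            for t_, lrt_, p_, _ in candidates:
                trace.append(EliminationStep(step, "random", ":".join(t_), lrt_, p_, "kept"))
            break
    # --- fixed terms
    while True:
        an = fit.anova()
        if not len(an):
            break
        removable = {":".join(t) for t in spec.removable_fixed()}
        an = an[an["term"].isin(removable)]
        if not len(an):
            break
        worst = an.loc[an["p"].idxmax()]
        step += 1
        if worst["p"] > alpha_fixed:
            term = tuple(worst["term"].split(":"))
            trace.append(EliminationStep(step, "fixed", worst["term"],
                                         float(worst["F"]), float(worst["p"]), "dropped"))
            spec = spec.drop_fixed(term)
            fit = MixedModel(spec, data).fit(start=fit.reml.gamma, extra_starts=False)
        else:
            trace.append(EliminationStep(step, "fixed", worst["term"],
                                         float(worst["F"]), float(worst["p"]), "kept"))
            break
    trace_df = pd.DataFrame([s.__dict__ for s in trace],
                            columns=["step", "kind", "term", "statistic", "p", "action"])
    return fit, trace_df
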