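"""Fixed-effect design matrices with sum-to-zero factor coding.

Factors are coded with deviation (sum-to-zero) contrasts so that testing a
term's coefficient block is the type-III hypothesis for that term, and
estimated marginal means average cleanly over the other factors.  Interaction
columns are element-wise products of the coded main-effect columns.  A small
formula grammar covers the model specs used throughout:

    "AKL ~ SW*strain + SW*GSR + strain*GSR + (1|strain:family) + (1|sire) + (1|dam)"
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd


class FormulaError(ValueError):
    pass


Term = tuple[str, ...]  # e.g. ("strain",), ("SW", "GSR"); () is the intercept


@dataclass(frozen=True)
class ModelSpec:
    """Response, fixed terms and random-intercept grouping terms."""

    response: str
    fixed: tuple[Term, ...]
    random: tuple[Term, ...] = ()

    def __post_init__(self):
        mains = {t[0] for t in self.fixed if len(t) == 1}
        for t in self.fixed:
            if len(t) > 1 and not set(t) <= mains:
                raise FormulaError(f"interaction {t} present without both main effects")

    def drop_fixed(self, term: Term) -> "ModelSpec":
        return ModelSpec(self.response, tuple(t for t in self.fixed if t != term), self.random)

    def drop_random(self, term: Term) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed, tuple(t for t in self.random if t != term))

    def add_random(self, term: Term) -> "ModelSpec":
        if term in self.random:
            return self
        return ModelSpec(self.response, self.fixed, self.random + (term,))

    def removable_fixed(self) -> list[Term]:
        """Fixed terms not contained in a retained higher-order term (marginality)."""
        out = []
        for t in self.fixed:
            if any(set(t) < set(u) for u in self.fixed):
                continue
            out.append(t)
        return out

    def formula(self) -> str:
        parts = [":".join(t) for t in self.fixed] or ["1"]
        parts += [f"(1|{':'.join(t)})" for t in self.random]
        return f"{self.response} ~ " + " + ".join(parts)


def parse_formula(formula: str) -> ModelSpec:
    """Parse ``resp ~ a*b + c + (1|g) + (1|a:b)`` into a :class:`ModelSpec`.

    ``a*b`` expands to ``a + b + a:b``; ``a:b`` is the bare interaction;
    ``(1|a:b)`` is a random intercept for the combined grouping.
    """
    if "~" not in formula:
        raise FormulaError(f"formula needs '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    if not response:
        raise FormulaError("empty response")
    fixed: list[Term] = []
    random: list[Term] = []
    for raw in re.split(r"\+", rhs):
        tok = raw.strip()
        if not tok or tok == "1":
            continue
        m = re.fullmatch(r"\(\s*1\s*\|\s*([\w:.]+)\s*\)", tok)
        if m:
            random.append(tuple(v.strip() for v in m.group(1).split(":")))
            continue
        if "*" in tok:
            vars_ = [v.strip() for v in tok.split("*")]
            for v in vars_:
                if (v,) not in fixed:
                    fixed.append((v,))
            for i in range(len(vars_)):
                for j in range(i + 1, len(vars_)):
                    t = (vars_[i], vars_[j])
                    if t not in fixed:
                        fixed.append(t)
        elif ":" in tok:
            t = tuple(v.strip() for v in tok.split(":"))
            if t not in fixed:
                fixed.append(t)
        else:
            if (tok,) not in fixed:
                fixed.append((tok,))
    # order: mains first, then interactions (stable)
    fixed.sort(key=len)
    return ModelSpec(response=response, fixed=tuple(fixed), random=tuple(random))


@dataclass
class DesignInfo:
    """Column bookkeeping for a sum-coded fixed design."""

    terms: list[Term]
    term_slices: dict[Term, list[int]]
    column_names: list[str]
    factor_levels: dict[str, list[str]]
    covariate_means: dict[str, float]
    kept_columns: np.ndarray | None = None  # indices kept after aliasing drop

    def encode_rows(self, grid: pd.DataFrame) -> np.ndarray:
        """Encode arbitrary factor/covariate combinations with the fitted coding."""
        X = _encode(grid, self.terms, self.factor_levels)
        if self.kept_columns is not None:
            X = X[:, self.kept_columns]
        return X


def _code_factor(values: pd.Series, levels: list[str]) -> np.ndarray:
    """Deviation coding: k-1 columns; the last level codes as -1 everywhere."""
    k = len(levels)
    idx = pd.Categorical(values.astype(str), categories=levels).codes
    if np.any(idx < 0):
        bad = sorted(set(values.astype(str)) - set(levels))
        raise FormulaError(f"unseen factor level(s) {bad}")
    out = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        out[idx == j, j] = 1.0
    out[idx == k - 1, :] = -1.0
    return out


def _encode(data: pd.DataFrame, terms: list[Term], factor_levels: dict[str, list[str]]) -> np.ndarray:
    n = len(data)
    cols = [np.ones((n, 1))]
    for t in terms:
        if not t:
            continue
        block = np.ones((n, 1))
        for v in t:
            if v in factor_levels:
                coded = _code_factor(data[v], factor_levels[v])
            else:
                coded = np.asarray(data[v], dtype=float).reshape(n, 1)
            # kronecker-style expansion of the running block with this variable
            block = (block[:, :, None] * coded[:, None, :]).reshape(n, -1)
        cols.append(block)
    return np.concatenate(cols, axis=1)


def build_design(data: pd.DataFrame, terms: tuple[Term, ...],
                 drop_aliased: bool = True) -> tuple[np.ndarray, DesignInfo]:
    """Build the sum-coded fixed design for ``terms`` over ``data``.

    Columns that are exactly aliased (e.g. an interaction cell empty in the
    observed design) are dropped by pivoted-QR rank detection when
    ``drop_aliased`` is set.
    """
    terms = [tuple(t) for t in terms]
    factor_levels: dict[str, list[str]] = {}
    covariate_means: dict[str, float] = {}
    variables = sorted({v for t in terms for v in t})
    for v in variables:
        if v not in data.columns:
            raise FormulaError(f"variable {v!r} not in data")
        col = data[v]
        # float columns are covariates; integer/string columns are factors
        # (sea-winter age is an integer-coded factor, GSR a float covariate)
        if pd.api.types.is_float_dtype(col):
            covariate_means[v] = float(col.mean())
        else:
            factor_levels[v] = sorted(col.astype(str).unique())
    names = ["(Intercept)"]
    slices: dict[Term, list[int]] = {(): [0]}
    pos = 1
    for t in terms:
        if not t:
            continue
        width = 1
        for v in t:
            width *= (len(factor_levels[v]) - 1) if v in factor_levels else 1
        slices[t] = list(range(pos, pos + width))
        names += [f"{':'.join(t)}[{j}]" for j in range(width)]
        pos += width
    X = _encode(data, terms, factor_levels)
    info = DesignInfo(terms=terms, term_slices=slices, column_names=names,
                      factor_levels=factor_levels, covariate_means=covariate_means)
    if drop_aliased and X.shape[1] > 1:
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int(np.sum(diag > diag[0] * 1e-10)) if diag[0] > 0 else 1
        if rank < X.shape[1]:
            keep = np.sort(piv[:rank])
            if 0 not in keep:  # never drop the intercept
                keep = np.sort(np.append(keep[:-1], 0))
            info.kept_columns = keep
            remap = {old: new for new, old in enumerate(keep)}
            info.term_slices = {t: [remap[c] for c in cols if c in remap]
                                for t, cols in info.term_slices.items()}
            info.column_names = [names[c] for c in keep]
            X = X[:, keep]
    return X, info


def random_structure(data: pd.DataFrame, terms: tuple[Term, ...]) -> list[np.ndarray]:
    """One n x n indicator-product matrix per random-intercept term."""
    mats = []
    n = len(data)
    for t in terms:
        labels = data[list(t)].astype(str).agg(":".join, axis=1).to_numpy()
        if len(np.unique(labels)) < 2:
            raise FormulaError(f"random term {t} has fewer than 2 levels")
        mats.append((labels[:, None] == labels[None, :]).astype(float))
    return mats
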