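"""REML engine, Satterthwaite df, type-III tests, EMMs and elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kypemorph.design import FormulaError, parse_formula
from kypemorph.lmm import MixedModel, backward_eliminate
from kypemorph.reml import RemlProblem, boundary_lrt_pvalue


# ---------------------------------------------------------------------------
# formula grammar
# ---------------------------------------------------------------------------

def test_formula_star_expansion_and_random_terms():
    spec = parse_formula(
        "AKL ~ SW*strain + SW*GSR + strain*GSR + (1|strain:family) + (1|sire) + (1|dam)")
    assert spec.response == "AKL"
    assert ("SW",) in spec.fixed and ("SW", "strain") in spec.fixed
    assert len([t for t in spec.fixed if len(t) == 2]) == 3
    assert spec.random == (("strain", "family"), ("sire",), ("dam",))


def test_formula_hierarchy_enforced():
    with pytest.raises(FormulaError):
        parse_formula("y ~ a:b + a")


def test_removable_respects_marginality():
    spec = parse_formula("y ~ a*b + c")
    removable = spec.removable_fixed()
    assert ("a",) not in removable and ("a", "b") in removable and ("c",) in removable


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

def _one_way(k, m, s2b, s2e, seed):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(k), m)
    y = 3.0 + rng.normal(0, np.sqrt(s2b), k)[g] + rng.normal(0, np.sqrt(s2e), k * m)
    X = np.ones((k * m, 1))
    V = (g[:, None] == g[None, :]).astype(float)
    return y, X, V, g


def test_balanced_one_way_closed_form():
    """REML on a balanced one-way random design equals (MSB - MSW)/m."""
    k, m = 25, 5
    y, X, V, g = _one_way(k, m, 2.0, 1.0, seed=1)
    fit = RemlProblem(y, X, [V]).fit()
    ybar = y.reshape(k, m).mean(axis=1)
    msb = m * np.var(ybar, ddof=1)
    msw = np.sum((y.reshape(k, m) - ybar[:, None]) ** 2) / (k * (m - 1))
    assert fit.sigma2_components[0] == pytest.approx((msb - msw) / m, rel=1e-6)
    assert fit.sigma2_e == pytest.approx(msw, rel=1e-6)


def test_profile_grid_agrees_with_optimizer():
    y, X, V, _ = _one_way(15, 4, 1.5, 1.0, seed=2)
    pr = RemlProblem(y, X, [V])
    fit = pr.fit()
    grid = np.linspace(0.0, 8.0, 4000)
    grid_best = max(pr.loglik_profiled([gma]) for gma in grid)
    assert fit.loglik >= grid_best - 1e-4


def test_null_component_estimates_on_boundary():
    """Zero between-group variance: the component lands at 0."""
    rng = np.random.default_rng(5)
    k, m = 12, 6
    g = np.repeat(np.arange(k), m)
    y = rng.normal(0, 1.0, k * m)
    y = y.reshape(k, m)
    y = (y - y.mean(axis=1, keepdims=True)).ravel()  # remove any group signal
    V = (g[:, None] == g[None, :]).astype(float)
    fit = RemlProblem(y, np.ones((k * m, 1)), [V]).fit()
    assert fit.sigma2_components[0] == pytest.approx(0.0, abs=1e-8)


def test_boundary_lrt_pvalue_mixture():
    assert boundary_lrt_pvalue(0.0) == 1.0
    assert boundary_lrt_pvalue(2.706) == pytest.approx(0.05, abs=1e-3)
    assert 0 < boundary_lrt_pvalue(10.0) < 0.001


# ---------------------------------------------------------------------------
# Satterthwaite
# ---------------------------------------------------------------------------

def _frame(seed, n_per=8, k=6, effects=None):
    rng = np.random.default_rng(seed)
    rows = []
    for lev in range(k):
        for i in range(n_per):
            mu = 0.0 if effects is None else effects[lev]
            rows.append({"group": f"g{lev}", "y": mu + rng.normal()})
    return pd.DataFrame(rows)


def test_fixed_only_model_df_is_n_minus_p_and_matches_classical_anova():
    df = _frame(0)
    fit = MixedModel("y ~ group", df).fit()
    an = fit.anova()
    n, k = len(df), df["group"].nunique()
    assert an.loc[0, "df2"] == pytest.approx(n - k)
    # classical one-way ANOVA F as the independent oracle
    groups = [g["y"].to_numpy() for _, g in df.groupby("group")]
    f_classic, p_classic = stats.f_oneway(*groups)
    assert an.loc[0, "F"] == pytest.approx(f_classic, rel=1e-10)
    assert an.loc[0, "p"] == pytest.approx(p_classic, rel=1e-8)


def _split_plot(a=3, r=4, b=3, seed=6):
    """Balanced split-plot: whole-plot factor A, subplot factor B,
    r whole plots per A level."""
    rng = np.random.default_rng(seed)
    rows = []
    for ai in range(a):
        for ri in range(r):
            wp = f"w{ai}_{ri}"
            u = rng.normal(0, 1.0)
            for bi in range(b):
                rows.append({"A": f"a{ai}", "B": f"b{bi}", "wholeplot": wp,
                             "y": 0.5 * ai + 0.3 * bi + u + rng.normal(0, 0.7)})
    return pd.DataFrame(rows), a, r, b


def test_split_plot_satterthwaite_equals_classical_df():
    """On a balanced split-plot the Satterthwaite denominators reproduce the
    classical whole-plot and subplot error degrees of freedom."""
    df, a, r, b = _split_plot()
    fit = MixedModel("y ~ A*B + (1|wholeplot)", df).fit()
    an = fit.anova().set_index("term")
    assert an.loc["A", "df2"] == pytest.approx(a * (r - 1), rel=0.02)
    assert an.loc["B", "df2"] == pytest.approx(a * (r - 1) * (b - 1), rel=0.02)
    assert an.loc["A:B", "df2"] == pytest.approx(a * (r - 1) * (b - 1), rel=0.02)


def test_type3_invariant_to_level_recoding():
    df, *_ = _split_plot(seed=8)
    fit1 = MixedModel("y ~ A*B + (1|wholeplot)", df).fit()
    relabel = {"a0": "zebra", "a1": "alpha", "a2": "m"}
    df2 = df.assign(A=df["A"].map(relabel))
    fit2 = MixedModel("y ~ A*B + (1|wholeplot)", df2).fit()
    a1 = fit1.anova().set_index("term")
    a2 = fit2.anova().set_index("term")
    for term in ("A", "B", "A:B"):
        assert a1.loc[term, "F"] == pytest.approx(a2.loc[term, "F"], rel=1e-6)
        assert a1.loc[term, "df2"] == pytest.approx(a2.loc[term, "df2"], rel=1e-4)


# ---------------------------------------------------------------------------
# EMMs / Tukey
# ---------------------------------------------------------------------------

def test_emmeans_equal_group_means_in_balanced_one_way():
    df = _frame(10, effects=[0.0, 0.5, 1.0, 0.2, -0.3, 0.9])
    fit = MixedModel("y ~ group", df).fit()
    emm = fit.emmeans("group").means.set_index("level")["emmean"]
    raw = df.groupby("group")["y"].mean()
    np.testing.assert_allclose(emm.sort_index(), raw.sort_index(), atol=1e-10)


def test_two_level_tukey_equals_raw_p():
    rng = np.random.default_rng(12)
    df = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10, "y": rng.normal(size=20)})
    emm = MixedModel("y ~ group", df).fit().emmeans("group")
    row = emm.contrasts.iloc[0]
    assert row["p_tukey"] == pytest.approx(row["p_raw"], abs=1e-10)


def test_tukey_adjusted_never_below_raw(small_cohort):
    from kypemorph.allometry import adjusted_trait_table
    from kypemorph.io import records_to_frame
    frame = records_to_frame(small_cohort.records).rename(columns={"sea_winters": "SW"})
    frame = frame.merge(adjusted_trait_table(small_cohort.records), on="fish_id")
    fit = MixedModel("AKL ~ SW + strain + (1|strain:family_id)", frame).fit()
    con = fit.emmeans("strain").contrasts
    assert len(con) == 15  # 6 choose 2
    assert (con["p_tukey"] >= con["p_raw"] - 1e-12).all()
    assert con[["p_raw", "p_tukey"]].le(1.0 + 1e-12).all().all()


def test_familywise_error_of_tukey_all_null():
    """All-null one-way design with 6 levels: the chance that any
    Tukey-adjusted pairwise p falls below 0.05 stays near 0.05.

    The fitted EMM machinery is first checked rep-by-rep against the
    closed-form studentized-range decision (they must agree exactly in the
    balanced fixed-effects case), then the rejection rate is measured with
    the closed form over many replicates.
    """
    rng = np.random.default_rng(99)
    k, m = 6, 8
    crit = stats.studentized_range.ppf(0.95, k, k * (m - 1))

    def range_stat(y):
        means = y.mean(axis=1)
        msw = y.var(axis=1, ddof=1).mean()
        return (means.max() - means.min()) / np.sqrt(msw / m)

    for _ in range(40):
        y = rng.normal(size=(k, m))
        df = pd.DataFrame({"group": np.repeat([f"g{i}" for i in range(k)], m),
                           "y": y.ravel()})
        con = MixedModel("y ~ group", df).fit().emmeans("group").contrasts
        ours = bool((con["p_tukey"] < 0.05).any())
        oracle = bool(range_stat(y) > crit)
        assert ours == oracle
    hits = sum(range_stat(rng.normal(size=(k, m))) > crit for _ in range(4000))
    assert abs(hits / 4000 - 0.05) < 0.012


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def test_elimination_trace_and_noise_terms(small_cohort):
    from kypemorph.allometry import adjusted_trait_table
    from kypemorph.io import records_to_frame
    from kypemorph.pipeline import FULL_MODEL
    frame = records_to_frame(small_cohort.records).rename(columns={"sea_winters": "SW"})
    frame = frame.merge(adjusted_trait_table(small_cohort.records), on="fish_id")
    fit, trace = backward_eliminate(FULL_MODEL.format(response="AKL"), frame)
    # every dropped step's p exceeded its threshold
    for row in trace.itertuples():
        if row.action == "dropped":
            thr = 0.1 if row.kind == "random" else 0.05
            assert row.p > thr
    # anything retained tests at or below the threshold when last examined
    kept = trace[trace["action"] == "kept"]
    assert (kept["p"] <= np.where(kept["kind"] == "random", 0.1, 0.05) + 1e-12).all()


def test_random_term_single_level_errors():
    df = pd.DataFrame({"y": np.random.default_rng(0).normal(size=10),
                       "g": ["same"] * 10})
    with pytest.raises(FormulaError):
        MixedModel("y ~ (1|g)", df)
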