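"""Synthetic-cohort generator: meiosis model, determinism, and the
statistical structure the downstream analysis assumes."""

import numpy as np
import pandas as pd
import pytest

from kypemorph.io import records_to_frame
from kypemorph.morphometrics import gpa, shape_pca
from kypemorph.simulate import (SimulationConfig, haldane_fraction,
                                make_default_map, simulate_cohort,
                                simulate_pedigree, transmit)
from kypemorph.io import MarkerMap


def _two_marker_map(d_cm: float) -> MarkerMap:
    return MarkerMap(pd.DataFrame({"marker_id": ["a", "b"], "linkage_group": [1, 1],
                                   "position_cm": [0.0, d_cm]}))


def test_default_map_shape():
    mp = make_default_map()
    t = mp.table
    assert len(t) == 109
    assert t["linkage_group"].nunique() == 29
    assert (t.groupby("linkage_group")["position_cm"].apply(
        lambda s: s.is_monotonic_increasing)).all()


def test_haldane_limits():
    assert haldane_fraction(0.0) == 0.0
    assert haldane_fraction(1e6) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        haldane_fraction(-1.0)


def test_zero_distance_markers_coinherit():
    rng = np.random.default_rng(0)
    parent = np.array([[0, 1], [0, 1]], dtype=np.int8)  # heterozygous, phased
    _, states = transmit(parent, 500, _two_marker_map(0.0), rng)
    assert np.all(states[:, 0] == states[:, 1])


def test_haldane_empirical_recombination_fraction():
    """d = 10 cM over 20,000 meioses: observed fraction near (1 - e^-0.2)/2."""
    rng = np.random.default_rng(42)
    parent = np.array([[0, 1], [0, 1]], dtype=np.int8)
    _, states = transmit(parent, 20_000, _two_marker_map(10.0), rng)
    frac = float(np.mean(states[:, 0] != states[:, 1]))
    expected = (1.0 - np.exp(-0.2)) / 2.0  # 0.09063...
    se = np.sqrt(expected * (1 - expected) / 20_000)
    assert abs(frac - expected) < 3 * se


def test_same_seed_identical_different_seed_not(small_cohort):
    cfg = small_cohort.truth.config
    a = simulate_cohort(cfg, seed=11)
    b = simulate_cohort(cfg, seed=12)
    assert records_to_frame(a.records).equals(records_to_frame(small_cohort.records))
    np.testing.assert_array_equal(a.genotypes.calls, small_cohort.genotypes.calls)
    assert not records_to_frame(b.records).equals(records_to_frame(a.records))


def test_mendelian_consistency_exhaustive(small_cohort):
    """Every offspring allele is carried by the corresponding parent."""
    g = small_cohort.genotypes
    ped = small_cohort.pedigree.table.set_index("individual_id")
    for ind in ped.index[ped["family_id"].notna()]:
        o = g.row(ind)
        s = g.row(ped.loc[ind, "sire_id"])
        d = g.row(ped.loc[ind, "dam_id"])
        pat_ok = (o[:, 0] == s[:, 0]) | (o[:, 0] == s[:, 1])
        mat_ok = (o[:, 1] == d[:, 0]) | (o[:, 1] == d[:, 1])
        assert pat_ok.all() and mat_ok.all()


def test_pedigree_zero_families_errors():
    cfg = SimulationConfig.balanced(families_per_strain=1)
    cfg.design = {s: {sw: (0, 0, 0) for sw in (1, 2, 3)} for s in cfg.design}
    with pytest.raises(ValueError, match="zero families"):
        simulate_pedigree(cfg, np.random.default_rng(0))


def test_table1_design_counts():
    """The default design realises 37 families with 1SW kype-length males."""
    cohort = simulate_cohort(seed=2)
    from kypemorph.io import summarize_cohort
    s = summarize_cohort(cohort.records)
    assert s.n_males_kype_length == 528
    assert int(s.family_counts[1].sum()) == 37


def test_noise_free_limit_is_deterministic_in_design():
    """With all variances at zero the kype trait is an exact function of
    fork length, strain and sea-winter class."""
    cfg = SimulationConfig.balanced(
        families_per_strain=2, offspring_per_family=6, sw_split=(2, 2, 2),
        marker_map=make_default_map(2, 4), q2=0.0, log_fl_sd=0.0)
    cfg.sigma2_a = {t: 0.0 for t in cfg.sigma2_a}
    cfg.sigma2_e = {t: 0.0 for t in cfg.sigma2_e}
    cohort = simulate_cohort(cfg, seed=3)
    df = records_to_frame(cohort.records)
    df = df[df["kype_length"].notna()]
    grouped = df.groupby(["strain", "sea_winters"])["kype_length"].nunique()
    assert (grouped == 1).all()
    a, b = cfg.allometry["kype_length"]
    one = df.iloc[0]
    expected = 10 ** (a + b * np.log10(one["fork_length"])
                      + cfg.strain_effects["kype_length"][one["strain"]]
                      + cfg.sw_effects["kype_length"][one["sea_winters"]])
    assert one["kype_length"] == pytest.approx(expected, rel=1e-12)


def test_full_sib_phenotypic_covariance_is_half_additive_variance():
    """Over ~5,000 sib pairs the covariance of the non-allometric part of the
    trait approaches sigma2_a / 2 (Monte-Carlo oracle for the additive model)."""
    s2a, s2e = 0.01, 0.01
    cfg = SimulationConfig.balanced(
        families_per_strain=850, offspring_per_family=2, sw_split=(2, 0, 0),
        marker_map=make_default_map(1, 2), q2=0.0, sire_reuse=0.0,
        n_genetic_females=0)
    cfg.design = {"Arna": cfg.design["Arna"]}  # one strain is enough
    cfg.female_design = {}
    cfg.sigma2_a = {t: s2a for t in cfg.sigma2_a}
    cfg.sigma2_e = {t: s2e for t in cfg.sigma2_e}
    cfg.strain_effects = {t: {k: 0.0 for k in v} for t, v in cfg.strain_effects.items()}
    cfg.sw_effects = {t: {k: 0.0 for k in v} for t, v in cfg.sw_effects.items()}
    pairs = []
    for seed in range(6):  # 6 x 850 full-sib pairs
        cohort = simulate_cohort(cfg, seed=seed)
        df = records_to_frame(cohort.records)
        a, b = cfg.allometry["kype_length"]
        df["resid"] = np.log10(df["kype_length"]) - a - b * np.log10(df["fork_length"])
        for _, fam in df.groupby("family_id"):
            r = fam["resid"].to_numpy()
            if len(r) == 2:
                pairs.append((r[0], r[1]))
    pairs = np.asarray(pairs)
    assert len(pairs) >= 5000
    cov = float(np.mean(pairs[:, 0] * pairs[:, 1]))  # means are 0 by construction
    # MC standard error of the product mean is ~sqrt(v1*v2 + cov^2)/sqrt(n)
    se = np.sqrt((s2a + s2e) ** 2 + (s2a / 2) ** 2) / np.sqrt(len(pairs))
    assert abs(cov - s2a / 2) < 4 * se


def test_allometric_slope_ci_coverage():
    """With no strain/SW shifts the fitted log-log slope covers the
    generating value in ~95% of replicates."""
    from kypemorph.allometry import size_adjust
    cfg = SimulationConfig.balanced(
        families_per_strain=3, offspring_per_family=10, sw_split=(4, 3, 3),
        marker_map=make_default_map(1, 2), q2=0.0)
    cfg.strain_effects = {t: {k: 0.0 for k in v} for t, v in cfg.strain_effects.items()}
    cfg.sw_effects = {t: {k: 0.0 for k in v} for t, v in cfg.sw_effects.items()}
    b_true = cfg.allometry["kype_length"][1]
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        cohort = simulate_cohort(cfg, seed=seed)
        _, fit = size_adjust(cohort.records, "kype_length")
        lo, hi = fit.slope_ci()
        hits += lo <= b_true <= hi
    assert hits >= 93


def test_offspring_breeding_value_variance_matches_config():
    """Empirical variance of simulated breeding values tracks sigma2_a."""
    cfg = SimulationConfig.balanced(
        families_per_strain=84, offspring_per_family=4, sw_split=(2, 1, 1),
        marker_map=make_default_map(1, 2), q2=0.0, sire_reuse=0.0)
    s2a = cfg.sigma2_a["kype_length"]
    cohort = simulate_cohort(cfg, seed=9)
    off = cohort.pedigree.table
    off_ids = off.loc[off["family_id"].notna(), "individual_id"]
    bv = cohort.truth.breeding_values["kype_length"].loc[off_ids]
    assert len(bv) == 2016
    assert np.var(bv) == pytest.approx(s2a, rel=0.15)


def test_landmarks_noise_free_identical_up_to_similarity():
    cfg = SimulationConfig.balanced(
        families_per_strain=2, offspring_per_family=6, sw_split=(6, 0, 0),
        marker_map=make_default_map(1, 2), landmark_noise_sd=0.0)
    cfg.sw_displacement = {1: 0.0, 2: 0.0, 3: 0.0}
    cohort = simulate_cohort(cfg, seed=4)
    males = [l for l in cohort.landmarks if l.sex == "male"]
    res = gpa(males[:30])
    assert float(np.sum(res.objective_trace[-1])) < 1e-12


def test_planted_sw_displacement_separates_pc1(default_cohort):
    """The dorsal displacement with sea-winter age makes PC1 the axis that
    separates SW groups more than any other component."""
    males = [l for l in default_cohort.landmarks if l.sex == "male"]
    res = gpa(males)
    pca = shape_pca(res)
    sw = np.array([l.sea_winters for l in males])
    separation = []
    for k in range(4):
        g1 = pca.scores[sw == 1, k].mean()
        g3 = pca.scores[sw == 3, k].mean()
        pooled = pca.scores[:, k].std()
        separation.append(abs(g1 - g3) / pooled)
    assert np.argmax(separation) == 0


def test_landmark_kype_points_encode_phenotype(small_cohort):
    """Measurement points are placed so their distances equal the recorded
    kype length and height."""
    from kypemorph.morphometrics import measure_kype
    recs = {r.fish_id: r for r in small_cohort.records}
    n_checked = 0
    for cfg in small_cohort.landmarks:
        r = recs[cfg.specimen_id]
        if cfg.jaw_points is None:
            continue
        kl, kh = measure_kype(cfg)
        assert kl == pytest.approx(r.kype_length, rel=1e-9)
        if r.kype_height is not None:
            assert kh == pytest.approx(r.kype_height, rel=1e-9)
            n_checked += 1
    assert n_checked > 10
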