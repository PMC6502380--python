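"""Kinship, locus IBD, QTL model fits, scan invariances, haplotype contrast."""

import numpy as np
import pandas as pd
import pytest

from kypemorph.io import records_to_frame
from kypemorph.qtl import (MendelianError, QtlScan, fit_qtl_models,
                           haplotype_contrast, locus_ibd, marker_average_kinship,
                           pedigree_kinship, qtl_variance_proportion)
from kypemorph.reml import RemlFit, RemlProblem

from conftest import toy_genotypes, toy_pedigree


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def test_kinship_founders_identity():
    ped = toy_pedigree(n_off=2)
    A = pedigree_kinship(ped, ["S0", "D0"])
    np.testing.assert_allclose(A.to_numpy(), np.eye(2))


def test_kinship_full_and_half_sibs():
    ped = toy_pedigree(n_off=2, n_fam=2, half_sib=True)
    A = pedigree_kinship(ped, ["O0_0", "O0_1", "O1_0"])
    assert A.loc["O0_0", "O0_1"] == pytest.approx(0.5)   # full sibs
    assert A.loc["O0_0", "O1_0"] == pytest.approx(0.25)  # half sibs (shared sire)
    assert (np.diag(A.to_numpy()) == 1.0).all()


def _kinship_oracle(ped_rows):
    """Independent oracle: coefficient-of-kinship recursion, a_xy = 2 f_xy."""
    parents = {r[0]: (r[1], r[2]) for r in ped_rows}

    def f(x, y, depth=0):
        if x is None or y is None:
            return 0.0
        if x == y:
            sx, dx = parents[x]
            return 0.5 * (1.0 + f(sx, dx))
        # recurse on the individual appearing later in the table
        order = [r[0] for r in ped_rows]
        if order.index(x) < order.index(y):
            x, y = y, x
        sx, dx = parents[x]
        return 0.5 * (f(sx, y) + f(dx, y))

    return f


def test_kinship_against_path_counting_oracle():
    """10-individual three-generation pedigree vs an independent recursion."""
    rows = [("A", None, None), ("B", None, None), ("C", None, None), ("D", None, None),
            ("E", "A", "B"), ("F", "A", "B"), ("G", "C", "D"),
            ("H", "E", "G"), ("I", "F", "G"), ("J", "E", "G")]
    ped_df = pd.DataFrame([{"individual_id": i, "sire_id": s, "dam_id": d,
                            "strain": "Arna",
                            "family_id": None if s is None else f"{s}x{d}"}
                           for i, s, d in rows])
    from kypemorph.io import Pedigree
    ped = Pedigree(ped_df)
    ids = [r[0] for r in rows]
    A = pedigree_kinship(ped, ids)
    f = _kinship_oracle(rows)
    for x in ids:
        for y in ids:
            expected = 2.0 * f(x, y) if x != y else f(x, x) * 2.0
            assert A.loc[x, y] == pytest.approx(expected, abs=1e-12), (x, y)


# ---------------------------------------------------------------------------
# locus IBD
# ---------------------------------------------------------------------------

def test_ibd_uninformative_parents_prior_half():
    """Homozygous AA x AA parents: every full-sib pair sits at the prior."""
    ped = toy_pedigree(n_off=3)
    geno = toy_genotypes(ped, {
        "S0": [0, 0], "D0": [0, 0],
        "O0_0": [0, 0], "O0_1": [0, 0], "O0_2": [0, 0]})
    Z = locus_ibd(geno, ped, "m0").values
    off = ["O0_0", "O0_1", "O0_2"]
    for i in off:
        for j in off:
            assert Z.loc[i, j] == (1.0 if i == j else 0.5)


def test_ibd_fully_informative_extremes():
    """Het x het parents with homozygous offspring: AA vs AA pairs share both
    transmissions (IBD 1), AA vs BB pairs share none (IBD 0)."""
    ped = toy_pedigree(n_off=3)
    geno = toy_genotypes(ped, {
        "S0": [0, 1], "D0": [0, 1],
        "O0_0": [0, 0], "O0_1": [0, 0], "O0_2": [1, 1]})
    Z = locus_ibd(geno, ped, "m0").values
    assert Z.loc["O0_0", "O0_1"] == pytest.approx(1.0)
    assert Z.loc["O0_0", "O0_2"] == pytest.approx(0.0)
    assert Z.loc["O0_0", "O0_0"] == 1.0


def test_ibd_one_informative_parent():
    """AB sire x AA dam: the sire meiosis is read off the offspring, the dam
    meiosis stays at the prior, giving 1/2 (1 + 1/2) or 1/2 (0 + 1/2)."""
    ped = toy_pedigree(n_off=2)
    geno = toy_genotypes(ped, {
        "S0": [0, 1], "D0": [0, 0],
        "O0_0": [0, 0], "O0_1": [1, 0]})
    Z = locus_ibd(geno, ped, "m0").values
    assert Z.loc["O0_0", "O0_1"] == pytest.approx(0.25)  # different sire allele
    geno2 = toy_genotypes(ped, {
        "S0": [0, 1], "D0": [0, 0],
        "O0_0": [0, 0], "O0_1": [0, 0]})
    Z2 = locus_ibd(geno2, ped, "m0").values
    assert Z2.loc["O0_0", "O0_1"] == pytest.approx(0.75)  # same sire allele


def test_ibd_mendelian_error_names_trio_and_marker():
    ped = toy_pedigree(n_off=1)
    geno = toy_genotypes(ped, {"S0": [0, 0], "D0": [0, 0], "O0_0": [1, 1]})
    with pytest.raises(MendelianError, match="O0_0") as exc:
        locus_ibd(geno, ped, "m0")
    assert "m0" in str(exc.value)


def test_ibd_entries_bounded_and_symmetric(small_cohort):
    mk = small_cohort.genotypes.marker_map.marker_ids[0]
    Z = locus_ibd(small_cohort.genotypes, small_cohort.pedigree, mk).as_array()
    assert np.allclose(Z, Z.T)
    assert Z.min() >= 0.0 and Z.max() <= 1.0
    assert np.allclose(np.diag(Z), 1.0)


def test_mean_ibd_over_unlinked_markers_approaches_kinship():
    """Averaged over many unlinked markers the expected IBD fraction
    converges to the pedigree relationship (0.5 for full sibs, 0.25 for
    half sibs)."""
    from kypemorph.io import MarkerMap, GenotypeMatrix
    from kypemorph.simulate import SimulationConfig, simulate_genotypes
    rng = np.random.default_rng(21)
    ped = toy_pedigree(n_off=6, n_fam=2, half_sib=True)
    n_mark = 150
    mp = MarkerMap(pd.DataFrame({"marker_id": [f"u{j}" for j in range(n_mark)],
                                 "linkage_group": np.arange(1, n_mark + 1),
                                 "position_cm": np.zeros(n_mark)}))
    cfg = SimulationConfig(marker_map=mp, q2=0.0, qtl_marker="u0")
    geno = simulate_genotypes(ped, cfg, rng)
    G = marker_average_kinship(geno, ped)
    A = pedigree_kinship(ped, list(G.index))
    off_diag = ~np.eye(len(G), dtype=bool)
    err = np.abs(G.to_numpy() - A.to_numpy())[off_diag]
    assert err.max() < 0.12
    assert err.mean() < 0.04


def test_multipoint_posterior_matches_single_marker_when_informative():
    """Markers 0 cM apart: a meiosis informative at one marker pins the
    posterior at the other, and fully informative pairs agree across the
    two estimators."""
    from kypemorph.io import MarkerMap, GenotypeMatrix
    ped = toy_pedigree(n_off=2)
    mp = MarkerMap(pd.DataFrame({"marker_id": ["a", "b"], "linkage_group": [1, 1],
                                 "position_cm": [0.0, 0.0]}))
    calls = {"S0": [[0, 1], [0, 1]], "D0": [[0, 0], [0, 1]],
             "O0_0": [[0, 0], [0, 0]], "O0_1": [[1, 0], [1, 1]]}
    ids = list(ped.table["individual_id"])
    arr = np.array([calls[i] for i in ids], dtype=np.int8)
    geno = GenotypeMatrix(individual_ids=ids, calls=arr, marker_map=mp)
    z_single = locus_ibd(geno, ped, "a").values
    z_multi = locus_ibd(geno, ped, "a", multipoint=True).values
    # sire informative at 'a' for both offspring: single and multipoint agree
    assert z_multi.loc["O0_0", "O0_1"] <= z_single.loc["O0_0", "O0_1"]
    assert 0.0 <= z_multi.loc["O0_0", "O0_1"] <= 1.0


# ---------------------------------------------------------------------------
# model fits / scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scan_inputs(small_cohort):
    from kypemorph.allometry import size_adjust
    adj, _ = size_adjust(small_cohort.records, "kype_length")
    adj = adj.rename("AKL")
    ped = small_cohort.pedigree
    off_ids = [i for i in ped.table.loc[ped.table["family_id"].notna(),
                                        "individual_id"] if i in adj.index]
    raw = records_to_frame(small_cohort.records).set_index("fish_id")
    fixed = raw.loc[off_ids, ["tank", "strain", "sea_winters"]]
    return adj.loc[off_ids], fixed, small_cohort.genotypes, ped


def test_identical_structures_give_zero_lrt(scan_inputs):
    """Z = G: model 1 cannot improve on model 0 beyond numerical noise."""
    y, fixed, geno, ped = scan_inputs
    scan = QtlScan(y, fixed, geno, ped)
    fit0, fit1 = fit_qtl_models(scan.y, scan.X, scan.G, scan.G.copy(),
                                blocks=scan.blocks)
    lrt = 2.0 * (fit1.loglik - fit0.loglik)
    assert abs(lrt) < 1e-4


def test_grid_profile_matches_optimizer_two_families(scan_inputs):
    y, fixed, geno, ped = scan_inputs
    scan = QtlScan(y, fixed, geno, ped)
    Z = scan.ibd_at(geno.marker_map.marker_ids[3])
    pr = RemlProblem(scan.y, scan.X, [scan.G, Z], blocks=scan.blocks)
    fit = pr.fit()
    best = max(pr.loglik_profiled([a, q])
               for a in np.linspace(0, 4, 60) for q in np.linspace(0, 4, 60))
    assert fit.loglik >= best - 1e-4


def test_variance_proportion_arithmetic():
    fit = RemlFit(problem=None, gamma=np.array([0.5, 0.5]), beta=np.zeros(1),
                  sigma2_e=2.0, cov_beta=np.eye(1), loglik=0.0, converged=True)
    assert qtl_variance_proportion(fit) == pytest.approx(0.25)  # (1,1,2) -> 1/4
    fit0 = RemlFit(problem=None, gamma=np.array([0.7, 0.0]), beta=np.zeros(1),
                   sigma2_e=1.0, cov_beta=np.eye(1), loglik=0.0, converged=True)
    assert qtl_variance_proportion(fit0) == 0.0


def test_lrt_location_scale_invariance(scan_inputs):
    y, fixed, geno, ped = scan_inputs
    markers = geno.marker_map.marker_ids[:4]
    r1 = QtlScan(y, fixed, geno, ped).fit(markers=markers)
    r2 = QtlScan(3.0 * y + 7.0, fixed, geno, ped).fit(markers=markers)
    np.testing.assert_allclose(r1.table["LRT"], r2.table["LRT"], atol=1e-5)


def test_scan_independent_of_marker_order(scan_inputs):
    y, fixed, geno, ped = scan_inputs
    markers = list(geno.marker_map.marker_ids[:6])
    r1 = QtlScan(y, fixed, geno, ped).fit(markers=markers)
    r2 = QtlScan(y, fixed, geno, ped).fit(markers=markers[::-1])
    t1 = r1.table.set_index("marker")["LRT"]
    t2 = r2.table.set_index("marker")["LRT"]
    np.testing.assert_allclose(t1.loc[markers], t2.loc[markers], atol=1e-5)


def test_permutation_destroys_planted_signal():
    """Permuting phenotypes over a cohort with a strong planted QTL collapses
    the LRT at the planted marker."""
    from kypemorph.allometry import size_adjust
    from kypemorph.simulate import SimulationConfig, make_default_map, simulate_cohort
    cfg = SimulationConfig.balanced(
        families_per_strain=4, offspring_per_family=12, sw_split=(4, 4, 4),
        marker_map=make_default_map(2, 6), q2=0.4)
    cohort = simulate_cohort(cfg, seed=17)
    adj, _ = size_adjust(cohort.records, "kype_length")
    adj = adj.rename("AKL")
    ped = cohort.pedigree
    off_ids = [i for i in ped.table.loc[ped.table["family_id"].notna(),
                                        "individual_id"] if i in adj.index]
    raw = records_to_frame(cohort.records).set_index("fish_id")
    fixed = raw.loc[off_ids, ["tank", "strain", "sea_winters"]]
    y = adj.loc[off_ids]
    marker = cfg.qtl_marker
    lrt_true = QtlScan(y, fixed, cohort.genotypes, ped).fit(
        markers=[marker]).table["LRT"].iloc[0]
    rng = np.random.default_rng(1)
    perm_lrts = []
    for _ in range(5):
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index, name="AKL")
        perm_lrts.append(QtlScan(yp, fixed, cohort.genotypes, ped).fit(
            markers=[marker]).table["LRT"].iloc[0])
    assert lrt_true > 4.0
    assert np.median(perm_lrts) < lrt_true / 2


# ---------------------------------------------------------------------------
# haplotype contrast
# ---------------------------------------------------------------------------

def test_haplotype_contrast_pooled_t_oracle():
    ped = toy_pedigree(n_off=6)
    geno = toy_genotypes(ped, {
        "S0": [0, 1], "D0": [0, 0],
        **{f"O0_{i}": ([0, 0] if i < 3 else [1, 0]) for i in range(6)}})
    vals = pd.Series([1.0, 1.2, 0.8, 2.0, 2.5, 2.1],
                     index=[f"O0_{i}" for i in range(6)])
    hc = haplotype_contrast(vals, geno, ped, "S0", "m0")
    g1, g2 = vals.iloc[:3].to_numpy(), vals.iloc[3:].to_numpy()
    sp2 = (g1.var(ddof=1) * 2 + g2.var(ddof=1) * 2) / 4
    t_oracle = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (2 / 3))
    assert hc.t == pytest.approx(t_oracle, abs=1e-12)
    assert hc.df == 4
    assert hc.group_sizes == (3, 3)


def test_haplotype_contrast_identical_groups_t_zero():
    ped = toy_pedigree(n_off=6)
    geno = toy_genotypes(ped, {
        "S0": [0, 1], "D0": [0, 0],
        **{f"O0_{i}": ([0, 0] if i < 3 else [1, 0]) for i in range(6)}})
    vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                     index=[f"O0_{i}" for i in range(6)])
    hc = haplotype_contrast(vals, geno, ped, "S0", "m0")
    assert hc.t == pytest.approx(0.0, abs=1e-12)


def test_haplotype_contrast_uninformative_parent_errors():
    ped = toy_pedigree(n_off=4)
    geno = toy_genotypes(ped, {"S0": [0, 0], "D0": [0, 0],
                               **{f"O0_{i}": [0, 0] for i in range(4)}})
    vals = pd.Series(np.arange(4.0), index=[f"O0_{i}" for i in range(4)])
    with pytest.raises(ValueError, match="uninformative"):
        haplotype_contrast(vals, geno, ped, "S0", "m0")


def test_haplotype_contrast_detects_planted_direction():
    rng = np.random.default_rng(31)
    ped = toy_pedigree(n_off=30)
    calls = {"S0": [0, 1], "D0": [0, 0]}
    vals = {}
    for i in range(30):
        state = i % 2
        calls[f"O0_{i}"] = [state, 0]
        vals[f"O0_{i}"] = 0.5 * state + rng.normal(0, 0.2)
    geno = toy_genotypes(ped, calls)
    hc = haplotype_contrast(pd.Series(vals), geno, ped, "S0", "m0")
    assert hc.group_means[1] > hc.group_means[0]
    assert hc.p < 0.01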