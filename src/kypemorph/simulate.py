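"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the common-garden study design: six strains (one
domesticated, two reciprocal F1 hybrids, three wild), full-sib families with
occasional sire sharing, strongly unbalanced 1-3 sea-winter classes, a
109-SNP panel on 29 linkage groups transmitted by Haldane-model meioses,
log-log allometry of both kype traits on fork length with strain and
sea-winter shifts, a pedigree-structured polygenic term, one planted
biallelic QTL sitting on a panel marker, and landmark configurations with a
sea-winter-graded dorsal displacement.

Every stochastic call flows from a single integer seed through four named
sub-streams (pedigree, genotypes, phenotypes, landmarks), so a cohort is
bit-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import study_design
from .io import (GenotypeMatrix, LandmarkConfiguration, MarkerMap, Pedigree,
                 PhenotypeRecord, STRAINS, write_genotypes, write_pedigree,
                 write_phenotypes, write_tps)

#: hybrid strain -> (dam origin, sire origin)
HYBRID_CROSSES = {"HybridFM": ("Figgjo", "Mowi"), "HybridMF": ("Mowi", "Figgjo")}


def make_default_map(n_groups: int = 29, n_markers: int = 109,
                     group_length_cm: float = 100.0) -> MarkerMap:
    """Markers spread evenly over the linkage groups (default 109 over 29)."""
    base, extra = divmod(n_markers, n_groups)
    rows = []
    for g in range(1, n_groups + 1):
        k = base + (1 if g <= extra else 0)
        for j in range(k):
            pos = group_length_cm * (j + 0.5) / k
            rows.append({"marker_id": f"M{g}_{j + 1}", "linkage_group": g,
                         "position_cm": round(pos, 4)})
    return MarkerMap(pd.DataFrame(rows))


def haldane_fraction(d_cm: np.ndarray) -> np.ndarray:
    """Map distance (cM) to recombination fraction, r = (1 - exp(-2d/100)) / 2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("marker spacing must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass
class SimulationConfig:
    """Generating parameters; the defaults are the published study design.

    Trait parameters are on the log10 scale.  ``q2`` is the fraction of
    non-allometric variance (polygenic + QTL + residual) contributed by the
    planted QTL.
    """

    # strain -> {sw: (n_families_in_cell, n_males_kl, n_males_kh)}
    design: dict = field(default_factory=lambda: {
        s: {sw: (c[0], c[1], c[3]) for sw, c in study_design.MALE_DESIGN[s].items()}
        for s in STRAINS})
    female_design: dict = field(default_factory=lambda: dict(study_design.FEMALE_DESIGN))
    # log10 allometry per trait: intercept a, slope b
    allometry: dict = field(default_factory=lambda: {
        "kype_length": (-1.357, 1.3), "kype_height": (-3.38, 2.0)})
    milt_allometry: tuple = (-1.40, 1.0)      # log10 milt on log10 wet weight
    milt_sd: float = 0.10
    wet_sd: float = 0.02
    log_fl_mean: dict = field(default_factory=lambda: {
        sw: float(np.log10(m)) for sw, m in study_design.FORK_LENGTH_MEAN_CM.items()})
    log_fl_sd: float = 0.035
    strain_effects: dict = field(default_factory=lambda: {
        "kype_length": {"Mowi": 0.012, "HybridMF": 0.006, "HybridFM": 0.0,
                        "Arna": -0.022, "Figgjo": 0.0, "Vosso": 0.0},
        "kype_height": {"Mowi": -0.001, "HybridMF": 0.050, "HybridFM": 0.040,
                        "Arna": 0.100, "Figgjo": 0.115, "Vosso": 0.070}})
    sw_effects: dict = field(default_factory=lambda: {
        "kype_length": {1: 0.002, 2: 0.018, 3: -0.032},
        "kype_height": {1: -0.036, 2: 0.179, 3: 0.051}})
    sigma2_a: dict = field(default_factory=lambda: {
        "kype_length": 0.0008, "kype_height": 0.002})
    sigma2_e: dict = field(default_factory=lambda: {
        "kype_length": 0.0008, "kype_height": 0.002})
    gsr_effect: dict = field(default_factory=lambda: {
        "kype_length": 0.0, "kype_height": 0.0})
    q2: float = 0.05
    qtl_trait: str = "kype_length"
    qtl_marker: str = "M23_2"                 # a panel marker on linkage group 23
    maf: float = 0.5
    marker_map: MarkerMap = field(default_factory=make_default_map)
    sire_reuse: float = 0.3                   # P(two adjacent families share a sire)
    n_tanks: int = 6
    n_genetic_females: int = 3                # milt-producing genetic females kept in
    # landmark generation
    landmark_noise_sd: float = 0.18           # cm, isotropic, 6 head landmarks only
    sw_displacement: dict = field(default_factory=lambda: {
        1: 0.0, 2: 0.3, 3: 0.8})              # dorsal shift (cm) of eye/maxilla/post-gill

    def __post_init__(self):
        if not (0.0 <= self.q2 < 1.0):
            raise ValueError(f"q2 must be in [0, 1), got {self.q2}")
        for d in (self.sigma2_a, self.sigma2_e):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative variance for {k}")
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must be in (0, 1)")

    @classmethod
    def balanced(cls, families_per_strain: int = 5, offspring_per_family: int = 20,
                 sw_split: tuple = (8, 6, 6), **kwargs) -> "SimulationConfig":
        """A balanced design: every strain x SW cell filled, handy for
        simulation studies where the unbalanced published design is not the
        point."""
        if sum(sw_split) != offspring_per_family:
            raise ValueError("sw_split must sum to offspring_per_family")
        if "marker_map" in kwargs and "qtl_marker" not in kwargs:
            ids = kwargs["marker_map"].marker_ids
            kwargs["qtl_marker"] = ids[len(ids) // 2]
        design = {}
        for s in STRAINS:
            design[s] = {sw: (families_per_strain,
                              families_per_strain * sw_split[sw - 1],
                              families_per_strain * sw_split[sw - 1])
                         for sw in (1, 2, 3)}
        return cls(design=design, female_design={}, **kwargs)

    @property
    def traits(self) -> tuple:
        return tuple(self.allometry)


@dataclass
class SimulationTruth:
    """Realised generating values stored alongside every simulated cohort."""

    seed: int
    breeding_values: dict            # trait -> pd.Series by individual
    qtl_marker: str
    qtl_trait: str
    qtl_allele_effect: float         # substitution effect on the log10 trait
    qtl_dose: pd.Series              # B-allele count per offspring
    sigma2_q: float
    config: SimulationConfig


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    records: list
    landmarks: list
    truth: SimulationTruth

    def write(self, outdir: str | Path) -> dict:
        """Emit the exact file formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "phenotypes": "phenotypes.csv", "pedigree": "pedigree.csv",
            "genotypes": "genotypes.csv", "map": "marker_map.csv",
            "landmarks": "landmarks.tps"}.items()}
        write_phenotypes(self.records, paths["phenotypes"])
        write_pedigree(self.pedigree, paths["pedigree"])
        write_genotypes(self.genotypes, paths["genotypes"], paths["map"])
        write_tps(self.landmarks, paths["landmarks"])
        return paths


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Founders and full-sib families realising the configured design.

    Hybrid families are formed as Figgjo(f) x Mowi(m) and Mowi(f) x Figgjo(m)
    crosses; adjacent families within a strain may share a sire (half-sib
    structure), mirroring the partial factorial matings of the breeding
    design.  Offspring rows carry sea-winter class and the kype-height
    measurement flag as extra pedigree columns.
    """
    total_fams = sum(max(c[0] for c in config.design[s].values()) for s in config.design)
    if total_fams == 0:
        raise ValueError("design contains zero families")
    rows = []
    for strain in config.design:
        cells = config.design[strain]
        n_fam = max(c[0] for c in cells.values())
        if n_fam == 0:
            continue
        dam_origin, sire_origin = HYBRID_CROSSES.get(strain, (strain, strain))
        sires, dams = [], []
        for f in range(n_fam):
            if f > 0 and rng.random() < config.sire_reuse:
                sire = sires[-1]
            else:
                sire = f"{strain}_S{f:02d}"
                rows.append({"individual_id": sire, "sire_id": None, "dam_id": None,
                             "strain": sire_origin, "family_id": None,
                             "sea_winters": None, "kh_measured": None})
            dam = f"{strain}_D{f:02d}"
            rows.append({"individual_id": dam, "sire_id": None, "dam_id": None,
                         "strain": dam_origin, "family_id": None,
                         "sea_winters": None, "kh_measured": None})
            sires.append(sire)
            dams.append(dam)
        for sw, (n_fam_cell, n_kl, n_kh) in cells.items():
            if n_kl == 0 or n_fam_cell == 0:
                continue
            # distribute the cell's males over its families as evenly as possible
            base, extra = divmod(n_kl, n_fam_cell)
            sizes = np.full(n_fam_cell, base)
            sizes[rng.permutation(n_fam_cell)[:extra]] += 1
            # which of the cell's males carry a kype-height measurement
            kh_flags = np.zeros(n_kl, dtype=bool)
            kh_flags[rng.permutation(n_kl)[:n_kh]] = True
            k = 0
            for f in range(n_fam_cell):
                for i in range(sizes[f]):
                    rows.append({
                        "individual_id": f"{strain}_{sw}sw_f{f:02d}_{i:02d}",
                        "sire_id": sires[f], "dam_id": dams[f],
                        "strain": strain, "family_id": f"{strain}_F{f:02d}",
                        "sea_winters": sw, "kh_measured": bool(kh_flags[k])})
                    k += 1
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def transmit(parent_calls: np.ndarray, n_off: int, marker_map: MarkerMap,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gene-drop one parent's meioses for ``n_off`` offspring.

    Returns ``(alleles, states)``: the transmitted allele per offspring per
    marker, and which parental chromosome (0/1) it came from.  Recombination
    between adjacent markers within a linkage group follows the Haldane map
    function; linkage groups segregate independently.
    """
    m = parent_calls.shape[0]
    states = np.empty((n_off, m), dtype=np.int8)
    for _, idx, pos in marker_map.groups():
        r = haldane_fraction(np.diff(pos))
        init = rng.integers(0, 2, size=n_off)
        if len(idx) > 1:
            switches = rng.random((n_off, len(idx) - 1)) < r
            cum = np.concatenate([np.zeros((n_off, 1), dtype=int),
                                  np.cumsum(switches, axis=1)], axis=1)
        else:
            cum = np.zeros((n_off, 1), dtype=int)
        states[:, idx] = ((init[:, None] + cum) % 2).astype(np.int8)
    alleles = parent_calls[np.arange(m)[None, :], states]
    return alleles, states


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Founders at Hardy-Weinberg proportions; offspring by Haldane meioses."""
    mp = config.marker_map
    m = len(mp.marker_ids)
    calls = {}
    t = pedigree.table
    founder_mask = t["sire_id"].isna() & t["dam_id"].isna()
    for ind in t.loc[founder_mask, "individual_id"]:
        calls[ind] = (rng.random((m, 2)) < config.maf).astype(np.int8)
    # per full-sib family, drop both parents' gametes for all sibs at once
    off = pedigree.table[pedigree.table["family_id"].notna()]
    for _, grp in off.groupby("family_id", sort=True):
        sire = grp["sire_id"].iloc[0]
        dam = grp["dam_id"].iloc[0]
        n_off = len(grp)
        pat, _ = transmit(calls[sire], n_off, mp, rng)
        mat, _ = transmit(calls[dam], n_off, mp, rng)
        for i, ind in enumerate(grp["individual_id"]):
            calls[ind] = np.stack([pat[i], mat[i]], axis=1)
    ids = [i for i in pedigree.table["individual_id"]]
    arr = np.stack([calls[i] for i in ids])
    return GenotypeMatrix(individual_ids=ids, calls=arr, marker_map=mp)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(pedigree: Pedigree, genotypes: GenotypeMatrix,
                        config: SimulationConfig, rng: np.random.Generator,
                        seed: int = 0) -> tuple[list, SimulationTruth]:
    """Phenotypes from the generating model: for each kype trait,

        log10(trait) = a + b log10(FL) + strain + SW + u + q + e

    with ``u`` the pedigree-structured polygenic value (variance sigma2_a),
    ``q`` the additive effect of the planted QTL (variance fraction ``q2`` of
    the non-allometric variance) and ``e`` iid residual.  Milt and wet weight
    follow log-log links so the gonadosomatic residual is well defined.
    Supplementary mature females carry fork length and wet weight only.
    """
    t = pedigree.table
    off = t[t["family_id"].notna()].reset_index(drop=True)
    order = pedigree.topological_order
    parent_of = {r.individual_id: (r.sire_id, r.dam_id) for r in t.itertuples()}

    breeding = {}
    for trait in config.traits:
        s2a = config.sigma2_a[trait]
        bv: dict[str, float] = {}
        for ind in order:
            sire, dam = parent_of[ind]
            if sire is None:
                bv[ind] = rng.normal(0.0, np.sqrt(s2a)) if s2a > 0 else 0.0
            else:
                mid = 0.5 * (bv[sire] + bv[dam])
                bv[ind] = mid + (rng.normal(0.0, np.sqrt(s2a / 2.0)) if s2a > 0 else 0.0)
        breeding[trait] = pd.Series(bv)

    p = config.maf
    if config.q2 > 0:
        j = genotypes.marker_column(config.qtl_marker)
        dose_all = (genotypes.calls[:, j, :] == 1).sum(axis=1).astype(float)
        dose = pd.Series(dose_all, index=genotypes.individual_ids)
        trait = config.qtl_trait
        s2q = config.q2 * (config.sigma2_a[trait] + config.sigma2_e[trait]) / (1.0 - config.q2)
        alpha = float(np.sqrt(s2q / (2.0 * p * (1.0 - p))))
    else:
        dose = pd.Series(0.0, index=genotypes.individual_ids)
        s2q, alpha = 0.0, 0.0

    records: list[PhenotypeRecord] = []
    n_off = len(off)
    log_fl = np.array([rng.normal(config.log_fl_mean[int(sw)], config.log_fl_sd)
                       for sw in off["sea_winters"]])
    log_wet = np.log10(0.01) + 3.0 * log_fl + rng.normal(0.0, config.wet_sd, n_off)
    a_m, b_m = config.milt_allometry
    milt_resid = rng.normal(0.0, config.milt_sd, n_off)
    log_milt = a_m + b_m * log_wet + milt_resid
    tanks = rng.integers(1, config.n_tanks + 1, n_off)
    genetic_female = np.zeros(n_off, dtype=bool)
    if config.n_genetic_females and n_off > config.n_genetic_females:
        genetic_female[rng.choice(n_off, config.n_genetic_females, replace=False)] = True

    trait_values = {}
    for trait in config.traits:
        a, b = config.allometry[trait]
        vals = a + b * log_fl
        vals += np.array([config.strain_effects[trait][s] for s in off["strain"]])
        vals += np.array([config.sw_effects[trait][int(sw)] for sw in off["sea_winters"]])
        vals += breeding[trait].loc[off["individual_id"]].to_numpy()
        if config.q2 > 0 and trait == config.qtl_trait:
            vals += alpha * (dose.loc[off["individual_id"]].to_numpy() - 2.0 * p)
        vals += config.gsr_effect[trait] * milt_resid
        vals += rng.normal(0.0, np.sqrt(config.sigma2_e[trait]), n_off)
        trait_values[trait] = 10.0 ** vals

    for i, row in enumerate(off.itertuples()):
        records.append(PhenotypeRecord(
            fish_id=row.individual_id, strain=row.strain, family_id=row.family_id,
            sire_id=row.sire_id, dam_id=row.dam_id, sea_winters=int(row.sea_winters),
            tank=f"T{tanks[i]}",
            fork_length=float(10.0 ** log_fl[i]),
            kype_length=float(trait_values["kype_length"][i]),
            kype_height=(float(trait_values["kype_height"][i]) if row.kh_measured else None),
            milt_weight=float(10.0 ** log_milt[i]),
            wet_weight=float(10.0 ** log_wet[i]),
            genetic_sex="female" if genetic_female[i] else "male"))

    for strain, (n_fam, n_f) in config.female_design.items():
        for i in range(n_f):
            lf = rng.normal(config.log_fl_mean[2], config.log_fl_sd)
            records.append(PhenotypeRecord(
                fish_id=f"{strain}_female_{i:03d}", strain=strain,
                family_id=f"{strain}_FF{i % max(n_fam, 1):02d}",
                sire_id=f"{strain}_FS{i % max(n_fam, 1):02d}",
                dam_id=f"{strain}_FD{i % max(n_fam, 1):02d}",
                sea_winters=2, tank=f"T{rng.integers(1, config.n_tanks + 1)}",
                fork_length=float(10.0 ** lf),
                wet_weight=float(10.0 ** (np.log10(0.01) + 3.0 * lf)),
                genetic_sex="female"))

    truth = SimulationTruth(seed=seed, breeding_values=breeding,
                            qtl_marker=config.qtl_marker, qtl_trait=config.qtl_trait,
                            qtl_allele_effect=alpha, qtl_dose=dose,
                            sigma2_q=s2q, config=config)
    return records, truth


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

#: six head landmarks of the mean male shape (cm): upper-jaw apex, dorsal
#: gill-plate, ventral gill-plate, posterior gill-plate, maxillary bone, eye
MALE_MEAN_SHAPE = np.array([
    [0.0, 0.0], [14.0, 6.0], [13.0, -5.0], [16.0, 0.5], [5.0, -1.5], [8.0, 2.5]])
#: females: blunter snout, shallower head
FEMALE_MEAN_SHAPE = np.array([
    [0.5, 0.6], [13.2, 5.2], [12.6, -4.2], [15.2, 0.8], [5.2, -0.6], [7.8, 2.6]])
#: indices displaced dorsally with sea-winter age (posterior gill-plate,
#: maxillary bone, eye), the planted shape signal
SW_SHIFTED = np.array([3, 4, 5])
_REF_FL_CM = 60.0


def simulate_landmarks(records, config: SimulationConfig,
                       rng: np.random.Generator) -> list[LandmarkConfiguration]:
    """Landmark configurations for each fish.

    Each male configuration is the mean shape scaled by the fish's fork
    length, plus the sea-winter dorsal displacement and isotropic Gaussian
    landmark noise, then randomly rotated and translated; the written image
    scale varies per photograph.  Kype measurement points (7-8: jaw pair,
    9-10: hook pair, absent when the mouth was obscured) are placed so their
    distances equal the fish's recorded kype length and height exactly.
    Females get the female mean shape and no kype points.
    """
    configs = []
    for r in records:
        female = r.kype_length is None
        base = (FEMALE_MEAN_SHAPE if female else MALE_MEAN_SHAPE).copy()
        size = r.fork_length / _REF_FL_CM
        pts = base * size
        shift = config.sw_displacement.get(int(r.sea_winters), 0.0)
        pts[SW_SHIFTED, 1] += shift * size
        pts = pts + rng.normal(0.0, config.landmark_noise_sd, pts.shape)
        if not female:
            gill_bottom = pts[2]
            u = np.array([-13.0, 3.5]) / np.hypot(13.0, 3.5)
            jaw_tip = gill_bottom + r.kype_length * u
            pts = np.vstack([pts, jaw_tip, gill_bottom + np.array([0.0, -1e-9])])
            if r.kype_height is not None:
                curv = gill_bottom + 0.85 * r.kype_length * u + np.array([0.0, -0.3 * size])
                peak = curv + np.array([0.0, r.kype_height])
                pts = np.vstack([pts, peak, curv])
        theta = rng.uniform(-np.pi / 18, np.pi / 18)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts = pts @ rot.T + rng.uniform(-5.0, 5.0, 2)
        scale = float(rng.uniform(0.04, 0.06))
        configs.append(LandmarkConfiguration(
            specimen_id=r.fish_id, landmarks=pts, scale=scale,
            sex=r.genetic_sex, sea_winters=int(r.sea_winters)))
    return configs


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Pedigree, genotypes, phenotypes and landmarks from one seed."""
    config = config or SimulationConfig()
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_ped, rng_gen, rng_phen, rng_lm = (np.random.default_rng(s) for s in streams)
    ped = simulate_pedigree(config, rng_ped)
    geno = simulate_genotypes(ped, config, rng_gen)
    records, truth = simulate_phenotypes(ped, geno, config, rng_phen, seed=seed)
    landmarks = simulate_landmarks(records, config, rng_lm)
    return SimulatedCohort(pedigree=ped, genotypes=geno, records=records,
                           landmarks=landmarks, truth=truth)
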