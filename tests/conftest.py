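"""Shared fixtures: the printed-design records and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from kypemorph import study_design
from kypemorph.io import GenotypeMatrix, MarkerMap, Pedigree
from kypemorph.simulate import SimulationConfig, make_default_map, simulate_cohort


@pytest.fixture(scope="session")
def design_records():
    """Deterministic phenotype records realising the published design table."""
    return study_design.build_design_records()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but fully structured cohort: all strains and SW classes,
    small families, a 4-group/12-marker map."""
    cfg = SimulationConfig.balanced(
        families_per_strain=2, offspring_per_family=9, sw_split=(3, 3, 3),
        marker_map=make_default_map(n_groups=4, n_markers=12))
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort from the full published design (528 males + 77 females)."""
    return simulate_cohort(seed=5)


def toy_pedigree(n_off: int = 4, n_fam: int = 1, half_sib: bool = False) -> Pedigree:
    """Small full-sib (optionally half-sib) pedigree for enumeration tests."""
    rows = []
    for f in range(n_fam):
        sire = "S0" if half_sib else f"S{f}"
        if not (half_sib and f > 0):
            rows.append({"individual_id": sire, "sire_id": None, "dam_id": None,
                         "strain": "Arna", "family_id": None})
        rows.append({"individual_id": f"D{f}", "sire_id": None, "dam_id": None,
                     "strain": "Arna", "family_id": None})
        for i in range(n_off):
            rows.append({"individual_id": f"O{f}_{i}", "sire_id": sire,
                         "dam_id": f"D{f}", "strain": "Arna", "family_id": f"F{f}"})
    return Pedigree(pd.DataFrame(rows))


def toy_genotypes(ped: Pedigree, calls_by_id: dict, n_markers: int = 1) -> GenotypeMatrix:
    """Genotypes from explicit per-individual allele pairs (code 0=A, 1=B, -1=missing)."""
    mp = MarkerMap(pd.DataFrame({"marker_id": [f"m{j}" for j in range(n_markers)],
                                 "linkage_group": [1] * n_markers,
                                 "position_cm": list(np.arange(n_markers) * 10.0)}))
    ids = list(ped.table["individual_id"])
    calls = np.full((len(ids), n_markers, 2), -1, dtype=np.int8)
    for i, ind in enumerate(ids):
        calls[i] = np.asarray(calls_by_id[ind], dtype=np.int8).reshape(n_markers, 2)
    return GenotypeMatrix(individual_ids=ids, calls=calls, marker_map=mp)
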