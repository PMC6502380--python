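"""The published cohort design, as printed: strain x sea-winter cell counts.

The study comprised six strains reared in a common garden — the domesticated
Mowi strain, the reciprocal F1 hybrids Figgjo(f) x Mowi(m) ("HybridFM") and
Mowi(f) x Figgjo(m) ("HybridMF"), and three wild populations (Arna, Figgjo,
Vosso) — with males maturing after 1, 2 or 3 sea winters.  For every cell the
design table records the number of full-sib families and the number of males
usable for kype-length analysis, with the (smaller) kype-height subset in a
second count; 77 supplementary 2SW mature females were photographed for the
shape analysis only.

These counts drive both the deterministic bookkeeping fixture built here and
the defaults of :mod:`kypemorph.simulate`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PhenotypeRecord, STRAINS

#: strain -> {sea_winters: (n_families_kl, n_males_kl, n_families_kh, n_males_kh)}
MALE_DESIGN: dict[str, dict[int, tuple[int, int, int, int]]] = {
    "Mowi":     {1: (5, 14, 4, 12), 2: (4, 16, 4, 12), 3: (4, 14, 4, 14)},
    "HybridFM": {1: (6, 95, 6, 91), 2: (5, 8, 4, 7),   3: (5, 13, 4, 11)},
    "HybridMF": {1: (7, 91, 7, 85), 2: (6, 18, 4, 11), 3: (4, 4, 4, 4)},
    "Arna":     {1: (6, 63, 6, 62), 2: (4, 11, 4, 10), 3: (3, 7, 3, 6)},
    "Figgjo":   {1: (6, 64, 6, 61), 2: (6, 8, 5, 6),   3: (0, 0, 0, 0)},
    "Vosso":    {1: (7, 70, 7, 67), 2: (6, 20, 6, 12), 3: (5, 12, 4, 9)},
}

#: strain -> (n_families, n_individuals) of supplementary 2SW mature females
FEMALE_DESIGN: dict[str, tuple[int, int]] = {
    "HybridMF": (7, 32),
    "HybridFM": (5, 14),
    "Arna": (3, 13),
    "Figgjo": (4, 11),
    "Vosso": (2, 4),
    "unknown": (0, 3),
}

#: per-sea-winter fork-length means (cm); sizes grade strongly with SW
FORK_LENGTH_MEAN_CM = {1: 60.0, 2: 80.0, 3: 100.0}


def male_totals() -> dict[str, dict[int, int]]:
    """Column totals of the male design table (kype-length and -height subsets)."""
    kl = {sw: sum(MALE_DESIGN[s][sw][1] for s in STRAINS) for sw in (1, 2, 3)}
    kh = {sw: sum(MALE_DESIGN[s][sw][3] for s in STRAINS) for sw in (1, 2, 3)}
    return {"kype_length": kl, "kype_height": kh}


def n_families_per_strain() -> dict[str, int]:
    """Distinct full-sib families per strain (the 1SW column carries them all)."""
    return {s: MALE_DESIGN[s][1][0] for s in STRAINS}


def design_frame() -> pd.DataFrame:
    rows = []
    for s in STRAINS:
        for sw, (fk, nk, fh, nh) in MALE_DESIGN[s].items():
            rows.append({"strain": s, "sea_winters": sw, "families_kl": fk,
                         "males_kl": nk, "families_kh": fh, "males_kh": nh})
    return pd.DataFrame(rows)


def build_design_records() -> list[PhenotypeRecord]:
    """Deterministic phenotype records realising the printed design exactly.

    Every cell of the male design table is expanded into individual records:
    all have a kype length, and the first ``n_males_kh`` per cell also carry a
    kype height; the female rows have neither.  Measurements are smooth
    deterministic functions of position in the cohort (a noise-free power law
    in fork length), so the fixture exercises regressions without randomness:
    only the bookkeeping — 397/81/50 kype-length males, 378/58/44 kype-height
    males, 77 females, 37 families — is meant to be authoritative.
    """
    records: list[PhenotypeRecord] = []
    for strain in STRAINS:
        for sw in (1, 2, 3):
            n_fam_cell, n_kl, _, n_kh = MALE_DESIGN[strain][sw]
            if n_kl == 0:
                continue
            n_fam_cell = max(n_fam_cell, 1)
            for i in range(n_kl):
                fam = i % n_fam_cell
                fl = FORK_LENGTH_MEAN_CM[sw] * (1.0 + 0.002 * (i % 25) - 0.025)
                kl = 10 ** (-1.357 + 1.3 * np.log10(fl))
                kh = 10 ** (-3.38 + 2.0 * np.log10(fl))
                wet = 0.01 * fl ** 3
                milt = 10 ** (-1.40 + 1.0 * np.log10(wet))
                records.append(PhenotypeRecord(
                    fish_id=f"{strain}_{sw}sw_{i:03d}",
                    strain=strain,
                    family_id=f"{strain}_F{fam:02d}",
                    sire_id=f"{strain}_S{fam:02d}",
                    dam_id=f"{strain}_D{fam:02d}",
                    sea_winters=sw,
                    tank=f"T{i % 6 + 1}",
                    fork_length=round(fl, 3),
                    kype_length=round(kl, 4),
                    kype_height=round(kh, 4) if i < n_kh else None,
                    milt_weight=round(milt, 2),
                    wet_weight=round(wet, 1),
                    genetic_sex="male",
                ))
    for strain, (n_fam, n_f) in FEMALE_DESIGN.items():
        for i in range(n_f):
            fam = i % max(n_fam, 1)
            fl = FORK_LENGTH_MEAN_CM[2] * (1.0 + 0.002 * (i % 25) - 0.025)
            records.append(PhenotypeRecord(
                fish_id=f"{strain}_female_{i:03d}",
                strain=strain,
                family_id=f"{strain}_FF{fam:02d}",
                sire_id=f"{strain}_FS{fam:02d}",
                dam_id=f"{strain}_FD{fam:02d}",
                sea_winters=2,
                tank=f"T{i % 6 + 1}",
                fork_length=round(fl, 3),
                wet_weight=round(0.01 * fl ** 3, 1),
                genetic_sex="female",
            ))
    return records
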