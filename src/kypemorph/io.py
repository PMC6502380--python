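"""Readers and writers for the external formats the pipeline touches.

Four plain-text formats are supported:

* TPS landmark files (the tpsDig dialect: ``LM=``, coordinate lines, optional
  ``SCALE=``, ``ID=`` and ``IMAGE=`` keys),
* a phenotype table (CSV/TSV with header),
* a pedigree table (CSV/TSV), and
* a diploid genotype table plus a linkage map.

All coordinates are planar (digitised lateral photographs); TPS coordinates
are multiplied by ``SCALE`` on read so downstream code works in centimetres.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the six experimental strains: one domesticated (Mowi), two reciprocal F1
#: hybrids and three wild populations; "unknown" occurs only among the
#: supplementary females.
STRAINS = ("Mowi", "HybridFM", "HybridMF", "Arna", "Figgjo", "Vosso")
VALID_STRAINS = STRAINS + ("unknown",)

#: fixed landmark order for the six head landmarks used in Procrustes
#: superimposition: (1) upper-jaw apex, (2) dorsal gill-plate, (3) ventral
#: gill-plate, (4) posterior gill-plate, (5) maxillary bone, (6) eye.
N_GPA_LANDMARKS = 6

#: records may carry 2 extra jaw points (kype length) and 1-2 extra hook
#: points (kype height: dorsal peak, plus the curvature-onset point when one
#: is discernible); those are deliberately excluded from superimposition
#: because mouth opening moves them.
ALLOWED_LANDMARK_COUNTS = (6, 8, 9, 10)


class TpsParseError(ValueError):
    """Malformed TPS record (e.g. LM= count disagrees with coordinate lines)."""


class TpsDimensionError(ValueError):
    """A TPS record whose landmark count is not 6, 8 or 10."""


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class RowError(ValueError):
    """A table row failed validation; the message names the row."""


class PedigreeError(ValueError):
    """Cyclic pedigree or unresolved parent id."""


@dataclass
class LandmarkConfiguration:
    """One specimen's digitised head landmarks, in centimetres.

    The first six points are the superimposition landmarks; points 7-8, when
    present, are the lower-jaw measurement pair and points 9-10 the hook
    (kype height) pair.
    """

    specimen_id: str
    landmarks: np.ndarray  # (k, 2), k in {6, 8, 10}, cm
    scale: float | None = None  # cm per pixel as recorded in the file
    sex: str | None = None
    sea_winters: int | None = None

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise TpsDimensionError(
                f"{self.specimen_id}: landmarks must be (k, 2), got {self.landmarks.shape}"
            )
        if self.landmarks.shape[0] not in ALLOWED_LANDMARK_COUNTS:
            raise TpsDimensionError(
                f"{self.specimen_id}: expected 6 head landmarks "
                f"(optionally + 2 jaw and + 2 hook points), got {self.landmarks.shape[0]}"
            )
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError(f"{self.specimen_id}: non-finite landmark coordinate")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"{self.specimen_id}: scale must be > 0, got {self.scale}")

    @property
    def gpa_landmarks(self) -> np.ndarray:
        """The six points used in Procrustes superimposition."""
        return self.landmarks[:N_GPA_LANDMARKS]

    @property
    def jaw_points(self) -> np.ndarray | None:
        """Anterior lower-jaw point and bottom-of-gill-plate point (kype length)."""
        return self.landmarks[6:8] if self.landmarks.shape[0] >= 8 else None

    @property
    def hook_points(self) -> np.ndarray | None:
        """Dorsal hook peak and, when digitised, the curvature-onset point."""
        return self.landmarks[8:10] if self.landmarks.shape[0] >= 9 else None


@dataclass
class PhenotypeRecord:
    """One fish: identifiers, design factors and linear measurements."""

    fish_id: str
    strain: str
    family_id: str
    sire_id: str
    dam_id: str
    sea_winters: int
    tank: str
    fork_length: float  # cm
    kype_length: float | None = None  # cm
    kype_height: float | None = None  # cm
    milt_weight: float | None = None  # g
    wet_weight: float | None = None  # g
    genetic_sex: str = "male"

    def __post_init__(self) -> None:
        if self.strain not in VALID_STRAINS:
            raise RowError(f"{self.fish_id}: unknown strain {self.strain!r}")
        if int(self.sea_winters) not in (1, 2, 3):
            raise RowError(f"{self.fish_id}: sea_winters must be 1..3, got {self.sea_winters}")
        self.sea_winters = int(self.sea_winters)
        if not self.fork_length > 0:
            raise RowError(f"{self.fish_id}: fork_length must be > 0, got {self.fork_length}")
        for name in ("kype_length", "kype_height", "milt_weight", "wet_weight"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise RowError(f"{self.fish_id}: {name} must be positive when present, got {v}")
        if self.genetic_sex not in ("male", "female"):
            raise RowError(f"{self.fish_id}: genetic_sex must be male/female")


PHENOTYPE_COLUMNS = [
    "fish_id", "strain", "family_id", "sire_id", "dam_id", "sea_winters",
    "tank", "fork_length", "kype_length", "kype_height", "milt_weight",
    "wet_weight", "genetic_sex",
]


@dataclass
class Pedigree:
    """Family structure: rows of (individual, sire, dam, strain, family).

    Founders have null parents.  The table is validated to be acyclic with
    resolvable parent ids, and members of a family must share sire and dam.
    """

    table: pd.DataFrame  # columns individual_id, sire_id, dam_id, strain, family_id

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"individual_id", "sire_id", "dam_id", "strain", "family_id"}
        missing = required - set(t.columns)
        if missing:
            raise SchemaError(f"pedigree missing columns {sorted(missing)}")
        t["individual_id"] = t["individual_id"].astype(str)
        for c in ("sire_id", "dam_id", "family_id"):
            t[c] = t[c].where(t[c].notna(), None)
            t[c] = t[c].map(lambda v: None if v in (None, "", "NA", "0") else str(v))
        if t["individual_id"].duplicated().any():
            dup = t.loc[t["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise PedigreeError(f"duplicated individual id {dup!r}")
        ids = set(t["individual_id"])
        for c in ("sire_id", "dam_id"):
            bad = t.loc[t[c].notna() & ~t[c].isin(ids), c]
            if len(bad):
                raise PedigreeError(f"unknown parent id {bad.iloc[0]!r}")
        self.table = t
        self._order = self._toposort()
        # full sibs must share both parents
        off = t[t["family_id"].notna()]
        for fam, grp in off.groupby("family_id"):
            if grp["sire_id"].nunique(dropna=False) > 1 or grp["dam_id"].nunique(dropna=False) > 1:
                raise PedigreeError(f"family {fam!r} members do not share sire and dam")

    def _toposort(self) -> list[str]:
        t = self.table
        parents = {r.individual_id: (r.sire_id, r.dam_id) for r in t.itertuples()}
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(v: str) -> None:
            stack = [(v, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    raise PedigreeError(f"pedigree cycle involving {node!r}")
                if state.get(node) == 2:
                    continue
                state[node] = 1
                stack.append((node, True))
                for p in parents[node]:
                    if p is not None and state.get(p) != 2:
                        if state.get(p) == 1:
                            raise PedigreeError(f"pedigree cycle involving {p!r}")
                        stack.append((p, False))

        for v in parents:
            if state.get(v) != 2:
                visit(v)
        return order

    @property
    def founders(self) -> list[str]:
        t = self.table
        return list(t.loc[t["sire_id"].isna() & t["dam_id"].isna(), "individual_id"])

    @property
    def topological_order(self) -> list[str]:
        """Every parent precedes its offspring."""
        return list(self._order)

    def parents_of(self, individual_id: str) -> tuple[str | None, str | None]:
        row = self.table.set_index("individual_id").loc[individual_id]
        return row["sire_id"], row["dam_id"]


@dataclass
class MarkerMap:
    """109-SNP panel map: marker id, linkage group (1..29), position in cM."""

    table: pd.DataFrame  # marker_id, linkage_group, position_cm

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        required = {"marker_id", "linkage_group", "position_cm"}
        missing = required - set(t.columns)
        if missing:
            raise SchemaError(f"marker map missing columns {sorted(missing)}")
        t["marker_id"] = t["marker_id"].astype(str)
        t["linkage_group"] = t["linkage_group"].astype(int)
        t["position_cm"] = t["position_cm"].astype(float)
        if (t["position_cm"] < 0).any():
            raise ValueError("map positions must be non-negative")
        for g, grp in t.groupby("linkage_group"):
            if not grp["position_cm"].is_monotonic_increasing:
                raise ValueError(f"positions not non-decreasing within linkage group {g}")
        self.table = t

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    def groups(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """(linkage_group, marker row indices, positions) per group, cached."""
        cached = getattr(self, "_groups", None)
        if cached is None:
            cached = [(int(g), grp.index.to_numpy(), grp["position_cm"].to_numpy())
                      for g, grp in self.table.groupby("linkage_group")]
            object.__setattr__(self, "_groups", cached)
        return cached


@dataclass
class GenotypeMatrix:
    """Diploid calls for individuals x markers plus the linkage map.

    ``calls`` is an int8 array of shape (n_individuals, n_markers, 2) coding
    the two alleles per cell (0 = A, 1 = B, -1 = missing).
    """

    individual_ids: list[str]
    calls: np.ndarray
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m, two = self.calls.shape
        if two != 2:
            raise ValueError("calls must have two alleles per cell")
        if m != len(self.marker_map.marker_ids):
            raise ValueError("number of markers disagrees with the map")
        if n != len(self.individual_ids):
            raise ValueError("number of individuals disagrees with calls")
        self._index = {i: k for k, i in enumerate(self.individual_ids)}
        self._marker_index = {m_: k for k, m_ in enumerate(self.marker_map.marker_ids)}

    def row(self, individual_id: str) -> np.ndarray:
        return self.calls[self._index[individual_id]]

    def marker_column(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_KNOWN_TPS_KEYS = {"LM", "SCALE", "ID", "IMAGE"}


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into configurations (coordinates in cm).

    Coordinates are multiplied by ``SCALE`` when the record carries one, so a
    record digitised in pixels with ``SCALE=0.1`` comes back in centimetres.
    Unknown keys are ignored with a logged warning; a record whose ``LM=``
    count disagrees with its coordinate lines raises :class:`TpsParseError`.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n_record = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = re.match(r"LM\s*=\s*(\d+)$", line, flags=re.IGNORECASE)
        if m is None:
            raise TpsParseError(f"{path}: expected LM= at line {i + 1}, got {line!r}")
        n_record += 1
        n_lm = int(m.group(1))
        coords: list[tuple[float, float]] = []
        i += 1
        while i < len(lines) and len(coords) < n_lm:
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            if "=" in ln:
                break
            parts = ln.split()
            if len(parts) != 2:
                raise TpsParseError(f"{path}: record {n_record}: bad coordinate line {ln!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as e:
                raise TpsParseError(f"{path}: record {n_record}: {e}") from None
            i += 1
        if len(coords) != n_lm:
            raise TpsParseError(
                f"{path}: record {n_record}: LM={n_lm} but found {len(coords)} coordinate lines"
            )
        scale: float | None = None
        specimen_id = f"record_{n_record}"
        while i < len(lines):
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            if re.match(r"LM\s*=", ln, flags=re.IGNORECASE):
                break
            key, _, value = ln.partition("=")
            key = key.strip().upper()
            if key == "SCALE":
                scale = float(value)
            elif key == "ID":
                specimen_id = value.strip()
            elif key == "IMAGE":
                pass
            else:
                logger.warning("%s: record %d: ignoring unknown TPS key %r", path, n_record, key)
            i += 1
        arr = np.asarray(coords, dtype=float)
        if n_lm not in ALLOWED_LANDMARK_COUNTS:
            raise TpsDimensionError(
                f"{path}: record {n_record} ({specimen_id}): LM={n_lm} not in {ALLOWED_LANDMARK_COUNTS}"
            )
        if scale is not None:
            arr = arr * scale
        configs.append(LandmarkConfiguration(specimen_id=specimen_id, landmarks=arr, scale=scale))
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file re-readable by :func:`read_tps`.

    Coordinates are emitted at 6-decimal precision; when a configuration has a
    scale, raw (pixel) coordinates ``cm / scale`` are written together with a
    ``SCALE=`` line so the read/write round trip preserves centimetres.
    """
    if len(configs) == 0:
        raise ValueError("refusing to write an empty TPS file")
    out: list[str] = []
    for cfg in configs:
        pts = cfg.landmarks if cfg.scale is None else cfg.landmarks / cfg.scale
        out.append(f"LM={pts.shape[0]}")
        for x, y in pts:
            out.append(f"{x:.6f} {y:.6f}")
        out.append(f"ID={cfg.specimen_id}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale!r}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Load the per-fish phenotype table.

    Empty measurement cells (e.g. a kype height obscured by a closed mouth)
    become ``None``, never zero.  A missing mandatory column raises
    :class:`SchemaError`; an invalid value raises :class:`RowError` naming the
    row.
    """
    df = _read_table(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records: list[PhenotypeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        kwargs: dict = {k: d[k] for k in ("fish_id", "strain", "family_id", "sire_id",
                                          "dam_id", "tank", "genetic_sex")}
        try:
            kwargs["sea_winters"] = int(d["sea_winters"])
            for name in ("fork_length", "kype_length", "kype_height", "milt_weight", "wet_weight"):
                raw = d[name].strip()
                kwargs[name] = float(raw) if raw not in ("", "NA", "nan") else None
        except ValueError as e:
            raise RowError(f"{path}: row {i}: {e}") from None
        if kwargs["fork_length"] is None:
            raise RowError(f"{path}: row {i}: fork_length is mandatory")
        try:
            records.append(PhenotypeRecord(**kwargs))
        except RowError as e:
            raise RowError(f"{path}: row {i}: {e}") from None
    return records


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in PHENOTYPE_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PhenotypeRecord]:
    recs = []
    for _, row in df.iterrows():
        d = row.to_dict()
        for k, v in list(d.items()):
            if pd.isna(v):
                d[k] = None
        recs.append(PhenotypeRecord(**d))
    return recs


# ---------------------------------------------------------------------------
# cohort bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Strain x sea-winter male counts for each trait's usable subset, plus females."""

    kype_length_counts: pd.DataFrame  # strains x SW, males with non-null kype_length
    kype_height_counts: pd.DataFrame  # strains x SW, males with non-null kype_height
    family_counts: pd.DataFrame       # strains x SW, families with >= 1 KL-measured male
    n_females: int

    @property
    def kype_length_totals(self) -> pd.Series:
        return self.kype_length_counts.sum(axis=0)

    @property
    def kype_height_totals(self) -> pd.Series:
        return self.kype_height_counts.sum(axis=0)

    @property
    def n_males_kype_length(self) -> int:
        return int(self.kype_length_counts.to_numpy().sum())

    @property
    def n_males_kype_height(self) -> int:
        return int(self.kype_height_counts.to_numpy().sum())


def summarize_cohort(records: Sequence[PhenotypeRecord],
                     include_genetic_females: bool = True) -> CohortSummary:
    """Reproduce the cohort bookkeeping table: counts of phenotyped males per
    strain x sea-winter cell, separately for the kype-length and (smaller)
    kype-height subsets, plus the supplementary mature-female count.

    Males here means fish that entered the male kype dataset; the handful of
    genetically female, milt-producing fish are retained by default (flag to
    exclude).
    """
    sw_levels = [1, 2, 3]
    strains = list(STRAINS)
    kl = pd.DataFrame(0, index=strains, columns=sw_levels)
    kh = pd.DataFrame(0, index=strains, columns=sw_levels)
    fams: dict[tuple[str, int], set] = {}
    n_females = 0
    for r in records:
        is_male_dataset = r.kype_length is not None or r.milt_weight is not None
        if not is_male_dataset:
            n_females += 1
            continue
        if r.genetic_sex == "female" and r.milt_weight is None:
            n_females += 1
            continue
        if not include_genetic_females and r.genetic_sex == "female":
            continue
        if r.strain not in strains:
            continue
        if r.kype_length is not None:
            kl.loc[r.strain, r.sea_winters] += 1
            fams.setdefault((r.strain, r.sea_winters), set()).add(r.family_id)
        if r.kype_height is not None:
            kh.loc[r.strain, r.sea_winters] += 1
    fam_counts = pd.DataFrame(0, index=strains, columns=sw_levels)
    for (s, sw), members in fams.items():
        fam_counts.loc[s, sw] = len(members)
    return CohortSummary(kype_length_counts=kl, kype_height_counts=kh,
                         family_counts=fam_counts, n_females=n_females)


# ---------------------------------------------------------------------------
# pedigree / genotypes
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    df = _read_table(path)
    df = df.replace({"": None})
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, index=False)


_ALLELE_CODE = {"A": 0, "B": 1, ".": -1}
_ALLELE_CHAR = {0: "A", 1: "B", -1: "."}


def read_genotypes(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read an individual x marker table of "A/B"-style diploid calls
    ("./." missing) together with its linkage map."""
    mp = MarkerMap(_read_table(map_path))
    df = _read_table(path)
    if "individual_id" not in df.columns:
        raise SchemaError(f"{path}: missing individual_id column")
    marker_cols = [c for c in df.columns if c != "individual_id"]
    unknown = set(marker_cols) - set(mp.marker_ids)
    if unknown:
        raise SchemaError(f"{path}: markers without map entry: {sorted(unknown)[:5]}")
    absent = [m for m in mp.marker_ids if m not in marker_cols]
    if absent:
        raise SchemaError(f"{path}: markers missing from genotype table: {absent[:5]}")
    ids = df["individual_id"].astype(str).tolist()
    calls = np.empty((len(ids), len(mp.marker_ids), 2), dtype=np.int8)
    for j, mk in enumerate(mp.marker_ids):
        col = df[mk].astype(str).str.strip()
        for i, v in enumerate(col):
            a, _, b = v.partition("/")
            try:
                calls[i, j, 0] = _ALLELE_CODE[a]
                calls[i, j, 1] = _ALLELE_CODE[b]
            except KeyError:
                raise RowError(f"{path}: row {i}, marker {mk}: bad call {v!r}") from None
    return GenotypeMatrix(individual_ids=ids, calls=calls, marker_map=mp)


def write_genotypes(geno: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(geno.individual_ids):
        row = {"individual_id": ind}
        for j, mk in enumerate(geno.marker_map.marker_ids):
            a, b = geno.calls[i, j]
            row[mk] = f"{_ALLELE_CHAR[int(a)]}/{_ALLELE_CHAR[int(b)]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    geno.marker_map.table.to_csv(map_path, index=False)
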