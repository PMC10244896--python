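"""Domain types, CSV readers/writers and study filters.

The analysis follows individually marked female gray seals from their first
observed breeding season (recruitment) to the end of the study. Three tables
move through the pipeline:

* an encounter matrix (wide CSV, one row per female, one column per breeding
  season, cells 0/1 = not sighted / sighted with a pup),
* a female covariate table (birth cohort and weaning length L_w in cm),
* a pup table (one row per weighed pup: season, sex, weaning mass in kg,
  maternal age).

Entries before a female's first sighting are structurally absent — the
capture-recapture likelihood conditions on first capture — so ``NA`` cells
are permitted only before the first 1 in a row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sealrep")

__all__ = [
    "FemaleRecord",
    "EncounterHistory",
    "PupRecord",
    "Standardizer",
    "read_encounter_matrix",
    "write_encounter_matrix",
    "read_female_table",
    "write_female_table",
    "read_pup_table",
    "write_pup_table",
    "filter_single_season",
    "derive_parity",
    "fit_standardizer",
    "write_manifest",
    "read_manifest",
]

#: plausible weaning-length range (cm) for study-like data; values outside
#: trigger a warning, not an error (the range observed in the study sample).
LW_PLAUSIBLE_CM = (90.0, 132.0)


@dataclass
class FemaleRecord:
    """One marked female: identity, birth cohort and weaning length."""

    female_id: str
    cohort: int
    weaning_length_cm: float
    recruit_occasion: int | None = None

    def __post_init__(self) -> None:
        lo, hi = LW_PLAUSIBLE_CM
        if not (lo <= self.weaning_length_cm <= hi):
            logger.warning(
                "female %s: weaning length %.1f cm outside plausible range [%g, %g]",
                self.female_id,
                self.weaning_length_cm,
                lo,
                hi,
            )


@dataclass
class EncounterHistory:
    """Per-female 0/1 sighting vector over breeding seasons.

    ``sightings[t]`` is meaningful only for ``t >= recruit_occasion``; earlier
    entries are structurally absent and stored as 0.
    """

    female_id: str
    sightings: np.ndarray
    occasion_labels: np.ndarray

    def __post_init__(self) -> None:
        self.sightings = np.asarray(self.sightings, dtype=np.int8)
        self.occasion_labels = np.asarray(self.occasion_labels, dtype=int)
        if self.sightings.ndim != 1:
            raise ValueError("sightings must be a 1-d vector")
        if self.sightings.shape != self.occasion_labels.shape:
            raise ValueError("sightings and occasion_labels differ in length")
        if not np.isin(self.sightings, (0, 1)).all():
            raise ValueError(
                f"female {self.female_id}: sightings must be 0/1"
            )
        if self.sightings.sum() == 0:
            raise ValueError(f"female {self.female_id}: never sighted")

    @property
    def recruit_occasion(self) -> int:
        """Index of the first sighting (first observed breeding)."""
        return int(np.argmax(self.sightings == 1))

    @property
    def n_sightings(self) -> int:
        return int(self.sightings.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncounterHistory):
            return NotImplemented
        return (
            self.female_id == other.female_id
            and np.array_equal(self.sightings, other.sightings)
            and np.array_equal(self.occasion_labels, other.occasion_labels)
        )


@dataclass
class PupRecord:
    """One weighed pup: mother, season, sex, mass and maternal covariates."""

    female_id: str
    occasion: int
    pup_sex: str  # "female" | "male"
    weaning_mass_kg: float
    maternal_age_yr: int
    parity_group: int | None = None  # 1, 2 or 3 (3 == "3+")

    def __post_init__(self) -> None:
        if self.pup_sex not in ("female", "male"):
            raise ValueError(f"pup_sex must be 'female' or 'male', got {self.pup_sex!r}")
        if self.weaning_mass_kg <= 0:
            raise ValueError("weaning_mass_kg must be positive")


@dataclass
class Standardizer:
    """Affine z-score transform ``x -> (x - mean) / sd``."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("standardizer sd must be > 0")

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def fit_standardizer(values: Iterable[float]) -> Standardizer:
    """Fit a z-score standardizer (sample sd, ddof=1).

    Raises ``ValueError`` on fewer than two distinct values (zero variance).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError("need at least two distinct values to standardize")
    sd = float(arr.std(ddof=1))
    return Standardizer(mean=float(arr.mean()), sd=sd)


# ---------------------------------------------------------------------------
# encounter matrix I/O
# ---------------------------------------------------------------------------

def read_encounter_matrix(path: str | Path) -> list[EncounterHistory]:
    """Read a wide encounter matrix CSV into EncounterHistory objects.

    Header: ``female_id`` then one calendar year per column. Cells are 0, 1
    or NA; NA is allowed only before a female's first sighting.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty encounter matrix")
    id_col = df.columns[0]
    years = np.array([int(c) for c in df.columns[1:]])
    if df[id_col].duplicated().any():
        dups = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate female_id(s): {dups}")
    histories = []
    for _, row in df.iterrows():
        fid = str(row[id_col])
        cells = row.iloc[1:].to_numpy()
        vals = pd.to_numeric(pd.Series(cells), errors="coerce").to_numpy()
        is_na = np.isnan(vals)
        ones = np.where(vals == 1)[0]
        if ones.size == 0:
            raise ValueError(f"female {fid}: never sighted")
        first = ones[0]
        if is_na[first:].any():
            raise ValueError(f"female {fid}: NA cell after first sighting")
        filled = np.where(is_na, 0, vals)
        if not np.isin(filled, (0, 1)).all():
            raise ValueError(f"female {fid}: non-binary cell in encounter row")
        histories.append(
            EncounterHistory(
                female_id=fid,
                sightings=filled.astype(np.int8),
                occasion_labels=years,
            )
        )
    return histories


def write_encounter_matrix(histories: Sequence[EncounterHistory], path: str | Path) -> None:
    """Write histories as a wide CSV (inverse of :func:`read_encounter_matrix`)."""
    if not histories:
        raise ValueError("no histories to write")
    years = histories[0].occasion_labels
    rows = {}
    for h in histories:
        if not np.array_equal(h.occasion_labels, years):
            raise ValueError("histories have inconsistent occasion labels")
        rows[h.female_id] = h.sightings
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[str(y) for y in years])
    df.index.name = "female_id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# female / pup tables
# ---------------------------------------------------------------------------

FEMALE_COLUMNS = ["female_id", "cohort", "weaning_length_cm"]
PUP_COLUMNS = ["female_id", "year", "pup_sex", "weaning_mass_kg", "maternal_age_yr"]


def read_female_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"female_id": str})
    missing = set(FEMALE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"female table missing columns: {sorted(missing)}")
    if df["female_id"].duplicated().any():
        raise ValueError("duplicate female_id in female table")
    lo, hi = LW_PLAUSIBLE_CM
    bad = df[(df.weaning_length_cm < lo) | (df.weaning_length_cm > hi)]
    if len(bad):
        logger.warning(
            "%d weaning lengths outside plausible range [%g, %g] cm", len(bad), lo, hi
        )
    return df[FEMALE_COLUMNS + [c for c in df.columns if c not in FEMALE_COLUMNS]]


def write_female_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_pup_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"female_id": str})
    missing = set(PUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pup table missing columns: {sorted(missing)}")
    if (df.weaning_mass_kg <= 0).any():
        raise ValueError("non-positive pup weaning mass")
    return df


def write_pup_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study filters and derived covariates
# ---------------------------------------------------------------------------

def filter_single_season(histories: Sequence[EncounterHistory]) -> list[EncounterHistory]:
    """Drop females sighted in only one breeding season.

    Single-season females cannot contribute transition information and may
    not have truly recruited; the study sample keeps only females with at
    least two sightings. Idempotent.
    """
    kept = [h for h in histories if h.n_sightings >= 2]
    removed = len(histories) - len(kept)
    if removed:
        logger.info("filter_single_season: removed %d of %d females", removed, len(histories))
    return kept


def derive_parity(pup_table: pd.DataFrame) -> pd.Series:
    """Parity group (1, 2, 3=\"3+\") of each pup record.

    Parity is the mother's cumulative birth count at that record, ordered by
    season within female, discretized as 1, 2, 3+ because the experience
    effect plateaus. Raises on two records for the same female and season.
    """
    if pup_table.duplicated(subset=["female_id", "year"]).any():
        dup = pup_table[pup_table.duplicated(subset=["female_id", "year"], keep=False)]
        raise ValueError(
            "duplicate (female_id, year) pup records: "
            f"{dup[['female_id', 'year']].drop_duplicates().to_dict('records')}"
        )
    order = pup_table.sort_values(["female_id", "year"]).index
    counts = pup_table.loc[order].groupby("female_id").cumcount() + 1
    parity = counts.clip(upper=3).reindex(pup_table.index)
    return parity.rename("parity_group")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_manifest(entries: Mapping[str, object], path: str | Path) -> None:
    """Write a flat key=value manifest (one entry per line, sorted keys)."""
    lines = [f"{k} = {entries[k]}" for k in sorted(entries)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
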