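"""Encounter-history data model, validation and file I/O.

Data enter the package as individual capture histories (one row per
PIT-tagged animal: a binary detection vector over annual sampling
occasions, the marking occasion and age class at marking, and an optional
fledging mass) plus a per-season table of annual covariates (predation
pressure, lagged SST anomaly, climate indices, gateway reader effort,
mean fledging mass).  Histories travel in a MARK-style ``.inp`` text
dialect; covariates travel as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyCalendar",
    "EncounterHistory",
    "YearCovariateTable",
    "StandardizedCovariate",
    "Dataset",
    "InpParseError",
    "COVARIATE_COLUMNS",
    "read_inp",
    "write_inp",
    "read_year_covariates",
    "standardize",
    "filter_missing_mass",
]

FLEDGLING = "fledgling"
ADULT = "adult"

#: canonical annual-covariate columns (lags pre-applied by the data preparer:
#: the value stored at occasion t is the one acting on survival over t -> t+1)
COVARIATE_COLUMNS = (
    "pred_pressure",
    "lsst_lag0",
    "lsst_lag1",
    "enso_lag2",
    "enso_lag3",
    "sam_lag0",
    "sam_lag1",
    "gateway_days",
    "mean_fledging_mass",
)


class InpParseError(ValueError):
    """Raised for malformed ``.inp`` or covariate-CSV content; names the line."""


@dataclass(frozen=True)
class StudyCalendar:
    """Annual sampling design: label of the first season and occasion count."""

    first_season: int = 2003
    n_occasions: int = 10

    def __post_init__(self) -> None:
        if self.n_occasions < 2:
            raise ValueError("a study needs at least 2 occasions")

    @property
    def seasons(self) -> tuple[int, ...]:
        return tuple(self.first_season + i for i in range(self.n_occasions))

    def occasion_of(self, season: int) -> int:
        """1-based occasion index of a season label."""
        idx = season - self.first_season + 1
        if not 1 <= idx <= self.n_occasions:
            raise ValueError(f"season {season} outside calendar {self.seasons[0]}-{self.seasons[-1]}")
        return idx


@dataclass(frozen=True)
class EncounterHistory:
    """One animal: marking info, detection vector, optional fledging mass.

    ``detections`` is the full-length 0/1 vector over all occasions; the
    marking occasion is its first 1.  ``fledging_mass_kg`` is present only
    for animals marked as fledglings (mass at PIT tagging, a proxy for mass
    at fledging).
    """

    animal_id: str
    mark_occasion: int
    mark_class: str
    detections: tuple[int, ...]
    fledging_mass_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mark_class not in (FLEDGLING, ADULT):
            raise ValueError(f"unknown mark_class {self.mark_class!r}")
        det = tuple(int(d) for d in self.detections)
        object.__setattr__(self, "detections", det)
        if any(d not in (0, 1) for d in det):
            raise ValueError(f"{self.animal_id}: non-binary detection")
        if not 1 <= self.mark_occasion <= len(det):
            raise ValueError(f"{self.animal_id}: mark_occasion outside history")
        if det[self.mark_occasion - 1] != 1:
            raise ValueError(f"{self.animal_id}: marking occasion must be a detection")
        if any(det[: self.mark_occasion - 1]):
            raise ValueError(f"{self.animal_id}: detection before marking")
        if self.mark_class == ADULT and self.fledging_mass_kg is not None:
            raise ValueError(f"{self.animal_id}: adults carry no fledging mass")
        if self.fledging_mass_kg is not None and self.fledging_mass_kg < 0:
            raise ValueError(f"{self.animal_id}: negative mass")

    @property
    def is_fledgling(self) -> bool:
        return self.mark_class == FLEDGLING

    def age_at(self, occasion: int) -> int:
        """Age in years at an occasion (0 at marking for fledglings)."""
        return occasion - self.mark_occasion


@dataclass(frozen=True)
class StandardizedCovariate:
    """A covariate together with its z-scores and back-transform info."""

    raw: tuple[float, ...]
    center: float
    scale: float
    z: tuple[float, ...]

    def destandardize(self, z: np.ndarray | float) -> np.ndarray | float:
        return self.center + self.scale * np.asarray(z, dtype=float)

    def standardize_value(self, x: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(x, dtype=float) - self.center) / self.scale


def standardize(values: Sequence[float]) -> StandardizedCovariate:
    """z-score a covariate: (x - mean)/sd with the sample (n-1) sd.

    Effect sizes per 1 SD of the covariate become directly comparable
    between covariates measured in different units.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize needs a 1-d sequence of length >= 2")
    center = float(np.mean(x))
    scale = float(np.std(x, ddof=1))
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError("constant sequence has no scale to standardize by")
    z = (x - center) / scale
    return StandardizedCovariate(tuple(x), center, scale, tuple(z))


@dataclass(frozen=True)
class YearCovariateTable:
    """Annual covariates aligned to occasions 1..n_occasions.

    Missing optional columns are simply absent from ``table``; the
    ``available`` property reports which canonical columns are present.
    """

    calendar: StudyCalendar
    table: pd.DataFrame  # index: occasion 1..T

    def __post_init__(self) -> None:
        if len(self.table) != self.calendar.n_occasions:
            raise ValueError("covariate table must have one row per occasion")
        if list(self.table.index) != list(range(1, self.calendar.n_occasions + 1)):
            raise ValueError("covariate table index must be occasions 1..n_occasions")

    @property
    def available(self) -> tuple[str, ...]:
        return tuple(c for c in COVARIATE_COLUMNS if c in self.table.columns)

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(c for c in COVARIATE_COLUMNS if c not in self.table.columns)

    def values(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"annual covariate {name!r} not available")
        return self.table[name].to_numpy(dtype=float)

    def standardized(self, name: str) -> StandardizedCovariate:
        return standardize(self.values(name))


@dataclass
class Dataset:
    """A validated study: calendar, histories and (optionally) covariates."""

    calendar: StudyCalendar
    histories: list[EncounterHistory]
    year_covariates: Optional[YearCovariateTable] = None
    _mass_standardizer: Optional[StandardizedCovariate] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        T = self.calendar.n_occasions
        seen: set[str] = set()
        for h in self.histories:
            if len(h.detections) != T:
                raise ValueError(f"{h.animal_id}: history length {len(h.detections)} != {T}")
            if h.animal_id in seen:
                raise ValueError(f"duplicate animal_id {h.animal_id!r}")
            seen.add(h.animal_id)

    def __len__(self) -> int:
        return len(self.histories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if self.calendar != other.calendar or self.histories != other.histories:
            return False
        a, b = self.year_covariates, other.year_covariates
        if (a is None) != (b is None):
            return False
        return a is None or a.table.equals(b.table)

    @property
    def fledglings(self) -> list[EncounterHistory]:
        return [h for h in self.histories if h.is_fledgling]

    @property
    def adults(self) -> list[EncounterHistory]:
        return [h for h in self.histories if not h.is_fledgling]

    @property
    def mass_standardizer(self) -> StandardizedCovariate:
        """z-scoring of fledging mass over the pooled retained fledglings.

        Pooled (not per-cohort) so that within- and between-year mass
        contrasts remain on one common scale.
        """
        if self._mass_standardizer is None:
            masses = [h.fledging_mass_kg for h in self.fledglings if h.fledging_mass_kg is not None]
            self._mass_standardizer = standardize(masses)
        return self._mass_standardizer


# ---------------------------------------------------------------------------
# MARK-dialect .inp I/O
#
# One record line per animal:
#     <history string> <frequency> <group> [<mass>] ;
# group: 1 = marked as fledgling, 0 = marked at age 1+ ("adult"); the mass
# column is present exactly for fledglings with recorded mass.  Frequency is
# always 1 here (individual covariates preclude pooling).
# ---------------------------------------------------------------------------


def _parse_inp_line(line: str, lineno: int, T: int, counter: Iterable[int]) -> list[EncounterHistory]:
    body = line.split("/*")[0].strip().rstrip(";").strip()
    if not body:
        return []
    tokens = body.split()
    if len(tokens) < 3:
        raise InpParseError(f"line {lineno}: expected 'history freq group [mass]', got {line!r}")
    hist, freq_s, group_s = tokens[0], tokens[1], tokens[2]
    if len(hist) != T:
        raise InpParseError(f"line {lineno}: history length {len(hist)} != {T}")
    if set(hist) - {"0", "1"}:
        raise InpParseError(f"line {lineno}: non-binary character in history {hist!r}")
    if "1" not in hist:
        raise InpParseError(f"line {lineno}: history contains no detection")
    try:
        freq = int(freq_s)
        group = int(group_s)
    except ValueError as exc:
        raise InpParseError(f"line {lineno}: bad frequency/group field: {exc}") from None
    if group not in (0, 1):
        raise InpParseError(f"line {lineno}: group must be 0 (adult) or 1 (fledgling)")
    mass = None
    if len(tokens) >= 4:
        try:
            mass = float(tokens[3])
        except ValueError:
            raise InpParseError(f"line {lineno}: bad mass field {tokens[3]!r}") from None
    if group == 0 and mass is not None:
        raise InpParseError(f"line {lineno}: mass given for an adult-marked animal")
    mark = hist.index("1") + 1
    out = []
    for _ in range(freq):
        i = next(counter)
        out.append(
            EncounterHistory(
                animal_id=f"a{i:06d}",
                mark_occasion=mark,
                mark_class=FLEDGLING if group == 1 else ADULT,
                detections=tuple(int(c) for c in hist),
                fledging_mass_kg=mass,
            )
        )
    return out


def read_inp(path, calendar: StudyCalendar) -> Dataset:
    """Read a MARK-dialect ``.inp`` file into a validated Dataset.

    The marking occasion is the first '1' of each history; malformed lines
    raise :class:`InpParseError` naming the offending line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    histories: list[EncounterHistory] = []
    counter = iter(range(10**9))
    errors: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        try:
            histories.extend(_parse_inp_line(line, lineno, calendar.n_occasions, counter))
        except InpParseError as exc:
            errors.append(str(exc))
    if errors:
        raise InpParseError("; ".join(errors))
    return Dataset(calendar=calendar, histories=histories)


def write_inp(dataset: Dataset, path) -> str:
    """Write a Dataset in the ``.inp`` dialect, one line per animal.

    Ordering is deterministic (by animal_id); masses print with 2 decimals,
    so a write -> read -> write cycle is byte-identical.
    """
    lines = []
    for h in sorted(dataset.histories, key=lambda h: h.animal_id):
        hist = "".join(str(d) for d in h.detections)
        group = 1 if h.is_fledgling else 0
        if h.fledging_mass_kg is not None:
            lines.append(f"{hist} 1 {group} {h.fledging_mass_kg:.2f};")
        else:
            lines.append(f"{hist} 1 {group};")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
    return str(path)


def read_year_covariates(path, calendar: StudyCalendar) -> YearCovariateTable:
    """Read the annual-covariate CSV and align rows to calendar occasions.

    The CSV carries a ``season`` column plus any subset of
    :data:`COVARIATE_COLUMNS`; rows may arrive in any order and are sorted
    to calendar order.  Missing optional columns are allowed (flagged via
    :attr:`YearCovariateTable.missing`).
    """
    df = pd.read_csv(path)
    if "season" not in df.columns:
        raise InpParseError("covariate CSV needs a 'season' column")
    if len(df) != calendar.n_occasions:
        raise InpParseError(
            f"covariate CSV has {len(df)} rows, calendar has {calendar.n_occasions} occasions"
        )
    try:
        occ = [calendar.occasion_of(int(s)) for s in df["season"]]
    except (ValueError, TypeError) as exc:
        raise InpParseError(f"bad season value: {exc}") from None
    if sorted(occ) != list(range(1, calendar.n_occasions + 1)):
        raise InpParseError("seasons do not cover the calendar exactly once")
    df = df.assign(_occ=occ).sort_values("_occ").set_index("_occ")
    df.index.name = None
    keep = [c for c in COVARIATE_COLUMNS if c in df.columns]
    sub = df[keep].apply(pd.to_numeric, errors="coerce")
    bad = sub.columns[sub.isna().any()].tolist()
    if bad:
        raise InpParseError(f"non-numeric cells in covariate column(s) {bad}")
    return YearCovariateTable(calendar=calendar, table=sub)


def write_year_covariates(table: YearCovariateTable, path) -> str:
    df = table.table.copy()
    df.insert(0, "season", list(table.calendar.seasons))
    df.to_csv(path, index=False, float_format="%.6g")
    return str(path)


def filter_missing_mass(dataset: Dataset) -> tuple[Dataset, int]:
    """Drop fledgling-marked histories lacking a recorded mass.

    Adults are untouched; the removed count is returned so the analysis can
    report it.  Retained histories are passed through unchanged.
    """
    kept = [
        h
        for h in dataset.histories
        if not (h.is_fledgling and h.fledging_mass_kg is None)
    ]
    removed = len(dataset.histories) - len(kept)
    return (
        Dataset(
            calendar=dataset.calendar,
            histories=kept,
            year_covariates=dataset.year_covariates,
        ),
        removed,
    )
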