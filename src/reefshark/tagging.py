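"""Tag-recapture observational data model, readers and filters.

A recapture record pairs an individual's length and date at release with
its length and date at recapture.  Derived quantities are the elapsed
*time at large* (decimal years, day difference / 365.25) and the length
*increment* (recapture TL minus release TL, which may be slightly
negative under measurement error).  Records at large for fewer than a
minimum number of days (150 by default) carry almost no growth signal
relative to measurement noise and are removed before growth modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "TagRecord",
    "IncrementDataset",
    "MaturityObservation",
    "TaggingValidationError",
    "read_increments",
    "write_increments",
    "filter_min_days",
    "summarize_times",
]

#: Decimal-year convention: one year = 365.25 days.
DAYS_PER_YEAR = 365.25

#: Minimum days at large for inclusion in growth analyses (inclusive).
MIN_DAYS_AT_LARGE = 150

_SEXES = ("female", "male", "unknown")
_CLASPER_STATES = ("not_calcified", "partially_calcified", "calcified")

#: Default column mapping for recapture tables.  ``days`` may replace the
#: ``date2`` entry when the source table reports elapsed days instead of a
#: recapture date.
DEFAULT_COLUMNS: dict[str, str] = {
    "id": "individual_id",
    "sex": "sex",
    "date1": "release_date",
    "tl1": "release_tl",
    "date2": "recapture_date",
    "tl2": "recapture_tl",
}


class TaggingValidationError(ValueError):
    """Raised when a recapture table fails row-level validation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("\n".join(self.errors))


@dataclass(frozen=True)
class TagRecord:
    """One release-recapture event for one individual."""

    individual_id: str
    sex: str
    release_date: date
    release_tl: float
    recapture_date: date
    recapture_tl: float

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.recapture_date <= self.release_date:
            raise ValueError(
                f"{self.individual_id}: recapture_date must be after release_date"
            )
        for name, tl in (("release_tl", self.release_tl), ("recapture_tl", self.recapture_tl)):
            if not (0.0 < tl < 400.0):
                raise ValueError(f"{self.individual_id}: {name}={tl} outside (0, 400) cm")
        if self.increment <= -20.0:
            raise ValueError(
                f"{self.individual_id}: increment {self.increment:.1f} cm below -20 cm "
                "gross-error bound"
            )

    @property
    def days_at_large(self) -> int:
        return (self.recapture_date - self.release_date).days

    @property
    def time_at_large(self) -> float:
        """Elapsed time in decimal years (days / 365.25)."""
        return self.days_at_large / DAYS_PER_YEAR

    @property
    def increment(self) -> float:
        """Observed length change in cm (may be negative)."""
        return self.recapture_tl - self.release_tl


@dataclass(frozen=True)
class MaturityObservation:
    """A single male clasper-state observation (or a sexed length record)."""

    individual_id: str
    tl: float
    sex: str = "male"
    clasper_state: str | None = None
    clasper_length: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.clasper_state is not None:
            if self.sex != "male":
                raise ValueError("only male records carry clasper_state")
            if self.clasper_state not in _CLASPER_STATES:
                raise ValueError(
                    f"clasper_state must be one of {_CLASPER_STATES}, got {self.clasper_state!r}"
                )
        if not (0.0 < self.tl < 400.0):
            raise ValueError(f"tl={self.tl} outside (0, 400) cm")


@dataclass(frozen=True)
class IncrementDataset:
    """An immutable collection of :class:`TagRecord` with derived columns."""

    records: tuple[TagRecord, ...]
    removed_short: int = 0  # records dropped by the last min-days filter

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_records(cls, records: Iterable[TagRecord]) -> "IncrementDataset":
        return cls(records=tuple(records))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived ``time_at_large`` and ``increment``."""
        rows = [
            {
                "individual_id": r.individual_id,
                "sex": r.sex,
                "release_date": r.release_date,
                "release_tl": r.release_tl,
                "recapture_date": r.recapture_date,
                "recapture_tl": r.recapture_tl,
                "time_at_large": r.time_at_large,
                "increment": r.increment,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @property
    def release_tl(self) -> np.ndarray:
        return np.array([r.release_tl for r in self.records])

    @property
    def increments(self) -> np.ndarray:
        return np.array([r.increment for r in self.records])

    @property
    def times_at_large(self) -> np.ndarray:
        return np.array([r.time_at_large for r in self.records])

    @property
    def release_times(self) -> np.ndarray:
        """Release dates as decimal years (for seasonal adjustment)."""
        return np.array([_decimal_year(r.release_date) for r in self.records])

    def sex_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in _SEXES}
        for r in self.records:
            counts[r.sex] += 1
        return {s: n for s, n in counts.items() if n}

    def subset_sex(self, sex: str) -> "IncrementDataset":
        return IncrementDataset.from_records(r for r in self.records if r.sex == sex)


def _decimal_year(d: date) -> float:
    start = date(d.year, 1, 1)
    return d.year + (d - start).days / DAYS_PER_YEAR


def _parse_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    ts = pd.Timestamp(value)
    if pd.isna(ts):
        raise ValueError(f"unparseable date {value!r}")
    return ts.date()


def read_increments(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> IncrementDataset:
    """Read a recapture table from CSV/TSV into an :class:`IncrementDataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    columns
        Mapping from the canonical keys ``{id, sex, date1, tl1, date2, tl2}``
        to the file's column names.  ``days`` may be supplied instead of
        ``date2`` for tables that record elapsed days at large rather than a
        recapture date.
    sep
        Field separator; inferred from the file extension when omitted.

    Raises
    ------
    TaggingValidationError
        Listing every malformed row by line number, plus duplicated
        ``(id, release_date)`` pairs.
    """
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    uses_days = "days" in mapping and mapping["days"] in df.columns
    needed = ["id", "sex", "date1", "tl1", "tl2"] + (["days"] if uses_days else ["date2"])
    missing = [mapping[k] for k in needed if mapping[k] not in df.columns]
    if missing:
        raise TaggingValidationError([f"missing required column(s): {missing}"])

    records: list[TagRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            d1 = _parse_date(row[mapping["date1"]])
            if uses_days:
                d2 = d1 + timedelta(days=int(float(row[mapping["days"]])))
            else:
                d2 = _parse_date(row[mapping["date2"]])
            rec = TagRecord(
                individual_id=str(row[mapping["id"]]),
                sex=str(row[mapping["sex"]]).strip().lower(),
                release_date=d1,
                release_tl=float(row[mapping["tl1"]]),
                recapture_date=d2,
                recapture_tl=float(row[mapping["tl2"]]),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        records.append(rec)

    seen: set[tuple[str, date]] = set()
    for rec in records:
        key = (rec.individual_id, rec.release_date)
        if key in seen:
            errors.append(f"duplicate (id, release_date): {key}")
        seen.add(key)

    if errors:
        raise TaggingValidationError(errors)
    return IncrementDataset.from_records(records)


def write_increments(ds: IncrementDataset, path, sep: str = ",") -> None:
    """Write the dataset back to a delimited file (round-trips with the reader)."""
    df = ds.to_frame()[
        ["individual_id", "sex", "release_date", "release_tl", "recapture_date", "recapture_tl"]
    ].copy()
    for c in ("release_date", "recapture_date"):
        df[c] = df[c].map(lambda d: d.isoformat())
    df.to_csv(path, sep=sep, index=False)


def filter_min_days(ds: IncrementDataset, min_days: int = MIN_DAYS_AT_LARGE) -> IncrementDataset:
    """Keep records at large for at least ``min_days`` days (inclusive)."""
    if min_days < 0:
        raise ValueError("min_days must be >= 0")
    kept = tuple(r for r in ds.records if r.days_at_large >= min_days)
    removed = len(ds.records) - len(kept)
    if not kept:
        warnings.warn("filter_min_days removed every record", stacklevel=2)
    return IncrementDataset(records=kept, removed_short=removed)


def summarize_times(ds: IncrementDataset) -> dict[str, float]:
    """Median and maximum time at large (years, 1 dp) and maximum increment (cm)."""
    if not ds.records:
        raise ValueError("empty dataset")
    t = ds.times_at_large
    return {
        "n": len(ds.records),
        "median_years": round(float(np.median(t)), 1),
        "max_years": round(float(np.max(t)), 1),
        "max_increment_cm": float(np.max(ds.increments)),
    }
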