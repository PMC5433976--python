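"""Domain types, coordinate conventions and CSV I/O for ringing capture tables.

A capture record holds the day-of-year and calendar year of a first capture,
its (possibly unidentified) age and sex, body weight in grams, third-primary
length in millimetres, and an optional plumage label.  Age and sex are binary
codes (0 = young / female, 1 = adult / male); the four combinations form the
age-sex classes g = 1..4 used throughout the model:

    g = 1  young female      g = 3  adult female
    g = 2  young male        g = 4  adult male

Day enters the model centered on the midpoint of the capture season
(``day_c = 0`` in the middle of the capturing period) and year centered on a
reference year, so that slope parameters read directly as per-day and per-year
changes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_YOUNG = 0
AGE_ADULT = 1
SEX_FEMALE = 0
SEX_MALE = 1

PLUMAGE_FEMALE_COLORED = "female_colored"
PLUMAGE_PARADOXUS = "paradoxus"
PLUMAGE_LEVELS = (PLUMAGE_FEMALE_COLORED, PLUMAGE_PARADOXUS)

CLASS_LABELS = {1: "young female", 2: "young male", 3: "adult female", 4: "adult male"}

#: age code of class g (index g-1) and sex code of class g
CLASS_AGE = np.array([0, 0, 1, 1])
CLASS_SEX = np.array([0, 1, 0, 1])

CSV_COLUMNS = ["id", "year", "day", "age", "sex", "weight_g", "primary_mm", "plumage"]
SHADOW_COLUMNS = ["true_age", "true_sex"]


class LabelNotObserved(ValueError):
    """Raised when an operation requires an observed age/sex label that is missing."""


def class_index(age: int, sex: int) -> int:
    """Map an (age, sex) pair to the age-sex class g in {1, 2, 3, 4}.

    g = 1 + sex + 2*age: young females are class 1, young males class 2,
    adult females class 3 and adult males class 4.
    """
    if age is None or sex is None or (isinstance(age, float) and np.isnan(age)) or (
        isinstance(sex, float) and np.isnan(sex)
    ):
        raise LabelNotObserved("age and sex must both be observed to assign a class")
    age = int(age)
    sex = int(sex)
    if age not in (0, 1) or sex not in (0, 1):
        raise ValueError(f"age and sex must be binary codes, got age={age}, sex={sex}")
    return 1 + sex + 2 * age


def class_to_age_sex(g: int) -> tuple[int, int]:
    """Inverse of :func:`class_index`: class g -> (age, sex)."""
    if g not in (1, 2, 3, 4):
        raise ValueError(f"class index must be in 1..4, got {g}")
    return int(CLASS_AGE[g - 1]), int(CLASS_SEX[g - 1])


@dataclass(frozen=True)
class CaptureRecord:
    """One first-capture of a bird."""

    id: str
    year: int
    day: int  # 1-based day of year
    age: int | None  # 0 young, 1 adult, None unidentified
    sex: int | None  # 0 female, 1 male, None unidentified
    weight: float  # grams
    primary: float  # third-primary length, mm
    plumage: str | None = None

    def __post_init__(self) -> None:
        if not (self.weight > 0 and np.isfinite(self.weight)):
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not (self.primary > 0 and np.isfinite(self.primary)):
            raise ValueError(f"primary length must be positive, got {self.primary}")
        if self.age is not None and self.age not in (0, 1):
            raise ValueError(f"age code must be 0/1/None, got {self.age}")
        if self.sex is not None and self.sex not in (0, 1):
            raise ValueError(f"sex code must be 0/1/None, got {self.sex}")
        if self.plumage is not None and self.plumage not in PLUMAGE_LEVELS:
            raise ValueError(f"unknown plumage label {self.plumage!r}")
        if self.plumage == PLUMAGE_PARADOXUS:
            # paradoxus is by definition a first-year male plumage
            if self.age is not None and self.age != AGE_YOUNG:
                raise ValueError("paradoxus plumage implies a young bird")
            if self.sex is not None and self.sex != SEX_MALE:
                raise ValueError("paradoxus plumage implies a male")

    @property
    def g(self) -> int:
        """Age-sex class of the record (requires both labels observed)."""
        return class_index(self.age, self.sex)


@dataclass
class ReadReport:
    """Validation outcome of reading a capture CSV."""

    n_read: int = 0
    n_accepted: int = 0
    n_rejected_morphometrics: int = 0
    row_errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.row_errors


@dataclass
class CaptureTable:
    """An ordered collection of capture records with season/reference conventions.

    ``frame`` uses the CSV column layout (nullable ``Int64`` for age/sex,
    string plumage with missing as NA).  ``season_midpoint_day`` anchors the
    centered day covariate and ``reference_year`` the centered year covariate.
    Shadow columns ``true_age``/``true_sex`` may be present on synthetic
    tables for evaluation; they are never used by the model.
    """

    frame: pd.DataFrame
    season_midpoint_day: int
    reference_year: int
    report: ReadReport | None = dataclasses.field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"capture table is missing columns {missing}")
        if len(self.frame):
            dmin, dmax = int(self.frame["day"].min()), int(self.frame["day"].max())
            if not (dmin <= self.season_midpoint_day <= dmax):
                raise ValueError(
                    f"season midpoint {self.season_midpoint_day} outside observed day range [{dmin}, {dmax}]"
                )
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[CaptureRecord]:
        for row in self.frame.itertuples(index=False):
            yield CaptureRecord(
                id=str(row.id),
                year=int(row.year),
                day=int(row.day),
                age=None if pd.isna(row.age) else int(row.age),
                sex=None if pd.isna(row.sex) else int(row.sex),
                weight=float(row.weight_g),
                primary=float(row.primary_mm),
                plumage=None if pd.isna(row.plumage) else str(row.plumage),
            )

    # -- model covariates -------------------------------------------------
    def centered_days(self) -> np.ndarray:
        """Day covariate: day - season midpoint (0 mid-season)."""
        return self.frame["day"].to_numpy(dtype=float) - float(self.season_midpoint_day)

    def centered_years(self) -> np.ndarray:
        """Year covariate: calendar year - reference year, in years."""
        return self.frame["year"].to_numpy(dtype=float) - float(self.reference_year)

    def observed_age(self) -> np.ndarray:
        """Age codes with -1 for unidentified."""
        return self.frame["age"].fillna(-1).to_numpy(dtype=np.int64)

    def observed_sex(self) -> np.ndarray:
        """Sex codes with -1 for unidentified."""
        return self.frame["sex"].fillna(-1).to_numpy(dtype=np.int64)

    def paradoxus(self) -> np.ndarray:
        """Boolean mask of records recorded with paradoxus plumage."""
        return (self.frame["plumage"] == PLUMAGE_PARADOXUS).fillna(False).to_numpy(dtype=bool)

    def has_missing_labels(self) -> bool:
        return bool(self.frame["age"].isna().any() or self.frame["sex"].isna().any())

    def copy(self) -> "CaptureTable":
        return CaptureTable(
            frame=self.frame.copy(),
            season_midpoint_day=self.season_midpoint_day,
            reference_year=self.reference_year,
            report=self.report,
        )


def centered_day(record: CaptureRecord, table: CaptureTable) -> float:
    """Day covariate of one record relative to the table's season midpoint."""
    return float(record.day - table.season_midpoint_day)


def corrected_day(day: float, year: int, reference_year: int, shift_per_year: float = 0.2) -> float:
    """Correct a capture day for the phenological shift of migration timing.

    With migration getting later by ``shift_per_year`` days per year while the
    capture window stays fixed, a bird caught on day d in ``year`` corresponds
    phenologically to one caught ``shift_per_year * (year - reference_year)``
    days earlier in the reference year.  E.g. 10 October 2000 maps to
    6 October relative to 1980 at the default 0.2 days/year.
    """
    if not np.all(np.isfinite(shift_per_year)):
        raise ValueError("shift_per_year must be finite")
    return day - shift_per_year * (np.asarray(year, dtype=float) - reference_year)


def _default_midpoint(days: pd.Series) -> int:
    return int(round((int(days.min()) + int(days.max())) / 2))


def _default_reference_year(years: pd.Series) -> int:
    return int(round((int(years.min()) + int(years.max())) / 2))


def read_capture_table(
    path: str | Path,
    season_midpoint_day: int | None = None,
    reference_year: int | None = None,
) -> CaptureTable:
    """Read a capture table from CSV, validating rows.

    Missing age/sex/plumage may be coded as an empty cell or ``NA``.  Rows
    without a positive numeric weight and primary length are rejected (the
    analysis is restricted to captures with complete morphometrics); the
    rejection count and any per-row errors are attached as ``table.report``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"CSV is missing mandatory columns {missing_cols}")

    report = ReadReport(n_read=len(raw))
    rows: list[dict] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rownum = i + 2  # 1-based with header
        try:
            weight = _parse_float(row.weight_g)
            primary = _parse_float(row.primary_mm)
        except ValueError as exc:
            report.row_errors.append(f"row {rownum}: {exc}")
            continue
        if weight is None or primary is None:
            report.n_rejected_morphometrics += 1
            logger.debug("row %d rejected: missing weight or primary length", rownum)
            continue
        try:
            rec = CaptureRecord(
                id=str(row.id),
                year=_parse_int(row.year, "year"),
                day=_parse_int(row.day, "day"),
                age=_parse_label(row.age, "age"),
                sex=_parse_label(row.sex, "sex"),
                weight=weight,
                primary=primary,
                plumage=_parse_plumage(row.plumage),
            )
        except (ValueError, TypeError) as exc:
            report.row_errors.append(f"row {rownum}: {exc}")
            continue
        rows.append(
            dict(
                id=rec.id,
                year=rec.year,
                day=rec.day,
                age=rec.age,
                sex=rec.sex,
                weight_g=rec.weight,
                primary_mm=rec.primary,
                plumage=rec.plumage,
            )
        )
    report.n_accepted = len(rows)
    if report.n_rejected_morphometrics:
        logger.info(
            "rejected %d of %d rows lacking weight or primary length",
            report.n_rejected_morphometrics,
            report.n_read,
        )
    if not rows:
        raise ValueError(f"no valid capture records in {path}")
    frame = _records_frame(rows)
    return CaptureTable(
        frame=frame,
        season_midpoint_day=(
            season_midpoint_day if season_midpoint_day is not None else _default_midpoint(frame["day"])
        ),
        reference_year=(
            reference_year if reference_year is not None else _default_reference_year(frame["year"])
        ),
        report=report,
    )


def write_capture_table(table: CaptureTable, path: str | Path) -> None:
    """Write a capture table to CSV; missing labels are written as ``NA``."""
    out = table.frame[CSV_COLUMNS].copy()
    for col in ("age", "sex"):
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="NA")


def _records_frame(rows: list[dict]) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame["id"] = frame["id"].astype(str)
    frame["year"] = frame["year"].astype(np.int64)
    frame["day"] = frame["day"].astype(np.int64)
    frame["age"] = frame["age"].astype("Int64")
    frame["sex"] = frame["sex"].astype("Int64")
    frame["weight_g"] = frame["weight_g"].astype(float)
    frame["primary_mm"] = frame["primary_mm"].astype(float)
    frame["plumage"] = frame["plumage"].astype("string")
    return frame


def table_from_records(
    records: list[CaptureRecord],
    season_midpoint_day: int | None = None,
    reference_year: int | None = None,
) -> CaptureTable:
    """Build a CaptureTable from record objects (mainly for tests and small examples)."""
    rows = [
        dict(
            id=r.id,
            year=r.year,
            day=r.day,
            age=r.age,
            sex=r.sex,
            weight_g=r.weight,
            primary_mm=r.primary,
            plumage=r.plumage,
        )
        for r in records
    ]
    frame = _records_frame(rows)
    return CaptureTable(
        frame=frame,
        season_midpoint_day=(
            season_midpoint_day if season_midpoint_day is not None else _default_midpoint(frame["day"])
        ),
        reference_year=(
            reference_year if reference_year is not None else _default_reference_year(frame["year"])
        ),
    )


def _is_na(token: str) -> bool:
    return token.strip() in ("", "NA")


def _parse_float(token: str) -> float | None:
    if _is_na(token):
        return None
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"non-numeric value {token!r}") from None
    return value


def _parse_int(token: str, name: str) -> int:
    if _is_na(token):
        raise ValueError(f"{name} is mandatory")
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"non-integer {name} {token!r}") from None


def _parse_label(token: str, name: str) -> int | None:
    if _is_na(token):
        return None
    try:
        code = int(token)
    except ValueError:
        raise ValueError(f"out-of-domain {name} code {token!r}") from None
    if code not in (0, 1):
        raise ValueError(f"out-of-domain {name} code {code}")
    return code


def _parse_plumage(token: str) -> str | None:
    if _is_na(token):
        return None
    value = token.strip()
    if value not in PLUMAGE_LEVELS:
        raise ValueError(f"unknown plumage label {value!r}")
    return value
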