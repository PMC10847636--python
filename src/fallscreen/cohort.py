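"""Domain types, validation and CSV round-trip for patient cohorts.

A cohort is one row per patient: demographics, diagnosis, FIM motor and
cognitive subscores, the SIDE static-balance level, the three bedside
adherence items, the fall-within-14-days outcome, and (for fallers) the
management-method category of the fall.

All enumerations serialise to lower-case string tokens ("2a",
"not_testable", "positive", "c1", ...) so that a written cohort reads back
field-for-field identical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "SideLevel",
    "ItemResult",
    "Personality",
    "AdherenceItemResult",
    "Sex",
    "Diagnosis",
    "ManagementCategory",
    "PatientRecord",
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "RowError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]


class SideLevel(enum.Enum):
    """SIDE static standing-balance level.

    The six testable levels are totally ordered by difficulty,
    L0 < L1 < L2A < L2B < L3 < L4; ``NOT_TESTABLE`` (e.g. weight bearing
    prohibited) is unordered relative to all of them and comparing it
    raises ``ValueError``.
    """

    L0 = "0"
    L1 = "1"
    L2A = "2a"
    L2B = "2b"
    L3 = "3"
    L4 = "4"
    NOT_TESTABLE = "not_testable"

    @property
    def testable(self) -> bool:
        return self is not SideLevel.NOT_TESTABLE

    @property
    def rank(self) -> int:
        """Position in the difficulty order; undefined for NOT_TESTABLE."""
        if not self.testable:
            raise ValueError("NOT_TESTABLE has no rank in the SIDE ordering")
        return _SIDE_RANK[self]

    def __lt__(self, other: "SideLevel") -> bool:
        if not isinstance(other, SideLevel):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "SideLevel") -> bool:
        if not isinstance(other, SideLevel):
            return NotImplemented
        return self.rank <= other.rank

    def __gt__(self, other: "SideLevel") -> bool:
        if not isinstance(other, SideLevel):
            return NotImplemented
        return self.rank > other.rank

    def __ge__(self, other: "SideLevel") -> bool:
        if not isinstance(other, SideLevel):
            return NotImplemented
        return self.rank >= other.rank


TESTABLE_LEVELS: tuple[SideLevel, ...] = (
    SideLevel.L0,
    SideLevel.L1,
    SideLevel.L2A,
    SideLevel.L2B,
    SideLevel.L3,
    SideLevel.L4,
)
_SIDE_RANK = {lvl: i for i, lvl in enumerate(TESTABLE_LEVELS)}


class ItemResult(enum.Enum):
    """Outcome of a dichotomous adherence item; POSITIVE is the at-risk pole."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


class Personality(enum.Enum):
    """Family-interview personality characterisation.

    IMPATIENT is the at-risk pole and is what the contingency reports count
    as "positive"; RESERVED is "negative".
    """

    RESERVED = "reserved"
    IMPATIENT = "impatient"
    MISSING = "missing"


@dataclass(frozen=True)
class AdherenceItemResult:
    """Results of the three bedside adherence items.

    ``memory_instruction`` is the item that asks the patient to inform the
    nursing station when testing ends; POSITIVE (could not follow/retain the
    instruction) is the at-risk result used by the screening rules.
    """

    personality: Personality = Personality.MISSING
    memory_instruction: ItemResult = ItemResult.MISSING
    impulsiveness: ItemResult = ItemResult.MISSING


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Diagnosis(enum.Enum):
    FEMORAL_NECK_FRACTURE = "femoral_neck_fracture"
    CEREBRAL_HEMORRHAGE = "cerebral_hemorrhage"
    CEREBRAL_INFARCTION = "cerebral_infarction"
    SPINAL_CORD_INJURY = "spinal_cord_injury"
    VERTEBRAL_COMPRESSION_FRACTURE = "vertebral_compression_fracture"
    OTHER = "other"


class ManagementCategory(enum.Enum):
    """Management-method classification of a fall (terminals 1-5).

    ``NONE`` is reserved for patients who did not fall.
    """

    C1_SENSOR_RESTRAINT = "c1"
    C2_NO_SENSOR_RESTRAINT = "c2"
    C3_SUPERVISED = "c3"
    C4_SUPERVISOR_LEFT = "c4"
    C5_PERMITTED_ALONE = "c5"
    NONE = "none"


FALL_CATEGORIES: tuple[ManagementCategory, ...] = (
    ManagementCategory.C1_SENSOR_RESTRAINT,
    ManagementCategory.C2_NO_SENSOR_RESTRAINT,
    ManagementCategory.C3_SUPERVISED,
    ManagementCategory.C4_SUPERVISOR_LEFT,
    ManagementCategory.C5_PERMITTED_ALONE,
)

# FIM bounds: 13 motor items and 5 cognitive items, each scored 1-7.
FIM_MOTOR_RANGE = (13, 91)
FIM_COGNITIVE_RANGE = (5, 35)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: int
    sex: Sex
    diagnosis: Diagnosis
    fim_motor: int
    fim_cognitive: int
    side: SideLevel
    adherence: AdherenceItemResult
    fell_within_14d: bool
    management: ManagementCategory = ManagementCategory.NONE

    def validation_errors(self) -> list[str]:
        """Machine-readable reasons this record violates a type invariant."""
        errs: list[str] = []
        if not self.id:
            errs.append("id: empty")
        if self.age < 0:
            errs.append(f"age: negative ({self.age})")
        lo, hi = FIM_MOTOR_RANGE
        if not lo <= self.fim_motor <= hi:
            errs.append(f"fim_motor: {self.fim_motor} outside [{lo}, {hi}]")
        lo, hi = FIM_COGNITIVE_RANGE
        if not lo <= self.fim_cognitive <= hi:
            errs.append(f"fim_cognitive: {self.fim_cognitive} outside [{lo}, {hi}]")
        has_category = self.management is not ManagementCategory.NONE
        if has_category != self.fell_within_14d:
            errs.append(
                "management: category must be NONE exactly when "
                f"fell_within_14d is false (got {self.management.value!r}, "
                f"fell={self.fell_within_14d})"
            )
        return errs


@dataclass(frozen=True)
class RowError:
    """One row-level parse or validation failure."""

    row: int  # 1-based data-row number (header excluded)
    column: str
    token: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, column {self.column!r}: {self.message} (got {self.token!r})"


class CohortValidationError(ValueError):
    """Raised when one or more rows/records fail validation."""

    def __init__(self, errors: Sequence[RowError | str]):
        self.errors = list(errors)
        super().__init__("; ".join(str(e) for e in self.errors))


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of patient records with unique ids."""

    records: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        errs: list[str] = []
        seen: set[str] = set()
        for i, rec in enumerate(self.records):
            if rec.id in seen:
                errs.append(f"record {i}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            errs.extend(f"record {rec.id!r}: {e}" for e in rec.validation_errors())
        if errs:
            raise CohortValidationError(errs)

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord]) -> "Cohort":
        return cls(tuple(records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def by_id(self) -> dict[str, PatientRecord]:
        return {r.id: r for r in self.records}

    @property
    def fallers(self) -> tuple[PatientRecord, ...]:
        return tuple(r for r in self.records if r.fell_within_14d)

    @property
    def non_fallers(self) -> tuple[PatientRecord, ...]:
        return tuple(r for r in self.records if not r.fell_within_14d)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

#: Canonical column order; a ``schema`` mapping may rename any of them.
COLUMNS: tuple[str, ...] = (
    "id",
    "age",
    "sex",
    "diagnosis",
    "fim_motor",
    "fim_cognitive",
    "side",
    "personality",
    "memory_instruction",
    "impulsiveness",
    "fell_within_14d",
    "management",
)

_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False}


def _parse_enum(enum_cls, token: str):
    try:
        return enum_cls(token)
    except ValueError:
        raise ValueError(
            f"invalid token for {enum_cls.__name__}; expected one of "
            f"{sorted(m.value for m in enum_cls)}"
        ) from None


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort CSV and return a validated :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping of canonical field name -> actual column name,
        for files whose headers differ from :data:`COLUMNS`.

    Raises
    ------
    CohortValidationError
        Listing every malformed row (row number, column, offending token)
        and any duplicate ids.
    """
    colmap = {f: f for f in COLUMNS}
    if schema:
        unknown = set(schema) - set(COLUMNS)
        if unknown:
            raise ValueError(f"schema maps unknown fields: {sorted(unknown)}")
        colmap.update(schema)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(
            [f"missing required columns: {missing_cols}"]
        )

    errors: list[RowError] = []
    records: list[PatientRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))

        def get(fieldname: str) -> str:
            return str(rowd[colmap[fieldname]]).strip()

        def enum_field(fieldname: str, enum_cls):
            token = get(fieldname)
            try:
                return _parse_enum(enum_cls, token)
            except ValueError as e:
                errors.append(RowError(idx, colmap[fieldname], token, str(e)))
                return None

        def int_field(fieldname: str):
            token = get(fieldname)
            try:
                return int(token)
            except ValueError:
                errors.append(
                    RowError(idx, colmap[fieldname], token, "not an integer")
                )
                return None

        fell_token = get("fell_within_14d").lower()
        fell = _BOOL_TOKENS.get(fell_token)
        if fell is None:
            errors.append(
                RowError(
                    idx,
                    colmap["fell_within_14d"],
                    fell_token,
                    "not a boolean (use 0/1)",
                )
            )

        parsed = dict(
            id=get("id"),
            age=int_field("age"),
            sex=enum_field("sex", Sex),
            diagnosis=enum_field("diagnosis", Diagnosis),
            fim_motor=int_field("fim_motor"),
            fim_cognitive=int_field("fim_cognitive"),
            side=enum_field("side", SideLevel),
            personality=enum_field("personality", Personality),
            memory_instruction=enum_field("memory_instruction", ItemResult),
            impulsiveness=enum_field("impulsiveness", ItemResult),
            management=enum_field("management", ManagementCategory),
        )
        if fell is None or any(v is None for v in parsed.values()):
            continue
        records.append(
            PatientRecord(
                id=parsed["id"],
                age=parsed["age"],
                sex=parsed["sex"],
                diagnosis=parsed["diagnosis"],
                fim_motor=parsed["fim_motor"],
                fim_cognitive=parsed["fim_cognitive"],
                side=parsed["side"],
                adherence=AdherenceItemResult(
                    personality=parsed["personality"],
                    memory_instruction=parsed["memory_instruction"],
                    impulsiveness=parsed["impulsiveness"],
                ),
                fell_within_14d=fell,
                management=parsed["management"],
            )
        )

    if errors:
        raise CohortValidationError(errors)
    return Cohort.from_records(records)


def to_dataframe(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a tidy DataFrame with canonical string tokens."""
    rows = [
        {
            "id": r.id,
            "age": r.age,
            "sex": r.sex.value,
            "diagnosis": r.diagnosis.value,
            "fim_motor": r.fim_motor,
            "fim_cognitive": r.fim_cognitive,
            "side": r.side.value,
            "personality": r.adherence.personality.value,
            "memory_instruction": r.adherence.memory_instruction.value,
            "impulsiveness": r.adherence.impulsiveness.value,
            "fell_within_14d": int(r.fell_within_14d),
            "management": r.management.value,
        }
        for r in cohort
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV such that :func:`read_cohort` round-trips exactly."""
    to_dataframe(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    """Background summary: counts by sex and diagnosis, moments of covariates.

    ``numeric`` has rows age/fim_motor/fim_cognitive and columns
    mean/sd/min/max; the SD is the sample standard deviation (n-1
    denominator) and is NaN for a single observation.
    """

    n: int
    sex_counts: dict[Sex, int]
    diagnosis_counts: dict[Diagnosis, int]
    numeric: pd.DataFrame


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = to_dataframe(cohort)
    sex_counts = {s: int((df["sex"] == s.value).sum()) for s in Sex}
    dx_counts = {d: int((df["diagnosis"] == d.value).sum()) for d in Diagnosis}
    num = df[["age", "fim_motor", "fim_cognitive"]].astype(float)
    numeric = pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
        }
    )
    return CohortSummary(
        n=len(cohort),
        sex_counts=sex_counts,
        diagnosis_counts=dx_counts,
        numeric=numeric,
    )
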