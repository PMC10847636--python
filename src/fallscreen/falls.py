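"""Fall-case classification by management method and per-category
memory-item positivity rates.

Each fall is classified by the supervision/restraint context at the time it
occurred.  The decision structure first asks whether the patient's action
was permitted; non-permitted actions split on whether a sensor or restraint
was in place (C1/C2), and permitted actions split on supervision: supervised
or assisted (C3), supervisor left the scene (C4), or the patient was allowed
to act alone (C5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .cohort import (
    Cohort,
    FALL_CATEGORIES,
    ItemResult,
    ManagementCategory,
    PatientRecord,
)
from .rounding import round_half_up

__all__ = [
    "CategoryPositivityRow",
    "IncoherentFlagsError",
    "positivity_by_category",
    "positivity_table",
    "validate_category_assignment",
]


@dataclass(frozen=True)
class CategoryPositivityRow:
    """Falls and memory-item positives in one management category.

    ``rate`` is 100 * n_positive / n_falls rounded half-up to 1 decimal,
    or None for an empty category.
    """

    category: ManagementCategory | None  # None marks the total row
    n_falls: int
    n_positive: int
    rate: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_falls:
            raise ValueError(
                f"n_positive ({self.n_positive}) outside [0, n_falls={self.n_falls}]"
            )


def _row(category: ManagementCategory | None, falls: list[PatientRecord]) -> CategoryPositivityRow:
    n = len(falls)
    n_pos = sum(
        1 for r in falls if r.adherence.memory_instruction is ItemResult.POSITIVE
    )
    rate = round_half_up(100.0 * n_pos / n, 1) if n else None
    return CategoryPositivityRow(category, n, n_pos, rate)


def positivity_by_category(cohort: Cohort) -> list[CategoryPositivityRow]:
    """One row per management category C1..C5 plus a total row over all fallers.

    Every faller must carry a non-NONE category (enforced by record
    validation; re-checked here with ids listed).  A faller whose memory
    item is missing counts in ``n_falls`` but not in ``n_positive``; a
    warning is emitted because the rate then undercounts.
    """
    fallers = list(cohort.fallers)
    bad = [r.id for r in fallers if r.management is ManagementCategory.NONE]
    if bad:
        raise ValueError(f"fallers without a management category: {bad}")
    missing = [
        r.id for r in fallers if r.adherence.memory_instruction is ItemResult.MISSING
    ]
    if missing:
        warnings.warn(
            "fallers with a missing memory item counted as non-positive: "
            f"{missing}",
            stacklevel=2,
        )
    rows = [
        _row(cat, [r for r in fallers if r.management is cat])
        for cat in FALL_CATEGORIES
    ]
    rows.append(_row(None, fallers))
    return rows


def positivity_table(cohort: Cohort) -> pd.DataFrame:
    """The category-positivity breakdown as a DataFrame (total row last)."""
    rows = positivity_by_category(cohort)
    return pd.DataFrame(
        {
            "category": [r.category.value if r.category else "total" for r in rows],
            "n_falls": [r.n_falls for r in rows],
            "n_positive": [r.n_positive for r in rows],
            "rate_pct": [r.rate for r in rows],
        }
    )


class IncoherentFlagsError(ValueError):
    """The supervision/restraint flags do not form one coherent path."""


def validate_category_assignment(
    record: PatientRecord,
    *,
    action_permitted: bool,
    sensor_or_restraint: bool = False,
    supervised: bool = False,
    supervisor_left: bool = False,
    permitted_alone: bool = False,
) -> ManagementCategory:
    """Map the circumstances of a fall onto a management category.

    Exactly one terminal must be reachable: non-permitted actions resolve by
    ``sensor_or_restraint`` (C1 when present, C2 when absent); permitted
    actions require exactly one of ``supervised``/``supervisor_left``/
    ``permitted_alone``.  Any other flag combination raises
    :class:`IncoherentFlagsError`.
    """
    supervision_flags = (supervised, supervisor_left, permitted_alone)
    if not action_permitted:
        if any(supervision_flags):
            raise IncoherentFlagsError(
                f"record {record.id!r}: supervision flags set on a "
                "non-permitted action"
            )
        return (
            ManagementCategory.C1_SENSOR_RESTRAINT
            if sensor_or_restraint
            else ManagementCategory.C2_NO_SENSOR_RESTRAINT
        )
    if sensor_or_restraint:
        raise IncoherentFlagsError(
            f"record {record.id!r}: sensor_or_restraint set on a permitted action"
        )
    if sum(supervision_flags) != 1:
        raise IncoherentFlagsError(
            f"record {record.id!r}: permitted action must set exactly one of "
            "supervised/supervisor_left/permitted_alone "
            f"(got {supervision_flags})"
        )
    if supervised:
        return ManagementCategory.C3_SUPERVISED
    if supervisor_left:
        return ManagementCategory.C4_SUPERVISOR_LEFT
    return ManagementCategory.C5_PERMITTED_ALONE
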