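"""Dichotomizing screening rules for early fall risk.

Three predictors are supported:

* ``SIDE_ONLY`` — risk-positive when the SIDE level falls at or below an
  ordinal cutoff boundary (default 2a/2b, i.e. levels 0-2a positive).
* ``ADHERENCE_ONLY`` — risk-positive when the memory-and-instruction
  adherence item is positive.
* ``COMBINED`` — a two-stage sequential rule: patients with good balance
  (SIDE 3-4 by default) are classified negative outright; the remaining
  poor-balance patients (SIDE 0-2b) are classified by the memory item.

Patients whose required inputs are missing (SIDE not testable, memory item
missing) are EXCLUDED with a reason rather than silently dropped; the
combined rule excludes the union of both missingness sets.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass

from .cohort import (
    Cohort,
    ItemResult,
    PatientRecord,
    SideLevel,
    TESTABLE_LEVELS,
)

__all__ = [
    "SideCutoff",
    "Classification",
    "Rule",
    "ExclusionReason",
    "ScreeningResult",
    "classify_side",
    "classify_adherence",
    "classify_combined",
    "apply_rule",
    "exclusion_counts",
    "DEFAULT_SIDE_CUTOFF",
    "DEFAULT_COMBINED_BOUNDARY",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SideCutoff:
    """An adjacent-pair boundary on the ordinal SIDE scale.

    ``lower`` is the left side of the boundary: levels <= ``lower`` are
    risk-positive.  Valid boundaries are the five adjacent pairs 0|1,
    1|2a, 2a|2b, 2b|3 and 3|4.
    """

    lower: SideLevel

    def __post_init__(self) -> None:
        if not self.lower.testable or self.lower is SideLevel.L4:
            raise ValueError(
                f"cutoff lower boundary must be one of L0..L3, got {self.lower}"
            )

    @property
    def upper(self) -> SideLevel:
        return TESTABLE_LEVELS[self.lower.rank + 1]

    @classmethod
    def parse(cls, token: str) -> "SideCutoff":
        """Parse "2a/2b"-style notation (lower/upper adjacent pair)."""
        try:
            lo_tok, hi_tok = token.split("/")
            lo, hi = SideLevel(lo_tok.strip()), SideLevel(hi_tok.strip())
        except ValueError:
            raise ValueError(f"malformed cutoff {token!r}; expected e.g. '2a/2b'") from None
        cut = cls(lo)
        if cut.upper is not hi:
            raise ValueError(f"{token!r} is not an adjacent SIDE pair")
        return cut

    def __str__(self) -> str:
        return f"{self.lower.value}/{self.upper.value}"

    def is_positive(self, level: SideLevel) -> bool:
        return level <= self.lower


ALL_CUTOFFS: tuple[SideCutoff, ...] = tuple(
    SideCutoff(lvl) for lvl in TESTABLE_LEVELS[:-1]
)

DEFAULT_SIDE_CUTOFF = SideCutoff(SideLevel.L2A)  # 2a/2b
DEFAULT_COMBINED_BOUNDARY = SideCutoff(SideLevel.L2B)  # 2b/3


class Classification(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


class Rule(enum.Enum):
    SIDE_ONLY = "side"
    ADHERENCE_ONLY = "adherence"
    COMBINED = "combined"


class ExclusionReason(enum.Enum):
    NONE = "none"
    SIDE_MISSING = "side_missing"
    ADHERENCE_MISSING = "adherence_missing"
    BOTH_MISSING = "both_missing"


@dataclass(frozen=True)
class ScreeningResult:
    patient_id: str
    classification: Classification
    rule: Rule
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        excluded = self.classification is Classification.EXCLUDED
        has_reason = self.exclusion_reason is not ExclusionReason.NONE
        if excluded != has_reason:
            raise ValueError(
                "EXCLUDED iff exclusion_reason != NONE "
                f"(got {self.classification}, {self.exclusion_reason})"
            )


def classify_side(
    record: PatientRecord, cutoff: SideCutoff = DEFAULT_SIDE_CUTOFF
) -> ScreeningResult:
    """SIDE-only dichotomization at an ordinal cutoff."""
    if record.side is SideLevel.NOT_TESTABLE:
        return ScreeningResult(
            record.id, Classification.EXCLUDED, Rule.SIDE_ONLY, ExclusionReason.SIDE_MISSING
        )
    cls = (
        Classification.POSITIVE
        if cutoff.is_positive(record.side)
        else Classification.NEGATIVE
    )
    return ScreeningResult(record.id, cls, Rule.SIDE_ONLY)


def classify_adherence(record: PatientRecord) -> ScreeningResult:
    """Memory-and-instruction adherence item as the sole predictor."""
    mi = record.adherence.memory_instruction
    if mi is ItemResult.MISSING:
        return ScreeningResult(
            record.id,
            Classification.EXCLUDED,
            Rule.ADHERENCE_ONLY,
            ExclusionReason.ADHERENCE_MISSING,
        )
    cls = (
        Classification.POSITIVE if mi is ItemResult.POSITIVE else Classification.NEGATIVE
    )
    return ScreeningResult(record.id, cls, Rule.ADHERENCE_ONLY)


def classify_combined(
    record: PatientRecord,
    balance_boundary: SideCutoff = DEFAULT_COMBINED_BOUNDARY,
) -> ScreeningResult:
    """Two-stage rule: good balance -> negative, else the memory item decides.

    Records missing either input are excluded (with BOTH_MISSING when both
    are absent); a not-testable SIDE is never routed through the adherence
    stage.
    """
    side_missing = record.side is SideLevel.NOT_TESTABLE
    mi = record.adherence.memory_instruction
    adh_missing = mi is ItemResult.MISSING
    if side_missing or adh_missing:
        reason = (
            ExclusionReason.BOTH_MISSING
            if side_missing and adh_missing
            else ExclusionReason.SIDE_MISSING
            if side_missing
            else ExclusionReason.ADHERENCE_MISSING
        )
        return ScreeningResult(record.id, Classification.EXCLUDED, Rule.COMBINED, reason)
    if not balance_boundary.is_positive(record.side):
        return ScreeningResult(record.id, Classification.NEGATIVE, Rule.COMBINED)
    cls = (
        Classification.POSITIVE if mi is ItemResult.POSITIVE else Classification.NEGATIVE
    )
    return ScreeningResult(record.id, cls, Rule.COMBINED)


def apply_rule(
    cohort: Cohort,
    rule: Rule,
    *,
    cutoff: SideCutoff = DEFAULT_SIDE_CUTOFF,
    balance_boundary: SideCutoff = DEFAULT_COMBINED_BOUNDARY,
) -> list[ScreeningResult]:
    """Classify every record in the cohort under one rule.

    Exclusion counts by reason are logged at INFO level.
    """
    if rule is Rule.SIDE_ONLY:
        results = [classify_side(r, cutoff) for r in cohort]
    elif rule is Rule.ADHERENCE_ONLY:
        results = [classify_adherence(r) for r in cohort]
    elif rule is Rule.COMBINED:
        results = [classify_combined(r, balance_boundary) for r in cohort]
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown rule {rule!r}")
    counts = exclusion_counts(results)
    logger.info(
        "rule=%s: %d records, %d excluded (%s)",
        rule.value,
        len(results),
        sum(counts.values()),
        ", ".join(f"{k.value}={v}" for k, v in counts.items()) or "none",
    )
    return results


def exclusion_counts(results: list[ScreeningResult]) -> Counter:
    """Counts of excluded results by reason (NONE omitted)."""
    return Counter(
        r.exclusion_reason
        for r in results
        if r.exclusion_reason is not ExclusionReason.NONE
    )
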