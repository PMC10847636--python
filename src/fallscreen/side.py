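"""SIDE level assignment from raw sub-test outcomes.

The SIDE (Standing Test for Imbalance and Disequilibrium) grades static
standing balance through a fixed sequence of progressively harder stances:
wide-base stand, narrow-base stand held >5 s, tandem stance held >5 s with
each leg leading, and single-leg stance held >30 s on each leg.  Testing
stops at the first stance the patient cannot maintain, so a structurally
valid outcome never contains attempted results after a terminating failure.

Level semantics:

========  =====================================================
L0        wide-base stand cannot be maintained without help
L1        wide base OK, narrow base < 5 s
L2A       narrow base OK, tandem fails with both leading legs
L2B       tandem held with exactly one leading leg
L3        tandem held with both legs, single-leg < 30 s (at
          least one leg)
L4        single-leg stance >= 30 s on both legs
========  =====================================================

A patient for whom no sub-test was attempted (e.g. weight bearing
prohibited) is NOT_TESTABLE.  Assigning L4 requires success on *both* legs;
a single-leg split (one pass, one fail) stays at L3, mirroring the explicit
L2B/L3 tandem distinction and taking the conservative lower level.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .cohort import SideLevel

__all__ = [
    "SubTestResult",
    "SideTestOutcome",
    "SideStructureError",
    "determine_side_level",
    "enumerate_level_map",
    "assign_levels_csv",
]


class SubTestResult(enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_ATTEMPTED = "not_attempted"


@dataclass(frozen=True)
class SideTestOutcome:
    """Raw pass/fail outcomes of the six SIDE sub-tests."""

    wide_base_stand: SubTestResult
    narrow_base_5s: SubTestResult
    tandem_5s_left_front: SubTestResult
    tandem_5s_right_front: SubTestResult
    single_leg_30s_left: SubTestResult
    single_leg_30s_right: SubTestResult

    def as_tuple(self) -> tuple[SubTestResult, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))


FIELD_NAMES: tuple[str, ...] = tuple(f.name for f in fields(SideTestOutcome))


class SideStructureError(ValueError):
    """The outcome violates the stop-at-first-failure test structure."""

    def __init__(self, earlier: str, later: str, detail: str):
        self.inconsistent_pair = (earlier, later)
        super().__init__(f"inconsistent sub-tests ({earlier}, {later}): {detail}")


_P = SubTestResult.PASS
_F = SubTestResult.FAIL
_NA = SubTestResult.NOT_ATTEMPTED


def _check_structure(o: SideTestOutcome) -> None:
    """Raise SideStructureError naming the first inconsistent pair."""
    if all(r is _NA for r in o.as_tuple()):
        return  # untestable patient

    tandem = (o.tandem_5s_left_front, o.tandem_5s_right_front)
    single = (o.single_leg_30s_left, o.single_leg_30s_right)

    def require_not_attempted(earlier: str, names: tuple[str, ...]) -> None:
        for name in names:
            if getattr(o, name) is not _NA:
                raise SideStructureError(
                    earlier, name, f"{name} recorded after failure at {earlier}"
                )

    if o.wide_base_stand is _NA:
        raise SideStructureError(
            "wide_base_stand",
            "narrow_base_5s",
            "later sub-tests recorded but the wide-base stand was never attempted",
        )
    if o.wide_base_stand is _F:
        require_not_attempted("wide_base_stand", FIELD_NAMES[1:])
        return

    # wide base passed: narrow base must have been attempted
    if o.narrow_base_5s is _NA:
        raise SideStructureError(
            "wide_base_stand",
            "narrow_base_5s",
            "narrow-base stand not attempted after a wide-base pass",
        )
    if o.narrow_base_5s is _F:
        require_not_attempted("narrow_base_5s", FIELD_NAMES[2:])
        return

    # narrow base passed: both tandem trials must have been attempted
    for name, res in zip(FIELD_NAMES[2:4], tandem):
        if res is _NA:
            raise SideStructureError(
                "narrow_base_5s", name, f"{name} not attempted after a narrow-base pass"
            )
    if _F in tandem:
        # fewer than two tandem passes: testing stops before single-leg
        failed = FIELD_NAMES[2] if tandem[0] is _F else FIELD_NAMES[3]
        require_not_attempted(failed, FIELD_NAMES[4:])
        return

    # both tandem passed: both single-leg trials must have been attempted
    for name, res in zip(FIELD_NAMES[4:], single):
        if res is _NA:
            raise SideStructureError(
                FIELD_NAMES[3], name, f"{name} not attempted after tandem passes"
            )


def determine_side_level(outcome: SideTestOutcome) -> SideLevel:
    """Assign the SIDE level for a structurally valid sub-test outcome.

    Raises
    ------
    SideStructureError
        If the outcome violates the stop-at-first-failure structure; the
        error names the inconsistent pair of sub-tests.
    """
    _check_structure(outcome)
    t = outcome.as_tuple()
    if all(r is _NA for r in t):
        return SideLevel.NOT_TESTABLE
    if outcome.wide_base_stand is _F:
        return SideLevel.L0
    if outcome.narrow_base_5s is _F:
        return SideLevel.L1
    n_tandem = sum(
        r is _P for r in (outcome.tandem_5s_left_front, outcome.tandem_5s_right_front)
    )
    if n_tandem == 0:
        return SideLevel.L2A
    if n_tandem == 1:
        return SideLevel.L2B
    n_single = sum(
        r is _P for r in (outcome.single_leg_30s_left, outcome.single_leg_30s_right)
    )
    return SideLevel.L4 if n_single == 2 else SideLevel.L3


def enumerate_level_map() -> list[tuple[SideTestOutcome, SideLevel]]:
    """All structurally valid outcomes with their assigned levels.

    Serves as a test oracle: the valid outcomes partition into the seven
    levels (six testable + NOT_TESTABLE), each outcome mapping to exactly
    one.
    """
    out: list[tuple[SideTestOutcome, SideLevel]] = []
    for combo in itertools.product(SubTestResult, repeat=len(FIELD_NAMES)):
        outcome = SideTestOutcome(*combo)
        try:
            level = determine_side_level(outcome)
        except SideStructureError:
            continue
        out.append((outcome, level))
    return out


def assign_levels_csv(path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Read raw sub-test outcomes from CSV and append a ``side`` column.

    The input must have the six sub-test columns named after
    :data:`FIELD_NAMES` with tokens pass/fail/not_attempted.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FIELD_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"missing sub-test columns: {missing}")
    levels = []
    for _, row in df.iterrows():
        outcome = SideTestOutcome(
            *(SubTestResult(row[c].strip()) for c in FIELD_NAMES)
        )
        levels.append(determine_side_level(outcome).value)
    df = df.copy()
    df["side"] = levels
    df.to_csv(out_path, index=False)
    return df
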