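"""Diagnostic accuracy: 2x2 tables, sensitivity/specificity/Youden, Fisher
exact tests, and Youden-maximizing cutoff search on the ordinal SIDE scale.

Sensitivity is the proportion of fallers classified risk-positive and
specificity the proportion of non-fallers classified negative, both over
the analyzable (non-excluded) set.  The Youden index J = sensitivity +
specificity - 1 summarises a dichotomization in [-1, 1]; the cutoff search
picks the adjacent SIDE boundary maximizing J.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .cohort import Cohort
from .rounding import round_half_up
from .screening import (
    ALL_CUTOFFS,
    Classification,
    Rule,
    ScreeningResult,
    SideCutoff,
    apply_rule,
)

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticMetrics",
    "build_table",
    "compute_metrics",
    "fisher_exact_two_sided",
    "optimize_cutoff",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a dichotomized predictor against fall outcome.

    tp: positive fallers, fn: negative fallers, fp: positive non-fallers,
    tn: negative non-fallers.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Unrounded sensitivity/specificity/Youden over the analyzed set."""

    sensitivity: float
    specificity: float
    youden: float
    n_analyzed: int

    def rounded(self, ndigits: int = 2) -> "DiagnosticMetrics":
        """Reporting-layer copy with half-up rounding applied."""
        return DiagnosticMetrics(
            sensitivity=round_half_up(self.sensitivity, ndigits),
            specificity=round_half_up(self.specificity, ndigits),
            youden=round_half_up(self.youden, ndigits),
            n_analyzed=self.n_analyzed,
        )


def build_table(results: list[ScreeningResult], cohort: Cohort) -> ContingencyTable2x2:
    """Cross-tabulate screening results against the fall outcome.

    Excluded results contribute to no cell.  Raises ``KeyError`` if a
    non-excluded result's patient id is not in the cohort.
    """
    outcome = {r.id: r.fell_within_14d for r in cohort}
    tp = fn = fp = tn = 0
    for res in results:
        if res.classification is Classification.EXCLUDED:
            continue
        if res.patient_id not in outcome:
            raise KeyError(f"screening result for unknown patient id {res.patient_id!r}")
        fell = outcome[res.patient_id]
        pos = res.classification is Classification.POSITIVE
        if fell:
            tp, fn = (tp + 1, fn) if pos else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pos else (fp, tn + 1)
    return ContingencyTable2x2(tp=tp, fn=fn, fp=fp, tn=tn)


def compute_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """Sensitivity, specificity and Youden index of a 2x2 table.

    Raises ``ValueError`` naming the empty margin when either outcome group
    has no analyzed records.
    """
    fallers = table.tp + table.fn
    non_fallers = table.fp + table.tn
    if fallers == 0:
        raise ValueError("empty margin: no analyzed fallers (tp + fn = 0)")
    if non_fallers == 0:
        raise ValueError("empty margin: no analyzed non-fallers (fp + tn = 0)")
    sens = table.tp / fallers
    spec = table.tn / non_fallers
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        n_analyzed=table.total,
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the point-probability (minimum-likelihood) convention: p is the
    sum of hypergeometric probabilities, over tables with the observed
    margins, no greater than that of the observed table.
    """
    return float(
        _scipy_fisher([[table.tp, table.fn], [table.fp, table.tn]]).pvalue
    )


def optimize_cutoff(
    cohort: Cohort,
) -> tuple[SideCutoff, pd.DataFrame]:
    """Evaluate all five adjacent SIDE cutoffs and pick the Youden-maximal one.

    Not-testable records are excluded throughout.  Ties are broken toward
    higher sensitivity (the screening context favours catching fallers),
    then toward the lower boundary.

    Returns the best cutoff and a per-cutoff table with columns
    cutoff/n/sensitivity/specificity/youden (unrounded).
    """
    testable_fallers = sum(1 for r in cohort.fallers if r.side.testable)
    testable_non = sum(1 for r in cohort.non_fallers if r.side.testable)
    if testable_fallers == 0 or testable_non == 0:
        raise ValueError(
            "cutoff search needs at least one testable faller and one "
            f"testable non-faller (got {testable_fallers} and {testable_non})"
        )
    rows = []
    for cut in ALL_CUTOFFS:
        results = apply_rule(cohort, Rule.SIDE_ONLY, cutoff=cut)
        metrics = compute_metrics(build_table(results, cohort))
        rows.append(
            {
                "cutoff": str(cut),
                "n": metrics.n_analyzed,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "youden": metrics.youden,
            }
        )
    grid = pd.DataFrame(rows)
    best_idx = max(
        range(len(ALL_CUTOFFS)),
        key=lambda i: (
            grid.loc[i, "youden"],
            grid.loc[i, "sensitivity"],
            -ALL_CUTOFFS[i].lower.rank,
        ),
    )
    return ALL_CUTOFFS[best_idx], grid
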