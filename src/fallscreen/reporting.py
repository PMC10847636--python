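"""Orchestration: run the full screening analysis and emit report tables.

The report bundle mirrors the published presentation: the SIDE-by-fall
contingency table, the three adherence items by fall group, the metric
comparison of the three predictors (n, sensitivity, specificity, Youden),
the fall-management positivity breakdown, and a per-patient exclusion log.
Tables are written as CSV, the metrics bundle as JSON, so re-runs on
identical input are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    Cohort,
    ItemResult,
    Personality,
    SideLevel,
    TESTABLE_LEVELS,
    read_cohort,
)
from .diagnostics import build_table, compute_metrics
from .falls import positivity_table
from .rounding import round_half_up
from .screening import (
    Classification,
    DEFAULT_COMBINED_BOUNDARY,
    DEFAULT_SIDE_CUTOFF,
    ExclusionReason,
    Rule,
    SideCutoff,
    apply_rule,
)

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "input",
    "output_dir",
    "side_cutoff",
    "combined_balance_boundary",
    "seed",
    "verbosity",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    input: Path
    output_dir: Path
    side_cutoff: SideCutoff = DEFAULT_SIDE_CUTOFF
    combined_balance_boundary: SideCutoff = DEFAULT_COMBINED_BOUNDARY
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "input" not in doc or "output_dir" not in doc:
            raise ValueError("config requires 'input' and 'output_dir'")
        return cls(
            input=Path(doc["input"]),
            output_dir=Path(doc["output_dir"]),
            side_cutoff=SideCutoff.parse(doc.get("side_cutoff", "2a/2b")),
            combined_balance_boundary=SideCutoff.parse(
                doc.get("combined_balance_boundary", "2b/3")
            ),
            seed=int(doc.get("seed", 0)),
            verbosity=int(doc.get("verbosity", 0)),
        )


@dataclass(frozen=True)
class ReportBundle:
    side_table: pd.DataFrame
    adherence_table: pd.DataFrame
    metrics_table: pd.DataFrame
    falls_table: pd.DataFrame
    exclusion_log: pd.DataFrame
    metrics: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _side_by_fall(cohort: Cohort) -> pd.DataFrame:
    rows = []
    groups = {"fall": cohort.fallers, "no_fall": cohort.non_fallers}
    for lvl in TESTABLE_LEVELS + (SideLevel.NOT_TESTABLE,):
        row: dict = {"side": lvl.value}
        for tag, group in groups.items():
            n = sum(1 for r in group if r.side is lvl)
            row[f"{tag}_n"] = n
            row[f"{tag}_pct"] = (
                round_half_up(100.0 * n / len(group), 1) if group else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _adherence_by_fall(cohort: Cohort) -> pd.DataFrame:
    rows = []
    groups = {"fall": cohort.fallers, "no_fall": cohort.non_fallers}
    items = {
        "personality": lambda r: {
            Personality.IMPATIENT: "positive",
            Personality.RESERVED: "negative",
            Personality.MISSING: "missing",
        }[r.adherence.personality],
        "memory_instruction": lambda r: r.adherence.memory_instruction.value,
        "impulsiveness": lambda r: r.adherence.impulsiveness.value,
    }
    for item, getter in items.items():
        for result in ("positive", "negative", "missing"):
            row: dict = {"item": item, "result": result}
            for tag, group in groups.items():
                n = sum(1 for r in group if getter(r) == result)
                row[f"{tag}_n"] = n
                row[f"{tag}_pct"] = (
                    round_half_up(100.0 * n / len(group), 1) if group else None
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run all three screening rules on a cohort and write the report bundle.

    Outputs (under ``config.output_dir``): side_by_fall.csv,
    adherence_by_fall.csv, metrics.csv, falls_by_category.csv,
    exclusions.csv, metrics.json, run.log.  Deterministic given the input.
    """
    if not Path(config.input).exists():
        raise FileNotFoundError(f"input cohort not found: {config.input}")
    cohort = read_cohort(config.input)
    if len(cohort) == 0:
        raise ValueError("empty cohort: nothing to analyze")

    rules = {
        Rule.SIDE_ONLY: dict(cutoff=config.side_cutoff),
        Rule.ADHERENCE_ONLY: {},
        Rule.COMBINED: dict(balance_boundary=config.combined_balance_boundary),
    }
    metric_rows = []
    excl_rows = []
    metrics_json: dict = {"rules": {}}
    for rule, kwargs in rules.items():
        results = apply_rule(cohort, rule, **kwargs)
        table = build_table(results, cohort)
        m = compute_metrics(table)
        mr = m.rounded(2)
        metric_rows.append(
            {
                "rule": rule.value,
                "n": m.n_analyzed,
                "sensitivity": mr.sensitivity,
                "specificity": mr.specificity,
                "youden": mr.youden,
            }
        )
        metrics_json["rules"][rule.value] = {
            "n": m.n_analyzed,
            "table": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
            "sensitivity": mr.sensitivity,
            "specificity": mr.specificity,
            "youden": mr.youden,
            "sensitivity_unrounded": m.sensitivity,
            "specificity_unrounded": m.specificity,
            "youden_unrounded": m.youden,
        }
        for r in results:
            if r.classification is Classification.EXCLUDED:
                excl_rows.append(
                    {
                        "rule": rule.value,
                        "patient_id": r.patient_id,
                        "reason": r.exclusion_reason.value,
                    }
                )

    exclusion_log = pd.DataFrame(
        excl_rows, columns=["rule", "patient_id", "reason"]
    ).sort_values(["rule", "patient_id"], kind="stable").reset_index(drop=True)
    combined_excl = exclusion_log[exclusion_log["rule"] == Rule.COMBINED.value]
    metrics_json["exclusions"] = {
        "side_missing_total": int(
            combined_excl["reason"]
            .isin([ExclusionReason.SIDE_MISSING.value, ExclusionReason.BOTH_MISSING.value])
            .sum()
        ),
        "adherence_missing_total": int(
            combined_excl["reason"]
            .isin(
                [
                    ExclusionReason.ADHERENCE_MISSING.value,
                    ExclusionReason.BOTH_MISSING.value,
                ]
            )
            .sum()
        ),
        "both_missing": int(
            (combined_excl["reason"] == ExclusionReason.BOTH_MISSING.value).sum()
        ),
    }

    side_table = _side_by_fall(cohort)
    adherence_table = _adherence_by_fall(cohort)
    metrics_table = pd.DataFrame(metric_rows)
    falls_table = positivity_table(cohort)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "side_by_fall": out / "side_by_fall.csv",
        "adherence_by_fall": out / "adherence_by_fall.csv",
        "metrics_csv": out / "metrics.csv",
        "falls_by_category": out / "falls_by_category.csv",
        "exclusions": out / "exclusions.csv",
        "metrics_json": out / "metrics.json",
        "log": out / "run.log",
    }
    side_table.to_csv(paths["side_by_fall"], index=False)
    adherence_table.to_csv(paths["adherence_by_fall"], index=False)
    metrics_table.to_csv(paths["metrics_csv"], index=False)
    falls_table.to_csv(paths["falls_by_category"], index=False)
    exclusion_log.to_csv(paths["exclusions"], index=False)
    paths["metrics_json"].write_text(json.dumps(metrics_json, indent=2, sort_keys=True))
    log_lines = [
        f"records={len(cohort)} fallers={len(cohort.fallers)}",
        f"side_cutoff={config.side_cutoff} combined_boundary={config.combined_balance_boundary}",
    ] + [
        f"excluded rule={row.rule} id={row.patient_id} reason={row.reason}"
        for row in exclusion_log.itertuples(index=False)
    ]
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return ReportBundle(
        side_table=side_table,
        adherence_table=adherence_table,
        metrics_table=metrics_table,
        falls_table=falls_table,
        exclusion_log=exclusion_log,
        metrics=metrics_json,
        paths=paths,
    )
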