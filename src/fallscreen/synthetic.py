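"""Synthetic cohorts with the statistical structure the screening analysis
assumes.

Two generators are provided:

* :func:`build_fixture` — a deterministic 416-patient cohort that solves the
  integer constraint system implied by the published marginal tables: the
  SIDE-by-fall distribution, the three adherence items by fall group, the
  management-category breakdown of the 38 falls, the missing-data cascade
  (18 SIDE not testable, 14 memory item missing, 6 both), and the background
  demographics.  Joint cells that no printed margin pins down are fixed to a
  documented canonical solution, so every diagnostic metric computed from
  the fixture is an exact, reproducible number.

* :func:`sample_cohort` — a seeded stochastic sampler over the same margins
  (fall status first, then SIDE and adherence conditional on fall status,
  optionally tilted by an odds-ratio association between the poor-balance
  band and memory-item positivity) for property tests and power exploration.

The canonical joint closure, within each fall group, over (SIDE band x
memory item):

===========  =======================  ==========================
group        cell                     count
===========  =======================  ==========================
fallers      L0-2B positive           27   (of 35 testable-low)
fallers      L0-2B negative           8
fallers      L3 negative              1
fallers      not-testable positive    2
non-fallers  L0-2B positive/negative  127 / 125 (8 more missing)
non-fallers  L3-4 positive/negative   30 / 72
non-fallers  not-testable pos/neg     3 / 7   (6 more missing both)
===========  =======================  ==========================

This is the true-negative-maximal solution of the under-determined system
(227 combined-rule true negatives among 354 analyzable non-fallers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import fsolve
from scipy.stats import truncnorm

from .cohort import (
    AdherenceItemResult,
    Cohort,
    Diagnosis,
    FALL_CATEGORIES,
    FIM_COGNITIVE_RANGE,
    FIM_MOTOR_RANGE,
    ItemResult,
    ManagementCategory,
    PatientRecord,
    Personality,
    Sex,
    SideLevel,
    TESTABLE_LEVELS,
)

__all__ = [
    "CohortSpec",
    "ConstraintCheck",
    "ConstraintReport",
    "build_fixture",
    "fixture_spec",
    "sample_cohort",
    "verify_fixture",
]

# --------------------------------------------------------------------------
# Canonical fixture cell counts
# --------------------------------------------------------------------------

_L0, _L1, _L2A, _L2B, _L3, _L4 = TESTABLE_LEVELS
_NT = SideLevel.NOT_TESTABLE
_POS, _NEG, _MISS = ItemResult.POSITIVE, ItemResult.NEGATIVE, ItemResult.MISSING

# (side, memory item, count) for the 38 fallers.  Within the poor-balance
# band the 27 positives are spread near-proportionally over levels; only the
# band totals are pinned by printed numbers.
_FALLER_CELLS: tuple[tuple[SideLevel, ItemResult, int], ...] = (
    (_L0, _POS, 9), (_L0, _NEG, 3),
    (_L1, _POS, 4), (_L1, _NEG, 1),
    (_L2A, _POS, 11), (_L2A, _NEG, 3),
    (_L2B, _POS, 3), (_L2B, _NEG, 1),
    (_L3, _NEG, 1),
    (_NT, _POS, 2),
)

# (side, memory item, count) for the 378 non-fallers.
_NON_FALLER_CELLS: tuple[tuple[SideLevel, ItemResult, int], ...] = (
    (_L0, _POS, 35), (_L0, _NEG, 34), (_L0, _MISS, 3),
    (_L1, _POS, 22), (_L1, _NEG, 21), (_L1, _MISS, 2),
    (_L2A, _POS, 46), (_L2A, _NEG, 45), (_L2A, _MISS, 2),
    (_L2B, _POS, 24), (_L2B, _NEG, 25), (_L2B, _MISS, 1),
    (_L3, _POS, 23), (_L3, _NEG, 54),
    (_L4, _POS, 7), (_L4, _NEG, 18),
    (_NT, _POS, 3), (_NT, _NEG, 7), (_NT, _MISS, 6),
)

# Management categories of the 38 falls, split by the faller's memory-item
# result so the per-category positive counts come out exactly.
_CATEGORIES_FOR_POSITIVE_FALLERS: tuple[ManagementCategory, ...] = (
    (ManagementCategory.C1_SENSOR_RESTRAINT,) * 14
    + (ManagementCategory.C2_NO_SENSOR_RESTRAINT,) * 4
    + (ManagementCategory.C3_SUPERVISED,) * 7
    + (ManagementCategory.C5_PERMITTED_ALONE,) * 4
)
_CATEGORIES_FOR_NEGATIVE_FALLERS: tuple[ManagementCategory, ...] = (
    (ManagementCategory.C1_SENSOR_RESTRAINT,) * 2
    + (ManagementCategory.C2_NO_SENSOR_RESTRAINT,) * 3
    + (ManagementCategory.C4_SUPERVISOR_LEFT,) * 1
    + (ManagementCategory.C5_PERMITTED_ALONE,) * 3
)

# Remaining adherence items (no printed joint with anything else):
# counts (positive-pole, negative-pole, missing) per fall group.
_PERSONALITY_COUNTS = {True: (23, 15, 0), False: (264, 110, 4)}
_IMPULSIVENESS_COUNTS = {True: (2, 36, 0), False: (16, 345, 17)}

_SEX_COUNTS = {Sex.MALE: 154, Sex.FEMALE: 262}
_DIAGNOSIS_COUNTS = {
    Diagnosis.FEMORAL_NECK_FRACTURE: 65,
    Diagnosis.CEREBRAL_HEMORRHAGE: 49,
    Diagnosis.CEREBRAL_INFARCTION: 98,
    Diagnosis.SPINAL_CORD_INJURY: 8,
    Diagnosis.VERTEBRAL_COMPRESSION_FRACTURE: 46,
    Diagnosis.OTHER: 150,
}
_AGE_MEAN, _AGE_SD, _AGE_RANGE = 77.9, 9.6, (38, 102)
_FIM_MOTOR_MEAN, _FIM_MOTOR_SD = 49.7, 19.5
_FIM_COG_MEAN, _FIM_COG_SD = 25.5, 7.5

#: Deterministic internal stream for fixture demographics/ordering.
_FIXTURE_SEED = 416

#: Generator tolerance for matching printed moments in verify_fixture:
#: about three standard errors of a 416-sample moment estimate for the
#: widest covariate.
MOMENT_TOLERANCE = 2.5


def _truncnorm_matching(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal on [lo, hi] whose *truncated* moments are (mean, sd)."""

    def eqs(params):
        mu, s = params
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    mu, s = fsolve(eqs, [mean, sd], full_output=False)
    a, b = (lo - mu) / s, (hi - mu) / s
    return truncnorm(a, b, loc=mu, scale=s)


def _draw_int(dist, size: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    vals = np.rint(dist.rvs(size=size, random_state=rng)).astype(int)
    return np.clip(vals, lo, hi)


@dataclass(frozen=True)
class _Skeleton:
    """One record's categorical slots before demographics are attached."""

    fell: bool
    side: SideLevel
    memory: ItemResult
    management: ManagementCategory


def build_fixture() -> Cohort:
    """The deterministic 416-patient cohort solving the printed constraints.

    Calling it twice yields identical cohorts; demographics are drawn from
    a fixed internal stream and the youngest/oldest ages are pinned to the
    published range endpoints 38 and 102.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)

    skeletons: list[_Skeleton] = []
    pos_iter = iter(_CATEGORIES_FOR_POSITIVE_FALLERS)
    neg_iter = iter(_CATEGORIES_FOR_NEGATIVE_FALLERS)
    for side, memory, count in _FALLER_CELLS:
        for _ in range(count):
            cat = next(pos_iter) if memory is _POS else next(neg_iter)
            skeletons.append(_Skeleton(True, side, memory, cat))
    for side, memory, count in _NON_FALLER_CELLS:
        for _ in range(count):
            skeletons.append(_Skeleton(False, side, memory, ManagementCategory.NONE))

    # Unconstrained items, assigned within each fall group in a shuffled
    # order so they carry no accidental structure relative to SIDE.
    personality: dict[int, Personality] = {}
    impulsiveness: dict[int, ItemResult] = {}
    for fell in (True, False):
        idx = [i for i, s in enumerate(skeletons) if s.fell is fell]
        n_imp, n_res, n_pmiss = _PERSONALITY_COUNTS[fell]
        pvals = (
            [Personality.IMPATIENT] * n_imp
            + [Personality.RESERVED] * n_res
            + [Personality.MISSING] * n_pmiss
        )
        n_ipos, n_ineg, n_imiss = _IMPULSIVENESS_COUNTS[fell]
        ivals = [_POS] * n_ipos + [_NEG] * n_ineg + [_MISS] * n_imiss
        rng.shuffle(pvals)
        rng.shuffle(ivals)
        personality.update(zip(idx, pvals))
        impulsiveness.update(zip(idx, ivals))

    order = rng.permutation(len(skeletons))
    n = len(skeletons)

    sexes = [s for s, c in _SEX_COUNTS.items() for _ in range(c)]
    diagnoses = [d for d, c in _DIAGNOSIS_COUNTS.items() for _ in range(c)]
    rng.shuffle(sexes)
    rng.shuffle(diagnoses)

    age_lo, age_hi = _AGE_RANGE
    ages = _draw_int(
        _truncnorm_matching(_AGE_MEAN, _AGE_SD, age_lo, age_hi), n, age_lo, age_hi, rng
    )
    ages[0], ages[1] = age_lo, age_hi  # honour the printed range exactly
    fim_motor = _draw_int(
        _truncnorm_matching(_FIM_MOTOR_MEAN, _FIM_MOTOR_SD, *FIM_MOTOR_RANGE),
        n,
        *FIM_MOTOR_RANGE,
        rng,
    )
    fim_cog = _draw_int(
        _truncnorm_matching(_FIM_COG_MEAN, _FIM_COG_SD, *FIM_COGNITIVE_RANGE),
        n,
        *FIM_COGNITIVE_RANGE,
        rng,
    )

    records = []
    for pos, skel_idx in enumerate(order):
        s = skeletons[skel_idx]
        records.append(
            PatientRecord(
                id=f"p{pos + 1:04d}",
                age=int(ages[pos]),
                sex=sexes[pos],
                diagnosis=diagnoses[pos],
                fim_motor=int(fim_motor[pos]),
                fim_cognitive=int(fim_cog[pos]),
                side=s.side,
                adherence=AdherenceItemResult(
                    personality=personality[skel_idx],
                    memory_instruction=s.memory,
                    impulsiveness=impulsiveness[skel_idx],
                ),
                fell_within_14d=s.fell,
                management=s.management,
            )
        )
    return Cohort.from_records(records)


# --------------------------------------------------------------------------
# CohortSpec and the stochastic sampler
# --------------------------------------------------------------------------


def _count_dict(cells, key_index: int, keys) -> dict:
    out = {k: 0 for k in keys}
    for side, memory, count in cells:
        k = (side, memory)[key_index]
        out[k] += count
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Parameter set driving :func:`sample_cohort`.

    All distributions are given as per-group counts (summing to the group
    size at ``n_total``); the sampler converts them to proportions, so a
    spec may be sampled at any ``n``.  ``dependence`` in [-1, 1] tilts the
    joint of (poor-balance band) x (memory item positive) within each fall
    group by the odds ratio (1 + d) / (1 - d) while preserving both margins;
    0 means conditional independence.
    """

    n_total: int
    n_fallers: int
    side_fallers: Mapping[SideLevel, int]
    side_non_fallers: Mapping[SideLevel, int]
    memory_fallers: Mapping[ItemResult, int]
    memory_non_fallers: Mapping[ItemResult, int]
    personality_fallers: Mapping[Personality, int]
    personality_non_fallers: Mapping[Personality, int]
    impulsiveness_fallers: Mapping[ItemResult, int]
    impulsiveness_non_fallers: Mapping[ItemResult, int]
    n_missing_both: int  # non-fallers with SIDE not testable AND memory missing
    category_falls: Mapping[ManagementCategory, int]
    category_positives: Mapping[ManagementCategory, int]
    sex_counts: Mapping[Sex, int] = field(default_factory=lambda: dict(_SEX_COUNTS))
    diagnosis_counts: Mapping[Diagnosis, int] = field(
        default_factory=lambda: dict(_DIAGNOSIS_COUNTS)
    )
    age_mean: float = _AGE_MEAN
    age_sd: float = _AGE_SD
    age_range: tuple[int, int] = _AGE_RANGE
    fim_motor_mean: float = _FIM_MOTOR_MEAN
    fim_motor_sd: float = _FIM_MOTOR_SD
    fim_cognitive_mean: float = _FIM_COG_MEAN
    fim_cognitive_sd: float = _FIM_COG_SD
    seed: int = 0
    dependence: float = 0.0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated sum or bound."""
        n_non = self.n_total - self.n_fallers
        if not 0 <= self.n_fallers <= self.n_total:
            raise ValueError(
                f"n_fallers ({self.n_fallers}) outside [0, n_total={self.n_total}]"
            )
        sums = {
            "side_fallers": (self.side_fallers, self.n_fallers),
            "side_non_fallers": (self.side_non_fallers, n_non),
            "memory_fallers": (self.memory_fallers, self.n_fallers),
            "memory_non_fallers": (self.memory_non_fallers, n_non),
            "personality_fallers": (self.personality_fallers, self.n_fallers),
            "personality_non_fallers": (self.personality_non_fallers, n_non),
            "impulsiveness_fallers": (self.impulsiveness_fallers, self.n_fallers),
            "impulsiveness_non_fallers": (self.impulsiveness_non_fallers, n_non),
            "category_falls": (self.category_falls, self.n_fallers),
            "sex_counts": (self.sex_counts, self.n_total),
            "diagnosis_counts": (self.diagnosis_counts, self.n_total),
        }
        for name, (dist, expected) in sums.items():
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name}: negative count")
            got = sum(dist.values())
            if got != expected:
                raise ValueError(f"{name} sums to {got}, expected {expected}")
        for cat, n_pos in self.category_positives.items():
            n_falls = self.category_falls.get(cat, 0)
            if not 0 <= n_pos <= n_falls:
                raise ValueError(
                    f"category_positives[{cat.value}] = {n_pos} outside "
                    f"[0, {n_falls}]"
                )
        nt_non = self.side_non_fallers.get(_NT, 0)
        miss_non = self.memory_non_fallers.get(_MISS, 0)
        if not 0 <= self.n_missing_both <= min(nt_non, miss_non):
            raise ValueError(
                f"n_missing_both = {self.n_missing_both} outside "
                f"[0, min({nt_non}, {miss_non})]"
            )
        if not -1.0 <= self.dependence <= 1.0:
            raise ValueError(f"dependence {self.dependence} outside [-1, 1]")

    # -- YAML round-trip (flat token-keyed mappings) -----------------------

    def to_yaml(self, path: str | Path) -> None:
        def tokens(d: Mapping) -> dict:
            return {k.value: int(v) for k, v in d.items()}

        doc = {
            "n_total": self.n_total,
            "n_fallers": self.n_fallers,
            "side_fallers": tokens(self.side_fallers),
            "side_non_fallers": tokens(self.side_non_fallers),
            "memory_fallers": tokens(self.memory_fallers),
            "memory_non_fallers": tokens(self.memory_non_fallers),
            "personality_fallers": tokens(self.personality_fallers),
            "personality_non_fallers": tokens(self.personality_non_fallers),
            "impulsiveness_fallers": tokens(self.impulsiveness_fallers),
            "impulsiveness_non_fallers": tokens(self.impulsiveness_non_fallers),
            "n_missing_both": self.n_missing_both,
            "category_falls": tokens(self.category_falls),
            "category_positives": tokens(self.category_positives),
            "sex_counts": tokens(self.sex_counts),
            "diagnosis_counts": tokens(self.diagnosis_counts),
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_range": list(self.age_range),
            "fim_motor_mean": self.fim_motor_mean,
            "fim_motor_sd": self.fim_motor_sd,
            "fim_cognitive_mean": self.fim_cognitive_mean,
            "fim_cognitive_sd": self.fim_cognitive_sd,
            "seed": self.seed,
            "dependence": self.dependence,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text())

        def parse(d: Mapping, enum_cls) -> dict:
            return {enum_cls(k): int(v) for k, v in d.items()}

        spec = cls(
            n_total=int(doc["n_total"]),
            n_fallers=int(doc["n_fallers"]),
            side_fallers=parse(doc["side_fallers"], SideLevel),
            side_non_fallers=parse(doc["side_non_fallers"], SideLevel),
            memory_fallers=parse(doc["memory_fallers"], ItemResult),
            memory_non_fallers=parse(doc["memory_non_fallers"], ItemResult),
            personality_fallers=parse(doc["personality_fallers"], Personality),
            personality_non_fallers=parse(doc["personality_non_fallers"], Personality),
            impulsiveness_fallers=parse(doc["impulsiveness_fallers"], ItemResult),
            impulsiveness_non_fallers=parse(doc["impulsiveness_non_fallers"], ItemResult),
            n_missing_both=int(doc["n_missing_both"]),
            category_falls=parse(doc["category_falls"], ManagementCategory),
            category_positives=parse(doc["category_positives"], ManagementCategory),
            sex_counts=parse(doc["sex_counts"], Sex),
            diagnosis_counts=parse(doc["diagnosis_counts"], Diagnosis),
            age_mean=float(doc["age_mean"]),
            age_sd=float(doc["age_sd"]),
            age_range=tuple(doc["age_range"]),
            fim_motor_mean=float(doc["fim_motor_mean"]),
            fim_motor_sd=float(doc["fim_motor_sd"]),
            fim_cognitive_mean=float(doc["fim_cognitive_mean"]),
            fim_cognitive_sd=float(doc["fim_cognitive_sd"]),
            seed=int(doc["seed"]),
            dependence=float(doc["dependence"]),
        )
        spec.validate()
        return spec


def fixture_spec(seed: int = 0, dependence: float = 0.0) -> CohortSpec:
    """The canonical fixture's margins packaged as a sampler spec."""
    all_levels = TESTABLE_LEVELS + (_NT,)
    spec = CohortSpec(
        n_total=416,
        n_fallers=38,
        side_fallers=_count_dict(_FALLER_CELLS, 0, all_levels),
        side_non_fallers=_count_dict(_NON_FALLER_CELLS, 0, all_levels),
        memory_fallers=_count_dict(_FALLER_CELLS, 1, tuple(ItemResult)),
        memory_non_fallers=_count_dict(_NON_FALLER_CELLS, 1, tuple(ItemResult)),
        personality_fallers=dict(
            zip(
                (Personality.IMPATIENT, Personality.RESERVED, Personality.MISSING),
                _PERSONALITY_COUNTS[True],
            )
        ),
        personality_non_fallers=dict(
            zip(
                (Personality.IMPATIENT, Personality.RESERVED, Personality.MISSING),
                _PERSONALITY_COUNTS[False],
            )
        ),
        impulsiveness_fallers=dict(
            zip((_POS, _NEG, _MISS), _IMPULSIVENESS_COUNTS[True])
        ),
        impulsiveness_non_fallers=dict(
            zip((_POS, _NEG, _MISS), _IMPULSIVENESS_COUNTS[False])
        ),
        n_missing_both=6,
        category_falls={
            ManagementCategory.C1_SENSOR_RESTRAINT: 16,
            ManagementCategory.C2_NO_SENSOR_RESTRAINT: 7,
            ManagementCategory.C3_SUPERVISED: 7,
            ManagementCategory.C4_SUPERVISOR_LEFT: 1,
            ManagementCategory.C5_PERMITTED_ALONE: 7,
        },
        category_positives={
            ManagementCategory.C1_SENSOR_RESTRAINT: 14,
            ManagementCategory.C2_NO_SENSOR_RESTRAINT: 4,
            ManagementCategory.C3_SUPERVISED: 7,
            ManagementCategory.C4_SUPERVISOR_LEFT: 0,
            ManagementCategory.C5_PERMITTED_ALONE: 4,
        },
        seed=seed,
        dependence=dependence,
    )
    spec.validate()
    return spec


def _tilted_cell(a: float, p: float, dependence: float) -> float:
    """P(low band AND positive) with margins (a, p) under an odds-ratio tilt.

    Plackett-style joint: the odds ratio is (1 + d)/(1 - d); d = +-1 gives
    the Frechet bounds.
    """
    lo, hi = max(0.0, a + p - 1.0), min(a, p)
    if dependence >= 1.0:
        return hi
    if dependence <= -1.0:
        return lo
    if dependence == 0.0 or a in (0.0, 1.0) or p in (0.0, 1.0):
        return a * p
    odds_ratio = (1.0 + dependence) / (1.0 - dependence)
    b = 1.0 + (a + p) * (odds_ratio - 1.0)
    disc = b * b - 4.0 * odds_ratio * (odds_ratio - 1.0) * a * p
    x = (b - np.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    return float(np.clip(x, lo, hi))


def _categorical(rng: np.random.Generator, keys, probs, size: int) -> list:
    idx = rng.choice(len(keys), size=size, p=np.asarray(probs) / np.sum(probs))
    return [keys[i] for i in idx]


def sample_cohort(spec: CohortSpec, n_total: int | None = None) -> Cohort:
    """Draw a seeded stochastic cohort from a :class:`CohortSpec`.

    Fall status is Bernoulli at the spec's faller fraction; SIDE, the three
    adherence items, and (for fallers) the management category are drawn
    conditionally on fall status from the spec's per-group proportions.
    The same seed and spec always produce the same cohort; ``n_total``
    overrides the spec's size for convergence studies.
    """
    spec.validate()
    n = spec.n_total if n_total is None else int(n_total)
    rng = np.random.default_rng(spec.seed)
    n_non = spec.n_total - spec.n_fallers

    p_fall = spec.n_fallers / spec.n_total
    fell = rng.random(n) < p_fall

    all_levels = TESTABLE_LEVELS + (_NT,)
    side: list[SideLevel] = [None] * n  # type: ignore[list-item]
    memory: list[ItemResult] = [None] * n  # type: ignore[list-item]
    personality: list[Personality] = [None] * n  # type: ignore[list-item]
    impulsiveness: list[ItemResult] = [None] * n  # type: ignore[list-item]
    management = [ManagementCategory.NONE] * n

    for group, group_n, side_d, mem_d, pers_d, imp_d in (
        (True, spec.n_fallers, spec.side_fallers, spec.memory_fallers,
         spec.personality_fallers, spec.impulsiveness_fallers),
        (False, n_non, spec.side_non_fallers, spec.memory_non_fallers,
         spec.personality_non_fallers, spec.impulsiveness_non_fallers),
    ):
        idx = np.flatnonzero(fell == group)
        if idx.size == 0:
            continue
        if group_n == 0:
            raise ValueError(
                f"sampled {'fallers' if group else 'non-fallers'} but the "
                "spec assigns that group size 0"
            )
        side_probs = [side_d.get(lvl, 0) / group_n for lvl in all_levels]
        drawn_side = _categorical(rng, all_levels, side_probs, idx.size)
        for i, lvl in zip(idx, drawn_side):
            side[i] = lvl

        n_pos = mem_d.get(_POS, 0)
        n_neg = mem_d.get(_NEG, 0)
        n_miss = mem_d.get(_MISS, 0)
        p_miss = n_miss / group_n
        p_pos = n_pos / (n_pos + n_neg) if (n_pos + n_neg) else 0.0
        # band split among testable levels, for the dependence tilt
        n_testable = sum(side_d.get(lvl, 0) for lvl in TESTABLE_LEVELS)
        a = (
            sum(side_d.get(lvl, 0) for lvl in TESTABLE_LEVELS[:4]) / n_testable
            if n_testable
            else 0.0
        )
        cell = _tilted_cell(a, p_pos, spec.dependence)
        p_pos_low = cell / a if a > 0 else p_pos
        p_pos_high = (p_pos - cell) / (1.0 - a) if a < 1 else p_pos
        u_miss = rng.random(idx.size)
        u_pos = rng.random(idx.size)
        for j, i in enumerate(idx):
            if u_miss[j] < p_miss:
                memory[i] = _MISS
                continue
            lvl = side[i]
            if lvl is _NT:
                p_use = p_pos
            elif lvl <= _L2B:
                p_use = p_pos_low
            else:
                p_use = p_pos_high
            memory[i] = _POS if u_pos[j] < p_use else _NEG

        pers_keys = tuple(pers_d.keys())
        drawn_pers = _categorical(
            rng, pers_keys, [pers_d[k] / group_n for k in pers_keys], idx.size
        )
        imp_keys = tuple(imp_d.keys())
        drawn_imp = _categorical(
            rng, imp_keys, [imp_d[k] / group_n for k in imp_keys], idx.size
        )
        for i, pv, iv in zip(idx, drawn_pers, drawn_imp):
            personality[i] = pv
            impulsiveness[i] = iv

        if group and spec.n_fallers:
            cat_keys = tuple(FALL_CATEGORIES)
            probs = [spec.category_falls.get(c, 0) / spec.n_fallers for c in cat_keys]
            if sum(probs) > 0:
                drawn_cat = _categorical(rng, cat_keys, probs, idx.size)
                for i, c in zip(idx, drawn_cat):
                    management[i] = c

    sexes = _categorical(
        rng,
        tuple(spec.sex_counts.keys()),
        [v / spec.n_total for v in spec.sex_counts.values()],
        n,
    )
    dxs = _categorical(
        rng,
        tuple(spec.diagnosis_counts.keys()),
        [v / spec.n_total for v in spec.diagnosis_counts.values()],
        n,
    )
    age_lo, age_hi = spec.age_range
    ages = _draw_int(
        _truncnorm_matching(spec.age_mean, spec.age_sd, age_lo, age_hi),
        n, age_lo, age_hi, rng,
    )
    fim_motor = _draw_int(
        _truncnorm_matching(spec.fim_motor_mean, spec.fim_motor_sd, *FIM_MOTOR_RANGE),
        n, *FIM_MOTOR_RANGE, rng,
    )
    fim_cog = _draw_int(
        _truncnorm_matching(
            spec.fim_cognitive_mean, spec.fim_cognitive_sd, *FIM_COGNITIVE_RANGE
        ),
        n, *FIM_COGNITIVE_RANGE, rng,
    )

    records = [
        PatientRecord(
            id=f"s{i + 1:06d}",
            age=int(ages[i]),
            sex=sexes[i],
            diagnosis=dxs[i],
            fim_motor=int(fim_motor[i]),
            fim_cognitive=int(fim_cog[i]),
            side=side[i],
            adherence=AdherenceItemResult(
                personality=personality[i],
                memory_instruction=memory[i],
                impulsiveness=impulsiveness[i],
            ),
            fell_within_14d=bool(fell[i]),
            management=management[i],
        )
        for i in range(n)
    ]
    return Cohort.from_records(records)


# --------------------------------------------------------------------------
# Fixture self-audit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    expected: object
    observed: object
    passed: bool


@dataclass(frozen=True)
class ConstraintReport:
    checks: tuple[ConstraintCheck, ...]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> tuple[ConstraintCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)

    def __getitem__(self, name: str) -> ConstraintCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def verify_fixture(cohort: Cohort) -> ConstraintReport:
    """Re-derive every printed count and metric from a cohort.

    Returns a per-constraint pass/fail report; :func:`build_fixture`'s
    output passes every check.
    """
    from .diagnostics import build_table, compute_metrics
    from .falls import positivity_by_category
    from .rounding import round_half_up
    from .screening import (
        Classification,
        ExclusionReason,
        Rule,
        SideCutoff,
        apply_rule,
        exclusion_counts,
    )

    checks: list[ConstraintCheck] = []

    def add(name: str, expected, observed) -> None:
        checks.append(ConstraintCheck(name, expected, observed, expected == observed))

    def add_close(name: str, expected: float, observed: float, tol: float) -> None:
        checks.append(
            ConstraintCheck(name, expected, observed, abs(expected - observed) <= tol)
        )

    fallers, non_fallers = cohort.fallers, cohort.non_fallers
    add("n_total", 416, len(cohort))
    add("n_fallers", 38, len(fallers))

    side_expected = {
        True: {_L0: 12, _L1: 5, _L2A: 14, _L2B: 4, _L3: 1, _L4: 0, _NT: 2},
        False: {_L0: 72, _L1: 45, _L2A: 93, _L2B: 50, _L3: 77, _L4: 25, _NT: 16},
    }
    for fell, group in ((True, fallers), (False, non_fallers)):
        tag = "fall" if fell else "no_fall"
        for lvl, exp in side_expected[fell].items():
            add(
                f"side[{tag}][{lvl.value}]",
                exp,
                sum(1 for r in group if r.side is lvl),
            )

    adherence_expected = {
        "memory_instruction": {True: (29, 9, 0), False: (160, 204, 14)},
        "impulsiveness": {True: (2, 36, 0), False: (16, 345, 17)},
    }
    for item, by_group in adherence_expected.items():
        for fell, group in ((True, fallers), (False, non_fallers)):
            tag = "fall" if fell else "no_fall"
            vals = [getattr(r.adherence, item) for r in group]
            exp_pos, exp_neg, exp_miss = by_group[fell]
            add(f"{item}[{tag}][positive]", exp_pos, sum(v is _POS for v in vals))
            add(f"{item}[{tag}][negative]", exp_neg, sum(v is _NEG for v in vals))
            add(f"{item}[{tag}][missing]", exp_miss, sum(v is _MISS for v in vals))
    for fell, group in ((True, fallers), (False, non_fallers)):
        tag = "fall" if fell else "no_fall"
        vals = [r.adherence.personality for r in group]
        exp_imp, exp_res, exp_miss = _PERSONALITY_COUNTS[fell]
        add(
            f"personality[{tag}][impatient]",
            exp_imp,
            sum(v is Personality.IMPATIENT for v in vals),
        )
        add(
            f"personality[{tag}][reserved]",
            exp_res,
            sum(v is Personality.RESERVED for v in vals),
        )
        add(
            f"personality[{tag}][missing]",
            exp_miss,
            sum(v is Personality.MISSING for v in vals),
        )

    # management-category breakdown with positivity rates
    expected_rows = {
        ManagementCategory.C1_SENSOR_RESTRAINT: (16, 14, 87.5),
        ManagementCategory.C2_NO_SENSOR_RESTRAINT: (7, 4, 57.1),
        ManagementCategory.C3_SUPERVISED: (7, 7, 100.0),
        ManagementCategory.C4_SUPERVISOR_LEFT: (1, 0, 0.0),
        ManagementCategory.C5_PERMITTED_ALONE: (7, 4, 57.1),
        None: (38, 29, 76.3),
    }
    for row in positivity_by_category(cohort):
        exp_falls, exp_pos, exp_rate = expected_rows[row.category]
        tag = row.category.value if row.category else "total"
        add(f"category[{tag}][falls]", exp_falls, row.n_falls)
        add(f"category[{tag}][positive]", exp_pos, row.n_positive)
        add(f"category[{tag}][rate]", exp_rate, row.rate)

    # exclusion cascade
    nt_total = sum(1 for r in cohort if r.side is _NT)
    miss_total = sum(
        1 for r in cohort if r.adherence.memory_instruction is _MISS
    )
    both = sum(
        1
        for r in cohort
        if r.side is _NT and r.adherence.memory_instruction is _MISS
    )
    add("exclusions[side_not_testable]", 18, nt_total)
    add("exclusions[memory_missing]", 14, miss_total)
    add("exclusions[both]", 6, both)

    combined = apply_rule(cohort, Rule.COMBINED)
    analyzed = [r for r in combined if r.classification is not Classification.EXCLUDED]
    add("analysis_n[combined]", 390, len(analyzed))
    by_id = cohort.by_id()
    good_balance = sum(
        1
        for r in analyzed
        if by_id[r.patient_id].side.testable and by_id[r.patient_id].side >= _L3
    )
    add("analysis_n[combined_side_3_4]", 103, good_balance)
    add("analysis_n[combined_intermediate]", 287, len(analyzed) - good_balance)
    reasons = exclusion_counts(combined)
    add("exclusions[combined_both_reason]", 6, reasons.get(ExclusionReason.BOTH_MISSING, 0))

    side_results = apply_rule(cohort, Rule.SIDE_ONLY)
    add(
        "analysis_n[side_only]",
        398,
        sum(1 for r in side_results if r.classification is not Classification.EXCLUDED),
    )
    adh_results = apply_rule(cohort, Rule.ADHERENCE_ONLY)
    add(
        "analysis_n[adherence_only]",
        402,
        sum(1 for r in adh_results if r.classification is not Classification.EXCLUDED),
    )

    # headline metrics (reported rounding: half-up, 2 decimals)
    expected_metrics = {
        ("side_2a_2b", Rule.SIDE_ONLY, SideCutoff(_L2A)): (0.86, 0.42, 0.28),
        ("side_2b_3", Rule.SIDE_ONLY, SideCutoff(_L2B)): (0.97, 0.28, 0.25),
        ("adherence", Rule.ADHERENCE_ONLY, None): (0.76, 0.56, 0.32),
        ("combined", Rule.COMBINED, None): (0.75, 0.64, 0.39),
    }
    for (tag, rule, cutoff), (exp_se, exp_sp, exp_j) in expected_metrics.items():
        if cutoff is not None:
            results = apply_rule(cohort, rule, cutoff=cutoff)
        else:
            results = apply_rule(cohort, rule)
        m = compute_metrics(build_table(results, cohort)).rounded(2)
        add(f"metrics[{tag}][sensitivity]", exp_se, m.sensitivity)
        add(f"metrics[{tag}][specificity]", exp_sp, m.specificity)
        add(f"metrics[{tag}][youden]", exp_j, m.youden)

    # demographics
    for sex, exp in _SEX_COUNTS.items():
        add(f"sex[{sex.value}]", exp, sum(1 for r in cohort if r.sex is sex))
    for dx, exp in _DIAGNOSIS_COUNTS.items():
        add(
            f"diagnosis[{dx.value}]",
            exp,
            sum(1 for r in cohort if r.diagnosis is dx),
        )
    ages = np.array([r.age for r in cohort], dtype=float)
    add("age[min]", _AGE_RANGE[0], int(ages.min()))
    add("age[max]", _AGE_RANGE[1], int(ages.max()))
    moments = {
        "age": (ages, _AGE_MEAN, _AGE_SD),
        "fim_motor": (
            np.array([r.fim_motor for r in cohort], dtype=float),
            _FIM_MOTOR_MEAN,
            _FIM_MOTOR_SD,
        ),
        "fim_cognitive": (
            np.array([r.fim_cognitive for r in cohort], dtype=float),
            _FIM_COG_MEAN,
            _FIM_COG_SD,
        ),
    }
    for name, (vals, exp_mean, exp_sd) in moments.items():
        add_close(f"{name}[mean]", exp_mean, round_half_up(vals.mean(), 1), MOMENT_TOLERANCE)
        add_close(
            f"{name}[sd]", exp_sd, round_half_up(vals.std(ddof=1), 1), MOMENT_TOLERANCE
        )

    return ConstraintReport(tuple(checks))
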