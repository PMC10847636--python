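"""Independent brute-force oracles used by the tests.

These re-derive expected values from first principles (exact integer
arithmetic, exhaustive enumeration) without touching the implementation
paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_enumeration(tp: int, fn: int, fp: int, tn: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration of margin-fixed tables.

    Exact rational arithmetic: sums the hypergeometric point probabilities
    of every table (same margins) whose probability does not exceed the
    observed table's.
    """
    r1, c1, n = tp + fn, tp + fp, tp + fn + fp + tn
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    # shared denominator comb(n, r1); compare integer numerators exactly
    nums = [comb(c1, a) * comb(n - c1, r1 - a) for a in range(lo, hi + 1)]
    observed = nums[tp - lo]
    return Fraction(sum(x for x in nums if x <= observed), comb(n, r1))


# -- SIDE flowchart oracle --------------------------------------------------
# Sub-test results are encoded "p" (pass), "f" (fail), "n" (not attempted)
# in the order: wide base, narrow base, tandem left-front, tandem
# right-front, single-leg left, single-leg right.


def flowchart_level(t: tuple[str, ...]) -> str | None:
    """Level for a 6-tuple of sub-test results, or None if structurally
    invalid (a result recorded after the stance sequence stopped, or a
    stance skipped while the sequence was still running)."""
    w, nb, tl, tr, sl, sr = t
    if t == ("n",) * 6:
        return "not_testable"
    if w == "n":
        return None
    if w == "f":
        return "0" if (nb, tl, tr, sl, sr) == ("n",) * 5 else None
    if nb == "n":
        return None
    if nb == "f":
        return "1" if (tl, tr, sl, sr) == ("n",) * 4 else None
    if "n" in (tl, tr):
        return None
    n_tandem = (tl == "p") + (tr == "p")
    if n_tandem < 2:
        if (sl, sr) != ("n", "n"):
            return None
        return "2a" if n_tandem == 0 else "2b"
    if "n" in (sl, sr):
        return None
    return "4" if (sl, sr) == ("p", "p") else "3"
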