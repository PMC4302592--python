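"""Exact-test machinery for escape-versus-stratum association.

The two-sided Fisher exact p-value uses the minimum-likelihood rule: over
all 2x2 tables sharing the observed margins, sum the hypergeometric point
probabilities no greater than the observed table's (with a small relative
tolerance on the comparison).  Point probabilities are computed with
exact integer binomial coefficients — the common denominator C(N, c1)
cancels, so tables are compared and summed in integer arithmetic and
divided once at the end.  This is stable for totals well beyond the few
hundred genes a stratum analysis involves.

The observed-versus-expected construction places the expected escaper
count (whole-X escape rate scaled to the stratum size, rounded half away
from zero) as the comparator row of a same-sized pseudo-group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: relative tolerance when comparing point probabilities to the observed one
REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; row 1 is the group of interest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Accepts a :class:`ContingencyTable2x2` or a [[a, b], [c, d]] nested
    sequence.  Returns p in (0, 1].
    """
    t = _as_table(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    # point probability of table with k successes in row 1 is
    # C(r1, k) * C(r2, c1-k) / C(n, c1); compare numerators only
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_min, k_max + 1)]
    observed = weights[a - k_min]
    # integer-exact cutoff equivalent to w <= observed * (1 + REL_TOL)
    numer = sum(w for w in weights if w * 10**9 <= observed * int((1 + REL_TOL) * 10**9))
    denom = math.comb(n, c1)
    return min(1.0, numer / denom)


def expected_escapers(stratum_size: int, whole_escape_rate: float) -> int:
    """Expected escaper count: size x rate, rounded half away from zero."""
    if not 0.0 <= whole_escape_rate <= 1.0:
        raise ValueError("escape rate must lie in [0, 1]")
    x = stratum_size * whole_escape_rate
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def escape_enrichment(
    stratum_escapers: int,
    stratum_size: int,
    whole_escapers: int,
    whole_size: int,
    comparison: str = "expected",
) -> tuple[ContingencyTable2x2, int, float]:
    """Observed vs expected escaper counts in a stratum, with exact test.

    Returns ``(table, expected, p)``.  The default ``comparison``
    ("expected") tests the observed stratum against a same-sized
    pseudo-group carrying the whole-X expected count.  The alternative
    ("rest") tests the stratum against the remainder of the chromosome.
    """
    if stratum_size > whole_size or stratum_escapers > whole_escapers:
        raise ValueError("stratum counts cannot exceed whole-chromosome counts")
    if stratum_escapers > stratum_size:
        raise ValueError("more escapers than genes in the stratum")
    expected = expected_escapers(stratum_size, whole_escapers / whole_size)
    if comparison == "expected":
        table = ContingencyTable2x2(
            stratum_escapers,
            stratum_size - stratum_escapers,
            expected,
            stratum_size - expected,
        )
    elif comparison == "rest":
        table = ContingencyTable2x2(
            stratum_escapers,
            stratum_size - stratum_escapers,
            whole_escapers - stratum_escapers,
            (whole_size - stratum_size) - (whole_escapers - stratum_escapers),
        )
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    return table, expected, fisher_exact_two_sided(table)


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage on the printing convention used in summaries (e.g. 23/34 -> 68)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    value = 100.0 * numerator / denominator
    rounded = round(value, ndigits)
    return int(rounded) if ndigits == 0 else rounded
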