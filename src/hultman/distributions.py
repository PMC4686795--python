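"""Exact distributions of the algebraic rearrangement distance.

For a genome ``A`` drawn uniformly from one of the four universes (circular
genomes, all genomes, all genomes against a linear-containing identity, or
genomes with a fixed number of linear chromosomes), the algebraic distance to
the identity is ``d = n - c - p/2``, so its distribution follows directly
from the Hultman tables: the number of genomes at distance ``d`` is the sum
of the table entries with ``c + p/2 = n - d``.  In the circular case paths
never occur and the count at integer distance ``d`` is ``H_C(n, n-d)``.

Distances are half-integers when ``p`` is odd, so counts are keyed by
``2d`` (an exact integer) and probabilities/expectations are exact rationals.
The circular expectation additionally admits the closed form
``E[X_n] = n - sum_{j=0}^{n-1} 1/(2j+1)``: the cycle-count generating
polynomial ``sum_c H_C(n,c) x^c = x (x+2) (x+4) ... (x+2n-2)`` follows from
the recurrence, and differentiating at ``x = 1`` gives the expectation.  It
is kept here as an independent analytic cross-check of the table route.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .counting import hultman_table

__all__ = [
    "DistanceDistribution",
    "circular_genome_count",
    "matching_count",
    "distance_distribution",
    "pmf",
    "expected_distance",
    "expected_distance_circular_closed_form",
    "format_rational",
    "format_half_integer",
]


def circular_genome_count(n: int) -> int:
    """Number of circular genomes on ``n`` genes: the double factorial
    ``(2n-1)!!``, i.e. the number of perfect matchings on ``2n`` vertices."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    out = 1
    for k in range(1, 2 * n, 2):
        out *= k
    return out


def matching_count(vertices: int) -> int:
    """Number of matchings (not necessarily perfect) on *vertices* labelled
    vertices — the involution count sum_k v!/(2^k k! (v-2k)!).

    This is the number of genomes on ``n`` genes when called with ``2n``.
    """
    if vertices < 0 or vertices % 2:
        raise ValueError(f"vertex count must be even and non-negative, got {vertices}")
    total = 0
    for k in range(vertices // 2 + 1):
        total += math.factorial(vertices) // (
            2**k * math.factorial(k) * math.factorial(vertices - 2 * k)
        )
    return total


@dataclass(frozen=True)
class DistanceDistribution:
    """Exact counts of genomes by algebraic distance to the identity.

    ``counts`` maps ``twice_d = 2d`` to the number of genomes at distance
    ``d``; ``universe`` is the total number of genomes in the scenario, and
    the counts always sum to it.
    """

    scenario: str
    n: int
    params: tuple[tuple[str, int], ...]
    counts: Mapping[int, int]
    universe: int

    def count(self, d: Fraction | int | float) -> int:
        twice = Fraction(d) * 2
        if twice.denominator != 1:
            return 0
        return self.counts.get(int(twice), 0)

    def support(self) -> list[Fraction]:
        return [Fraction(t, 2) for t in sorted(self.counts)]

    def pmf(self, d: Fraction | int | float) -> Fraction:
        return Fraction(self.count(d), self.universe)

    def expectation(self) -> Fraction:
        acc = Fraction(0)
        for twice_d, cnt in self.counts.items():
            acc += Fraction(twice_d * cnt, 2)
        return acc / self.universe


def distance_distribution(
    scenario: str,
    n: int,
    *,
    num_linear: int | None = None,
    li: int | None = None,
    la: int | None = None,
) -> DistanceDistribution:
    """Distribution of the algebraic distance for one scenario at size ``n``.

    The universe is ``(2n-1)!!`` for circular, the matching count on ``2n``
    vertices for the general and linear-identity scenarios, and the computed
    table total for the fixed-linear scenario (no closed form is known).
    """
    table = hultman_table(scenario, n, num_linear=num_linear, li=li, la=la)
    counts: dict[int, int] = {}
    if scenario == "circular":
        for c, v in table.counts.items():
            counts[2 * (n - c)] = counts.get(2 * (n - c), 0) + v
        universe = circular_genome_count(n)
    else:
        for (c, p), v in table.counts.items():
            twice_d = 2 * n - 2 * c - p
            counts[twice_d] = counts.get(twice_d, 0) + v
        if scenario == "fixed_linear":
            universe = table.total()
        else:
            universe = matching_count(2 * n)
    if sum(counts.values()) != universe:
        raise AssertionError(
            f"table total {sum(counts.values())} != universe {universe} "
            f"for {scenario} n={n}"
        )
    return DistanceDistribution(
        scenario, n, table.params, dict(sorted(counts.items())), universe
    )


def pmf(dist: DistanceDistribution, d: Fraction | int | float) -> Fraction:
    """P[X = d] as a reduced exact rational (0 for unsupported d)."""
    return dist.pmf(d)


def expected_distance(
    scenario: str,
    n: int,
    *,
    num_linear: int | None = None,
    li: int | None = None,
    la: int | None = None,
) -> Fraction:
    """E[X_n] = sum_d d·P[X_n = d], exact."""
    return distance_distribution(
        scenario, n, num_linear=num_linear, li=li, la=la
    ).expectation()


def expected_distance_circular_closed_form(n: int) -> Fraction:
    """Analytic circular expectation ``n - sum_{j=0}^{n-1} 1/(2j+1)``."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return Fraction(n) - sum(
        (Fraction(1, 2 * j + 1) for j in range(n)), start=Fraction(0)
    )


def format_rational(value: Fraction, places: int = 2) -> str:
    """Decimal rendering of an exact rational, rounded half-even."""
    if places < 0:
        raise ValueError("places must be non-negative")
    with decimal.localcontext() as ctx:
        ctx.prec = max(places, 1) + len(str(abs(value.numerator))) + 5
        dec = decimal.Decimal(value.numerator) / decimal.Decimal(value.denominator)
        quantum = decimal.Decimal(1).scaleb(-places)
        return str(dec.quantize(quantum, rounding=decimal.ROUND_HALF_EVEN))


def format_half_integer(d: Fraction | int) -> str:
    """Render an exact half-integer: ``7`` or ``6.5``."""
    frac = Fraction(d)
    if frac.denominator == 1:
        return str(frac.numerator)
    if frac.denominator == 2:
        sign = "-" if frac < 0 else ""
        whole, half = divmod(abs(frac.numerator), 2)
        return f"{sign}{whole}.5"
    raise ValueError(f"{d} is not a half-integer")
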