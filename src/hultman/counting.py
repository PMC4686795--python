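"""Exact Hultman numbers for multichromosomal genomes.

Four count families, all against a fixed identity genome on ``n`` genes:

* ``hultman_circular(n, c)`` — circular genomes (perfect matchings) whose
  breakpoint graph against the circular identity has ``c`` cycles.
* ``hultman_general(n, c, p)`` — arbitrary genomes (all matchings) against
  the circular identity, by cycles ``c`` and paths ``p``.
* ``hultman_linear_identity(n, c, p, l)`` — arbitrary genomes against an
  identity with exactly ``l`` linear chromosomes.
* ``hultman_fixed_linear(n, c, p, li, la)`` — genomes with exactly ``la``
  linear chromosomes against an identity with ``li`` linear chromosomes.

The three general families are evaluated through auxiliary series over the
number of *unvisited vertices* ``e`` (``e = 2n`` at the top), with ``i``
identity-unsaturated vertices still unvisited and, for the fixed family, a
budget ``a`` of target-unsaturated vertices.  One unvisited vertex at a time
is either joined to another (closing a cycle or merging two paths, possibly
through an identity-unsaturated vertex) or skipped (left unsaturated in the
genome being counted).  Evaluation is bottom-up in ``e`` with rolling levels,
so no recursion depth is involved and arithmetic is exact arbitrary-precision
integer throughout; counts exceed 10**150 already near n = 100.

Out-of-range count arguments return 0, mirroring the recurrences' base cases;
structural parameters (``n`` for tables, the linear-chromosome counts) raise
on invalid values.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

__all__ = [
    "SCENARIOS",
    "HultmanTable",
    "stirling_first_unsigned",
    "hultman_circular",
    "hultman_general",
    "hultman_linear_identity",
    "hultman_fixed_linear",
    "hultman_table",
]

SCENARIOS = ("circular", "general", "linear_identity", "fixed_linear")


# ---------------------------------------------------------------------------
# Unsigned Stirling numbers of the first kind
# ---------------------------------------------------------------------------

_STIRLING_ROWS: list[tuple[int, ...]] = [(1,)]


def stirling_first_unsigned(n: int, k: int) -> int:
    """[n k], permutations of ``n`` elements with ``k`` cycles.

    Total function: any out-of-range argument gives 0.  Filled iteratively
    from ``[n k] = [n-1 k-1] + (n-1)·[n-1 k]`` with ``[0 0] = 1``.
    """
    if n < 0 or k < 0 or k > n:
        return 0
    while len(_STIRLING_ROWS) <= n:
        m = len(_STIRLING_ROWS)  # building row m from row m-1
        prev = _STIRLING_ROWS[m - 1]
        row = [0] * (m + 1)
        for j in range(m):
            row[j + 1] += prev[j]
            row[j] += (m - 1) * prev[j]
        _STIRLING_ROWS.append(tuple(row))
    return _STIRLING_ROWS[n][k]


# ---------------------------------------------------------------------------
# Circular genomes: H_C
# ---------------------------------------------------------------------------

_CIRCULAR_ROWS: list[tuple[int, ...]] = [(1,)]


def hultman_circular(n: int, c: int) -> int:
    """Number of circular genomes on ``n`` genes with ``c`` breakpoint-graph
    cycles against the circular identity.

    Recurrence ``H_C(n,c) = H_C(n-1,c-1) + (2n-2)·H_C(n-1,c)``; equals
    ``2^(n-c) · [n c]`` (unsigned Stirling, first kind).
    """
    if n < 0 or c < 0 or c > n:
        return 0
    while len(_CIRCULAR_ROWS) <= n:
        m = len(_CIRCULAR_ROWS)
        prev = _CIRCULAR_ROWS[m - 1]
        row = [0] * (m + 1)
        for j in range(m):
            row[j + 1] += prev[j]
            row[j] += (2 * m - 2) * prev[j]
        _CIRCULAR_ROWS.append(tuple(row))
    return _CIRCULAR_ROWS[n][c]


# ---------------------------------------------------------------------------
# Bottom-up engines for the auxiliary series H'_G, H'_L, H'_l
# ---------------------------------------------------------------------------
#
# Levels are dicts mapping (c, p) -> count; contributions are pushed from the
# e-1 and e-2 levels into level e.  A `None` level stands for e < 0 (all
# zero).  Coefficients refer to the *target* state (e, i[, a]).

_Level = dict[tuple[int, int], int]


@lru_cache(maxsize=64)
def _general_table(n: int) -> _Level:
    """Full table {(c, p): H_G(n, c, p)} via H'_G(2n, ., .)."""
    if n < 0:
        return {}
    lm1: _Level | None = None  # level e-1
    cur: _Level = {(0, 0): 1}  # level e = 0
    for e in range(1, 2 * n + 1):
        lm2, lm1 = lm1, cur
        nxt: _Level = defaultdict(int)
        if e % 2 == 0:
            if lm2:
                for (c, p), v in lm2.items():
                    nxt[(c + 1, p)] += v  # create cycle
                    if e > 2:
                        nxt[(c, p)] += (e - 2) * v  # merge paths
            for (c, p), v in lm1.items():
                nxt[(c, p)] += v  # skip vertex
        else:
            if lm2:
                for (c, p), v in lm2.items():
                    nxt[(c, p)] += (e - 1) * v  # merge paths
            for (c, p), v in lm1.items():
                nxt[(c, p + 1)] += v  # skip vertex closes a path
        cur = dict(nxt)
    return cur


def hultman_general(n: int, c: int, p: int) -> int:
    """Number of genomes on ``n`` genes (any chromosome types) with ``c``
    cycles and ``p`` paths against the circular identity."""
    if n < 0 or c < 0 or p < 0:
        return 0
    if n == 0:
        return 1 if c == p == 0 else 0
    return _general_table(n).get((c, p), 0)


_ILevels = dict[int, _Level]  # i -> {(c, p): count}


def _linear_levels(e_max: int, i_max: int) -> list[_ILevels]:
    """All levels of H'_L up to e_max; levels[e][i] maps (c,p) to counts."""
    levels: list[_ILevels] = [{0: {(0, 0): 1}}]
    for e in range(1, e_max + 1):
        lm1 = levels[e - 1]
        lm2 = levels[e - 2] if e >= 2 else {}
        nxt: _ILevels = {}
        for i in range(0, min(i_max, e) + 1):
            acc: _Level = defaultdict(int)
            if e == i:
                # only identity-unsaturated vertices remain: connect two of
                # them, or skip one; either way a finished path appears
                if i >= 2:
                    for (c, p), v in lm2.get(i - 2, {}).items():
                        acc[(c, p + 1)] += (i - 1) * v
                for (c, p), v in lm1.get(i - 1, {}).items():
                    acc[(c, p + 1)] += v
            elif (e + i) % 2 == 0:  # balanced
                for (c, p), v in lm2.get(i, {}).items():
                    acc[(c + 1, p)] += v  # create cycle
                    if e - 2 - i > 0:
                        acc[(c, p)] += (e - 2 - i) * v  # merge paths
                if i > 0:
                    for (c, p), v in lm2.get(i - 1, {}).items():
                        acc[(c, p)] += i * v  # connect with unsaturated
                for (c, p), v in lm1.get(i, {}).items():
                    acc[(c, p)] += v  # skip vertex
            else:  # unbalanced
                if e - 1 - i > 0:
                    for (c, p), v in lm2.get(i, {}).items():
                        acc[(c, p)] += (e - 1 - i) * v  # merge paths
                if i > 0:
                    for (c, p), v in lm2.get(i - 1, {}).items():
                        acc[(c, p + 1)] += i * v  # connect, path closes
                for (c, p), v in lm1.get(i, {}).items():
                    acc[(c, p + 1)] += v  # skip vertex, path closes
            if acc:
                nxt[i] = dict(acc)
        levels.append(nxt)
        if e >= 2:
            levels[e - 2] = {}  # rolled past; free memory
    return levels


@lru_cache(maxsize=64)
def _linear_table(n: int, num_linear: int) -> _Level:
    if n < 0:
        return {}
    levels = _linear_levels(2 * n, 2 * num_linear)
    return levels[2 * n].get(2 * num_linear, {})


def hultman_linear_identity(n: int, c: int, p: int, num_linear: int) -> int:
    """Number of genomes on ``n`` genes with ``c`` cycles and ``p`` paths
    against an identity genome with exactly *num_linear* linear chromosomes.

    Satisfies ``hultman_linear_identity(n, c, p, 0) == hultman_general(n, c, p)``.
    """
    if n >= 0 and not 0 <= num_linear <= n:
        raise ValueError(
            f"number of linear chromosomes must be in 0..{n}, got {num_linear}"
        )
    if n < 0 or c < 0 or p < 0:
        return 0
    if n == 0:
        return 1 if c == p == 0 else 0
    return _linear_table(n, num_linear).get((c, p), 0)


_IALevels = dict[tuple[int, int], _Level]  # (i, a) -> {(c, p): count}


def _fixed_levels(e_max: int, i_max: int, a_max: int) -> list[_IALevels]:
    """Levels of H'_l; the extra index ``a`` is the remaining budget of
    genome-unsaturated vertices, consumed only by skip-vertex moves."""
    levels: list[_IALevels] = [{(0, 0): {(0, 0): 1}}]
    for e in range(1, e_max + 1):
        lm1 = levels[e - 1]
        lm2 = levels[e - 2] if e >= 2 else {}
        nxt: _IALevels = {}
        for i in range(0, min(i_max, e) + 1):
            for a in range(0, min(a_max, e) + 1):
                acc: _Level = defaultdict(int)
                if e == i:
                    if i >= 2:
                        for (c, p), v in lm2.get((i - 2, a), {}).items():
                            acc[(c, p + 1)] += (i - 1) * v
                    if a > 0:
                        for (c, p), v in lm1.get((i - 1, a - 1), {}).items():
                            acc[(c, p + 1)] += v  # skip: uses one of budget a
                elif (e + i) % 2 == 0:  # balanced
                    for (c, p), v in lm2.get((i, a), {}).items():
                        acc[(c + 1, p)] += v
                        if e - 2 - i > 0:
                            acc[(c, p)] += (e - 2 - i) * v
                    if i > 0:
                        for (c, p), v in lm2.get((i - 1, a), {}).items():
                            acc[(c, p)] += i * v
                    if a > 0:
                        for (c, p), v in lm1.get((i, a - 1), {}).items():
                            acc[(c, p)] += v  # skip
                else:  # unbalanced
                    if e - 1 - i > 0:
                        for (c, p), v in lm2.get((i, a), {}).items():
                            acc[(c, p)] += (e - 1 - i) * v
                    if i > 0:
                        for (c, p), v in lm2.get((i - 1, a), {}).items():
                            acc[(c, p + 1)] += i * v
                    if a > 0:
                        for (c, p), v in lm1.get((i, a - 1), {}).items():
                            acc[(c, p + 1)] += v  # skip
                if acc:
                    nxt[(i, a)] = dict(acc)
        levels.append(nxt)
        if e >= 2:
            levels[e - 2] = {}
    return levels


@lru_cache(maxsize=64)
def _fixed_table(n: int, li: int, la: int) -> _Level:
    if n < 0:
        return {}
    levels = _fixed_levels(2 * n, 2 * li, 2 * la)
    return levels[2 * n].get((2 * li, 2 * la), {})


def hultman_fixed_linear(n: int, c: int, p: int, li: int, la: int) -> int:
    """Number of genomes on ``n`` genes with exactly *la* linear chromosomes,
    ``c`` cycles and ``p`` paths against an identity with *li* linear
    chromosomes.

    Summing over ``la = 0..n`` recovers ``hultman_linear_identity(n, c, p, li)``.
    """
    if n >= 0:
        for label, value in (("identity", li), ("genome", la)):
            if not 0 <= value <= n:
                raise ValueError(
                    f"{label} linear-chromosome count must be in 0..{n}, got {value}"
                )
    if n < 0 or c < 0 or p < 0:
        return 0
    if n == 0:
        return 1 if c == p == 0 else 0
    return _fixed_table(n, li, la).get((c, p), 0)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HultmanTable:
    """All nonzero counts of one scenario at a fixed ``n``.

    ``counts`` maps ``c`` (circular scenario) or ``(c, p)`` (the others) to
    exact integers, in sorted key order.
    """

    scenario: str
    n: int
    params: tuple[tuple[str, int], ...]
    counts: Mapping[int, int] | Mapping[tuple[int, int], int]

    def total(self) -> int:
        return sum(self.counts.values())


def hultman_table(
    scenario: str,
    n: int,
    *,
    num_linear: int | None = None,
    li: int | None = None,
    la: int | None = None,
) -> HultmanTable:
    """Full table of nonzero Hultman numbers for one scenario.

    ``num_linear`` is required for (and only for) ``linear_identity``;
    ``li``/``la`` for ``fixed_linear``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")

    if scenario == "circular":
        if num_linear is not None or li is not None or la is not None:
            raise ValueError("circular scenario takes no linear-chromosome counts")
        counts_c = {
            c: hultman_circular(n, c)
            for c in range(0, n + 1)
            if hultman_circular(n, c)
        }
        if n == 0:
            counts_c = {0: 1}
        return HultmanTable("circular", n, (), counts_c)

    if n == 0:
        return HultmanTable(scenario, 0, _scenario_params(scenario, num_linear, li, la), {(0, 0): 1})

    if scenario == "general":
        if num_linear is not None or li is not None or la is not None:
            raise ValueError("general scenario takes no linear-chromosome counts")
        raw = _general_table(n)
        return HultmanTable("general", n, (), dict(sorted(raw.items())))

    if scenario == "linear_identity":
        if num_linear is None:
            raise ValueError("linear_identity scenario requires num_linear")
        if li is not None or la is not None:
            raise ValueError("linear_identity scenario takes num_linear only")
        if not 0 <= num_linear <= n:
            raise ValueError(f"num_linear must be in 0..{n}, got {num_linear}")
        raw = _linear_table(n, num_linear)
        return HultmanTable(
            "linear_identity", n, (("num_linear", num_linear),),
            dict(sorted(raw.items())),
        )

    # fixed_linear
    if li is None or la is None:
        raise ValueError("fixed_linear scenario requires both li and la")
    if num_linear is not None:
        raise ValueError("fixed_linear scenario takes li/la, not num_linear")
    for label, value in (("li", li), ("la", la)):
        if not 0 <= value <= n:
            raise ValueError(f"{label} must be in 0..{n}, got {value}")
    raw = _fixed_table(n, li, la)
    return HultmanTable(
        "fixed_linear", n, (("li", li), ("la", la)), dict(sorted(raw.items()))
    )


def _scenario_params(
    scenario: str, num_linear: int | None, li: int | None, la: int | None
) -> tuple[tuple[str, int], ...]:
    if scenario == "linear_identity":
        return (("num_linear", num_linear or 0),)
    if scenario == "fixed_linear":
        return (("li", li or 0), ("la", la or 0))
    return ()
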