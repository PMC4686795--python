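"""Brute-force ground truth for the Hultman recurrences.

Enumerates every matching on a small labelled vertex set exactly once (no
shortcuts, no counting tricks — the point is independence from the
recurrences), decomposes each against an identity matching, and tabulates
the resulting (cycles, paths) census.  Also provides exact-uniform samplers
over the same universes for Monte-Carlo checks at sizes where enumeration is
impossible.

Enumeration order is deterministic: at each step the smallest unvisited
vertex is either skipped (where the mode permits) or paired with each larger
unvisited partner in increasing order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator

from .genomes import ExtremityMatching, decompose

__all__ = [
    "MAX_VERTICES",
    "EnumerationSpec",
    "enumerate_matchings",
    "tabulate",
    "tabulate_detailed",
    "sample_uniform",
]

MAX_VERTICES = 16
MODES = ("perfect", "all", "fixed_unsaturated")


@dataclass(frozen=True)
class EnumerationSpec:
    """A universe of matchings on ``vertices`` labelled vertices.

    ``perfect`` — perfect matchings (circular genomes); ``all`` — every
    matching (all genomes); ``fixed_unsaturated`` — matchings leaving exactly
    ``unsaturated`` vertices unmatched (genomes with ``unsaturated/2`` linear
    chromosomes).
    """

    vertices: int
    mode: str
    unsaturated: int | None = None

    def __post_init__(self) -> None:
        if self.vertices < 0 or self.vertices % 2:
            raise ValueError(
                f"vertex count must be even and non-negative, got {self.vertices}"
            )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "fixed_unsaturated":
            u = self.unsaturated
            if u is None or u % 2 or not 0 <= u <= self.vertices:
                raise ValueError(
                    "fixed_unsaturated mode needs an even unsaturated count "
                    f"in 0..{self.vertices}, got {u}"
                )
        elif self.unsaturated is not None:
            raise ValueError(f"mode {self.mode!r} takes no unsaturated count")

    @property
    def n(self) -> int:
        return self.vertices // 2


def enumerate_matchings(spec: EnumerationSpec) -> Iterator[ExtremityMatching]:
    """Yield every matching of the requested kind exactly once.

    Refuses more than ``MAX_VERTICES`` vertices: the universe size grows
    super-exponentially and the oracle is only meant for certification at
    small sizes.
    """
    if spec.vertices > MAX_VERTICES:
        raise ValueError(
            f"oracle enumeration is capped at {MAX_VERTICES} vertices "
            f"({spec.vertices} requested); use sample_uniform for larger sizes"
        )
    n = spec.n
    skip_budget = {
        "perfect": 0,
        "all": spec.vertices,
        "fixed_unsaturated": spec.unsaturated or 0,
    }[spec.mode]
    exact_skips = spec.mode == "fixed_unsaturated"

    free = list(range(1, spec.vertices + 1))
    edges: list[tuple[int, int]] = []

    def rec(free: list[int], skips_left: int) -> Iterator[ExtremityMatching]:
        if not free:
            if not exact_skips or skips_left == 0:
                yield ExtremityMatching(n=n, edges=frozenset(edges))
            return
        if exact_skips and skips_left > len(free):
            return
        u = free[0]
        if skips_left > 0:
            yield from rec(free[1:], skips_left - 1)
        for idx in range(1, len(free)):
            v = free[idx]
            edges.append((u, v))
            yield from rec(free[1:idx] + free[idx + 1 :], skips_left)
            edges.pop()

    yield from rec(free, skip_budget)


def tabulate(
    spec: EnumerationSpec, identity: ExtremityMatching
) -> dict[tuple[int, int], int]:
    """Census {(cycles, paths): count} of every enumerated matching
    decomposed against *identity* — the literal definition of the Hultman
    numbers."""
    if 2 * identity.n != spec.vertices:
        raise ValueError(
            f"identity has {2 * identity.n} vertices, spec has {spec.vertices}"
        )
    out: dict[tuple[int, int], int] = {}
    for m in enumerate_matchings(spec):
        s = decompose(m, identity)
        key = (s.cycles, s.paths)
        out[key] = out.get(key, 0) + 1
    return out


def tabulate_detailed(
    spec: EnumerationSpec, identity: ExtremityMatching
) -> dict[tuple[int, int, int], int]:
    """Census keyed (cycles, paths, unsaturated-in-genome); the third key
    splits the ``all`` universe by number of linear chromosomes, so one pass
    yields every fixed-unsaturated table at once."""
    if 2 * identity.n != spec.vertices:
        raise ValueError(
            f"identity has {2 * identity.n} vertices, spec has {spec.vertices}"
        )
    out: dict[tuple[int, int, int], int] = {}
    for m in enumerate_matchings(spec):
        s = decompose(m, identity)
        key = (s.cycles, s.paths, m.unsaturated_count)
        out[key] = out.get(key, 0) + 1
    return out


def _matching_counts_upto(v: int) -> list[int]:
    counts = [1, 1]
    for k in range(2, v + 1):
        counts.append(counts[k - 1] + (k - 1) * counts[k - 2])
    return counts[: v + 1]


def sample_uniform(
    spec: EnumerationSpec, count: int, seed: int
) -> Iterator[ExtremityMatching]:
    """Yield *count* exactly-uniform draws from the spec's universe.

    Perfect matchings: pair the smallest free vertex with a uniform other.
    All matchings: the smallest free vertex among ``v`` is left unmatched
    with probability M(v-1)/M(v) and matched to a given partner with
    probability M(v-2)/M(v), where M is the matching count — exact, via
    integer draws.  Fixed unsaturated: the saturated vertex set is drawn
    uniformly (every set of 2k vertices carries the same number (2k-1)!! of
    perfect matchings), then matched uniformly.  Deterministic under *seed*.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    rng = random.Random(seed)
    n = spec.n

    if spec.mode == "all":
        m_counts = _matching_counts_upto(spec.vertices)

    for _ in range(count):
        edges: list[tuple[int, int]] = []
        if spec.mode == "perfect":
            free = list(range(1, spec.vertices + 1))
            while free:
                u = free.pop(0)
                v = free.pop(rng.randrange(len(free)))
                edges.append((u, v))
        elif spec.mode == "all":
            free = list(range(1, spec.vertices + 1))
            while free:
                v_count = len(free)
                r = rng.randrange(m_counts[v_count])
                u = free.pop(0)
                if r < m_counts[v_count - 1]:
                    continue  # u stays unsaturated
                partner_idx = (r - m_counts[v_count - 1]) // m_counts[v_count - 2]
                v = free.pop(partner_idx)
                edges.append((u, v))
        else:  # fixed_unsaturated
            saturated = rng.sample(
                range(1, spec.vertices + 1), spec.vertices - (spec.unsaturated or 0)
            )
            free = sorted(saturated)
            while free:
                u = free.pop(0)
                v = free.pop(rng.randrange(len(free)))
                edges.append((u, v))
        yield ExtremityMatching(n=n, edges=frozenset(edges))
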