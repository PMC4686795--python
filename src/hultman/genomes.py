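"""Multichromosomal genomes, extremity matchings and breakpoint graphs.

A genome is a set of chromosomes, each an ordered sequence of signed genes;
linear chromosomes are flanked by telomeres, circular ones wrap around.  Every
oriented gene ``g`` has two extremities, the tail ``g^t`` and the head ``g^h``.
Non-telomeric adjacencies pair two extremities, so a genome on genes ``1..n``
corresponds one-to-one to a matching on the ``2n`` extremity vertices — a
perfect matching exactly when every chromosome is circular.

Superimposing the matchings of two genomes on the shared vertex set gives the
(multichromosomal) breakpoint graph.  Every vertex has degree 0, 1 or 2, so
the graph decomposes uniquely into alternating cycles and paths; the counts of
cycles ``c``, paths ``p`` and even paths ``e`` determine the double-cut-and-join
distance ``n - c - e/2`` and the algebraic rearrangement distance
``n - c - p/2``.

Vertex numbering convention: ``tail(g) = 2g - 1`` and ``head(g) = 2g``,
vertices ``1..2n``.  Components with no edges at all (vertices unsaturated in
both matchings) count as paths with zero edges, and zero is even.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple

__all__ = [
    "GenomeError",
    "TAIL",
    "HEAD",
    "Extremity",
    "tail",
    "head",
    "Chromosome",
    "Genome",
    "ExtremityMatching",
    "DecompositionSummary",
    "genome_to_matching",
    "identity_circular",
    "identity_with_linear",
    "decompose",
    "dcj_distance",
    "algebraic_distance",
]


class GenomeError(ValueError):
    """Structurally invalid genome/matching, or mismatched comparison inputs."""


TAIL = "tail"
HEAD = "head"


def tail(gene: int) -> int:
    """Vertex id of the tail extremity of *gene* (genes are 1-based)."""
    return 2 * gene - 1


def head(gene: int) -> int:
    """Vertex id of the head extremity of *gene*."""
    return 2 * gene


class Extremity(NamedTuple):
    gene: int
    side: str  # TAIL or HEAD

    @property
    def vertex_id(self) -> int:
        return tail(self.gene) if self.side == TAIL else head(self.gene)


def _left_vertex(signed_gene: int) -> int:
    """Extremity met first when reading *signed_gene* left to right."""
    return tail(signed_gene) if signed_gene > 0 else head(-signed_gene)


def _right_vertex(signed_gene: int) -> int:
    """Extremity met last when reading *signed_gene* left to right."""
    return head(signed_gene) if signed_gene > 0 else tail(-signed_gene)


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed genes, either linear or circular."""

    genes: tuple[int, ...]
    is_linear: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(int(g) for g in self.genes))
        if not self.genes:
            raise GenomeError("chromosome has no genes")
        seen: set[int] = set()
        for g in self.genes:
            if g == 0:
                raise GenomeError("gene label 0 is not allowed")
            if abs(g) in seen:
                raise GenomeError(f"gene {abs(g)} repeated within a chromosome")
            seen.add(abs(g))

    def __len__(self) -> int:
        return len(self.genes)

    def adjacencies(self) -> Iterable[tuple[int, int]]:
        """Vertex pairs of the non-telomeric adjacencies, in reading order."""
        k = len(self.genes)
        last = k - 1 if self.is_linear else k
        for idx in range(last):
            a = self.genes[idx]
            b = self.genes[(idx + 1) % k]
            yield _right_vertex(a), _left_vertex(b)


@dataclass(frozen=True)
class Genome:
    """A set of chromosomes whose absolute gene labels are exactly ``1..n``.

    Two genomes are equal iff they induce the same extremity matching; this
    identifies a circular chromosome with its rotations/reflections and a
    linear chromosome with its reversal.
    """

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        labels: set[int] = set()
        for chrom in self.chromosomes:
            for g in chrom.genes:
                if abs(g) in labels:
                    raise GenomeError(f"gene {abs(g)} appears more than once")
                labels.add(abs(g))
        n = len(labels)
        if labels and labels != set(range(1, n + 1)):
            missing = sorted(set(range(1, n + 1)) - labels)[:3]
            raise GenomeError(
                f"gene labels must be exactly 1..{n}; missing {missing}"
            )
        object.__setattr__(self, "_n", n)

    @property
    def n(self) -> int:
        """Number of genes."""
        return self._n  # type: ignore[attr-defined]

    @property
    def num_linear(self) -> int:
        return sum(1 for c in self.chromosomes if c.is_linear)

    def matching(self) -> "ExtremityMatching":
        return genome_to_matching(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.matching() == other.matching()

    def __hash__(self) -> int:
        return hash(self.matching())


@dataclass(frozen=True)
class ExtremityMatching:
    """A partial matching on the ``2n`` extremity vertices of ``n`` genes."""

    n: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        norm = frozenset(
            (u, v) if u < v else (v, u) for u, v in self.edges
        )
        object.__setattr__(self, "edges", norm)
        seen: set[int] = set()
        for u, v in norm:
            if u == v:
                raise GenomeError(f"self-loop on vertex {u}")
            for w in (u, v):
                if not 1 <= w <= 2 * self.n:
                    raise GenomeError(f"vertex {w} outside 1..{2 * self.n}")
                if w in seen:
                    raise GenomeError(f"vertex {w} saturated twice")
                seen.add(w)

    @property
    def unsaturated(self) -> tuple[int, ...]:
        sat = {w for e in self.edges for w in e}
        return tuple(v for v in range(1, 2 * self.n + 1) if v not in sat)

    @property
    def unsaturated_count(self) -> int:
        return 2 * self.n - 2 * len(self.edges)

    def is_perfect(self) -> bool:
        return 2 * len(self.edges) == 2 * self.n


@dataclass(frozen=True)
class DecompositionSummary:
    """Cycle/path census of a breakpoint graph.

    ``even_paths`` counts paths with an even number of edges (zero-edge
    singleton components included), the quantity entering the DCJ distance.
    """

    cycles: int
    paths: int
    even_paths: int
    path_edge_lengths: tuple[int, ...] = field(default=())

    @property
    def components(self) -> int:
        return self.cycles + self.paths


def genome_to_matching(g: Genome) -> ExtremityMatching:
    """Matching induced by the non-telomeric adjacencies of *g*.

    A circular chromosome of ``k`` genes contributes ``k`` edges; a linear one
    contributes ``k - 1`` and leaves its two telomeric extremities unsaturated.
    """
    edges: list[tuple[int, int]] = []
    for chrom in g.chromosomes:
        edges.extend(chrom.adjacencies())
    return ExtremityMatching(n=g.n, edges=frozenset(edges))


def identity_circular(n: int) -> Genome:
    """The circular identity genome ``{(1 2 ... n)}``."""
    if n < 1:
        raise GenomeError(f"need at least one gene, got n={n}")
    return Genome((Chromosome(tuple(range(1, n + 1)), is_linear=False),))


def identity_with_linear(n: int, num_linear: int) -> Genome:
    """Canonical identity genome on ``1..n`` with exactly *num_linear* linear
    chromosomes.

    For ``num_linear = 0`` this is the circular identity.  Otherwise the genes
    ``1..n`` are split into *num_linear* consecutive runs of near-equal length
    (the remainder going to the first chromosomes), all linear.
    """
    if n < 1:
        raise GenomeError(f"need at least one gene, got n={n}")
    if not 0 <= num_linear <= n:
        raise GenomeError(
            f"number of linear chromosomes must be in 0..{n}, got {num_linear}"
        )
    if num_linear == 0:
        return identity_circular(n)
    base, rem = divmod(n, num_linear)
    chroms: list[Chromosome] = []
    start = 1
    for idx in range(num_linear):
        size = base + (1 if idx < rem else 0)
        chroms.append(
            Chromosome(tuple(range(start, start + size)), is_linear=True)
        )
        start += size
    return Genome(tuple(chroms))


def decompose(a: ExtremityMatching, b: ExtremityMatching) -> DecompositionSummary:
    """Cycle/path decomposition of the union multigraph of two matchings.

    Parallel edges (an adjacency shared by both matchings) form a 2-edge
    cycle; a component is a cycle iff every vertex in it has degree 2, and a
    path otherwise, including zero-edge singletons.
    """
    if a.n != b.n:
        raise GenomeError(f"gene counts differ: {a.n} != {b.n}")
    nv = 2 * a.n
    adj: list[list[int]] = [[] for _ in range(nv + 1)]
    for m in (a, b):
        for u, v in m.edges:
            adj[u].append(v)
            adj[v].append(u)
    seen = bytearray(nv + 1)
    cycles = 0
    path_lengths: list[int] = []
    for s in range(1, nv + 1):
        if seen[s]:
            continue
        seen[s] = 1
        comp = [s]
        stack = [s]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if not seen[w]:
                    seen[w] = 1
                    comp.append(w)
                    stack.append(w)
        deg_sum = sum(len(adj[u]) for u in comp)
        if deg_sum == 2 * len(comp):  # every vertex has degree 2
            cycles += 1
        else:
            path_lengths.append(deg_sum // 2)
    path_lengths.sort()
    return DecompositionSummary(
        cycles=cycles,
        paths=len(path_lengths),
        even_paths=sum(1 for ln in path_lengths if ln % 2 == 0),
        path_edge_lengths=tuple(path_lengths),
    )


def _check_same_gene_set(a: Genome, b: Genome) -> int:
    if a.n != b.n:
        raise GenomeError(f"gene sets differ: 1..{a.n} vs 1..{b.n}")
    return a.n


def dcj_distance(a: Genome, b: Genome) -> Fraction:
    """Double-cut-and-join distance ``n - c - e/2`` (an exact half-integer)."""
    n = _check_same_gene_set(a, b)
    summary = decompose(a.matching(), b.matching())
    return Fraction(n) - summary.cycles - Fraction(summary.even_paths, 2)


def algebraic_distance(a: Genome, b: Genome) -> Fraction:
    """Algebraic rearrangement distance ``n - c - p/2`` (exact half-integer)."""
    n = _check_same_gene_set(a, b)
    summary = decompose(a.matching(), b.matching())
    return Fraction(n) - summary.cycles - Fraction(summary.paths, 2)
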