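"""Reading and writing genomes in GRIMM-style text files.

Dialect: a line beginning ``>`` names a genome; each following non-empty line
holds one or more chromosomes as whitespace-separated signed integers, each
chromosome terminated by ``$`` (linear) or ``@`` (circular).  As an input
alternative, a linear chromosome may be written between ``∘`` telomere
markers, e.g. ``∘ -9 3 8 7 ∘``.  Lines starting with ``#`` are comments.

The writer emits the ``$``/``@`` form; writing then re-reading a genome is
bit-exact on that canonical form.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .genomes import Chromosome, Genome, GenomeError

__all__ = ["GrimmParseError", "parse_grimm", "read_grimm", "format_grimm", "write_grimm"]

TELOMERE = "∘"  # '∘'


class GrimmParseError(GenomeError):
    """Malformed GRIMM input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _make_chromosome(genes: tuple[int, ...], is_linear: bool, lineno: int) -> Chromosome:
    try:
        return Chromosome(genes, is_linear=is_linear)
    except GenomeError as exc:
        raise GrimmParseError(str(exc), lineno) from exc


def _parse_chromosome_line(line: str, lineno: int) -> list[Chromosome]:
    chroms: list[Chromosome] = []
    genes: list[int] = []
    in_telomeres = False
    for token in line.split():
        if token == "$" or (token == TELOMERE and in_telomeres):
            if not genes:
                raise GrimmParseError("empty chromosome", lineno)
            chroms.append(_make_chromosome(tuple(genes), True, lineno))
            genes = []
            in_telomeres = False
        elif token == "@":
            if in_telomeres:
                raise GrimmParseError(
                    f"'@' inside '{TELOMERE}'-delimited chromosome", lineno
                )
            if not genes:
                raise GrimmParseError("empty chromosome", lineno)
            chroms.append(_make_chromosome(tuple(genes), False, lineno))
            genes = []
        elif token == TELOMERE:
            if genes:
                raise GrimmParseError(
                    f"'{TELOMERE}' may only open or close a chromosome", lineno
                )
            in_telomeres = True
        else:
            try:
                gene = int(token)
            except ValueError:
                raise GrimmParseError(f"not a signed integer: {token!r}", lineno)
            if gene == 0:
                raise GrimmParseError("gene label 0 is not allowed", lineno)
            genes.append(gene)
    if genes or in_telomeres:
        raise GrimmParseError(
            f"chromosome not terminated by '$', '@' or '{TELOMERE}'", lineno
        )
    return chroms


def parse_grimm(text: str) -> list[tuple[str, Genome]]:
    """Parse GRIMM text into ``(name, Genome)`` pairs, in file order."""
    genomes: list[tuple[str, Genome]] = []
    name: str | None = None
    chroms: list[Chromosome] = []

    def flush(lineno: int) -> None:
        nonlocal name, chroms
        if name is None:
            return
        if not chroms:
            raise GrimmParseError(f"genome {name!r} has no chromosomes", lineno)
        try:
            genomes.append((name, Genome(tuple(chroms))))
        except GenomeError as exc:
            raise GrimmParseError(f"genome {name!r}: {exc}", lineno) from exc
        name, chroms = None, []

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip()
            if not name:
                raise GrimmParseError("genome name missing after '>'", lineno)
        else:
            if name is None:
                raise GrimmParseError("chromosome line before any '>' header", lineno)
            chroms.extend(_parse_chromosome_line(line, lineno))
    flush(lineno + 1)
    return genomes


def read_grimm(path: str | Path) -> list[tuple[str, Genome]]:
    return parse_grimm(Path(path).read_text(encoding="utf-8"))


def format_grimm(named_genomes: Iterable[tuple[str, Genome]]) -> str:
    lines: list[str] = []
    for name, genome in named_genomes:
        lines.append(f">{name}")
        for chrom in genome.chromosomes:
            marker = "$" if chrom.is_linear else "@"
            lines.append(" ".join(str(g) for g in chrom.genes) + f" {marker}")
    return "\n".join(lines) + "\n"


def write_grimm(path: str | Path, named_genomes: Sequence[tuple[str, Genome]]) -> None:
    Path(path).write_text(format_grimm(named_genomes), encoding="utf-8")
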