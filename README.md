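# hultman

Exact combinatorics of multichromosomal breakpoint graphs: count genomes by
the number of cycles and paths of their breakpoint graph against a chosen
identity genome, and derive exact distributions and expected values of the
rearrangement distance between random genomes.

## Who this is for

Researchers in comparative genomics and genome rearrangement who need the
*distribution* of breakpoint-graph parameters — not just the distance between
one pair of genomes.  Knowing how many genomes on `n` genes have `c` cycles
and `p` paths against an identity lets you ask how probable a given distance
is under a uniform null model, which is the baseline for judging whether two
real gene orders are closer than chance.

## The model

A genome on genes `1..n` is a set of chromosomes: ordered sequences of
signed genes, linear (flanked by telomeres `∘`) or circular.  Each gene `g`
has two extremities, tail `gᵗ` and head `gʰ`; each non-telomeric adjacency
pairs two extremities, so a genome corresponds one-to-one to a matching on
the `2n` extremity vertices (perfect iff the genome is purely circular).
The breakpoint graph `BG(A, B)` superimposes the matchings of `A` and `B`;
every vertex has degree ≤ 2, so it decomposes uniquely into `c` alternating
cycles and `p` paths, of which `e` have an even number of edges.  Two
distances follow directly:

    d_DCJ(A, B) = n − c − e/2        (double cut and join)
    d_a(A, B)   = n − c − p/2        (algebraic rearrangement distance)

The package computes four exact count families ("Hultman numbers"), each by
its own big-integer recurrence:

| family                        | identity                  | universe                         |
|-------------------------------|---------------------------|----------------------------------|
| `H_C(n, c)`                   | circular genome           | circular genomes (`(2n−1)!!`)    |
| `H_G(n, c, p)`                | circular genome           | all genomes (matchings on `2n`)  |
| `H_L(n, c, p, ℓ)`             | `ℓ` linear chromosomes    | all genomes                      |
| `H_ℓ(n, c, p, ℓᵢ, ℓₐ)`        | `ℓᵢ` linear chromosomes   | genomes with `ℓₐ` linear chrs.   |

`H_C` also has the closed form `H_C(n, c) = 2^(n−c) · [n c]` with `[n k]`
the unsigned Stirling numbers of the first kind.  From any family the exact
distribution of `d_a` follows by summing entries with `c + p/2 = n − d`, and
from that exact-rational probabilities and expectations.  Every recurrence
is certified bit-exactly against a brute-force matching-enumeration oracle.

## Worked example

The nine-gene pair `A = {(1 2 3 4 5 6 7 8 9)}` (circular) and
`B = {(6 −1 4 5 −2), (∘ −9 3 8 7 ∘)}`, as GRIMM files:

```sh
$ cat A.grimm                 # '@' ends a circular chromosome
>A
1 2 3 4 5 6 7 8 9 @
$ cat B.grimm                 # '$' ends a linear chromosome ('∘ ... ∘' also accepted)
>B
6 -1 4 5 -2 @
-9 3 8 7 $
$ hultman bg A.grimm B.grimm
genome_a	A
genome_b	B
genes	9
cycles	2
paths	1
even_paths	0
dcj_distance	7
algebraic_distance	6.5
```

The breakpoint graph decomposes into two cycles and one path; the path has
five (an odd number of) edges, so no even path enters the DCJ formula:
`d_DCJ = 9 − 2 − 0/2 = 7` and `d_a = 9 − 2 − 1/2 = 6.5`.

Counting tables and expectations:

```sh
$ hultman table --scenario circular -n 4
scenario	n	params	c	p	count
circular	4	-	1	-	48
circular	4	-	2	-	44
circular	4	-	3	-	12
circular	4	-	4	-	1
```

48 of the 105 circular genomes on 4 genes form one cycle against the
identity, and only the identity itself forms four.

```sh
$ hultman expect --scenario circular -n 100 --precision 2
.../... ≈ 96.72
$ hultman expect --scenario general -n 100 --precision 2
.../... ≈ 95.22
```

(the exact fractions, elided here, have ~90-digit terms).  A genome drawn
uniformly from all circular genomes on 100 genes sits at expected algebraic
distance 96.72 from the identity — random genomes are almost as far as the
diameter `n`; over the universe of *all* genomes the expectation is 95.22.

`hultman distribution` prints the full exact distribution, and
`hultman verify --scenario general -n 3` shows the recurrence and the
brute-force oracle side by side (exit status 1 on any mismatch).

The same operations are available as library functions:

```python
>>> from hultman import hultman_circular, expected_distance
>>> hultman_circular(4, 2)
44
>>> expected_distance("circular", 2)
Fraction(2, 3)
```

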