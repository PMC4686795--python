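# Methods

## Genome ↔ matching model

Genomes are multichromosomal gene orders on labels `1..n` with orientation
signs; chromosomes are linear or circular.  The package identifies a genome
with the matching its non-telomeric adjacencies induce on the `2n` extremity
vertices, numbered `tail(g) = 2g−1`, `head(g) = 2g`.  This numbering is a
convention chosen for a stable total order (canonical serialization,
hashing); nothing downstream depends on it.  Genome equality is matching
equality, so a circular chromosome equals its rotations and reflections and
a linear chromosome equals its reversal — the representation a chromosome
was entered in is preserved for output but carries no extra meaning.

The breakpoint graph of two genomes is the union multigraph of their
matchings.  Degree ≤ 2 everywhere implies a unique decomposition into
cycles and paths, computed by direct traversal.  Three conventions fix the
degenerate cases:

* a vertex unsaturated in both matchings is a component of its own and is
  counted as a **path with zero edges**;
* zero is even, so such singletons are **even paths** for the DCJ formula —
  this is what makes `d_DCJ(A, A) = 0` for genomes with linear chromosomes;
* an adjacency present in both matchings is a pair of parallel edges and
  counts as a **2-edge cycle** (required for `c = n` when a circular genome
  is compared with itself).

Distances are returned as exact `Fraction` half-integers: the path count
`p` may be odd, making `n − c − p/2` half-integral.

## The four count families

All counting is exact arbitrary-precision integer arithmetic; the dominant
counts near `n = 100` exceed 10¹⁵⁰, so no floating point is permitted
anywhere in a count.

**Circular, `H_C(n, c)`** — `H_C(n,c) = H_C(n−1,c−1) + (2n−2)·H_C(n−1,c)`:
joining a vertex to the unique partner in its own component closes a cycle
(one way); joining it to any of the `2n−2` vertices of other components
merges two paths.  Rows are filled iteratively and cached.  The identity
`H_C(n,c) = 2^(n−c)·[n c]` (unsigned Stirling numbers, first kind, computed
by their own independent recurrence) is asserted in tests up to `n = 12`.

**General, `H_G(n, c, p)`** — evaluated through an auxiliary series over
the number `e` of still-unvisited vertices (`e = 2n` at the top), because a
*skip vertex* move (leaving a vertex unsaturated, i.e. creating a telomere)
consumes one vertex rather than two.  With `e` even the moves are create
cycle (1 way), merge paths (`e−2` ways) and skip; with `e` odd the stranded
vertex can merge (`e−1` ways) or skip, the skip closing a path.  The merge
coefficients are the counts of available partner vertices, `e−2` and `e−1`.

**Linear identity, `H_L(n, c, p, ℓ)`** — the auxiliary series gains an
index `i` = identity-unsaturated vertices still unvisited (`i = 2ℓ` at the
top).  The branch is chosen by comparing `e` with `i` and by the parity of
`e + i` (balanced/unbalanced); connect-with-unsaturated moves carry
coefficient `i`, connect-two-unsaturated `i−1`, and merges `e−2−i` or
`e−1−i`.

**Fixed linear, `H_ℓ(n, c, p, ℓᵢ, ℓₐ)`** — same structure with one more
index `a`, the remaining budget of genome-unsaturated vertices
(`a = 2ℓₐ` at the top).  Only the three skip-vertex moves consume the
budget; every other move carries `a` through unchanged, and a state at
`e = 0` contributes only if the budget is exactly spent.

All three auxiliary series are evaluated **bottom-up in `e`** with rolling
levels holding `{(c, p): count}` maps (push-style contribution
propagation), so there is no recursion depth to manage and memory stays at
two levels.  Out-of-range count arguments return 0, mirroring the base
cases; invalid structural parameters (linear-chromosome counts outside
`0..n`) raise.  Practical sizes on one core: circular to `n` in the
thousands, general and linear-identity to `n = 100` in seconds, fixed
linear to `n = 100` for small `ℓᵢ, ℓₐ` (the level count grows with
`ℓᵢ·ℓₐ`).

The canonical identity genome with `ℓ` linear chromosomes splits `1..n`
into `ℓ` consecutive near-equal runs (remainder to the first chromosomes).
The choice is immaterial: the recurrence depends only on `(e, i)`, and the
oracle tests confirm that every identity matching with the same number of
unsaturated vertices yields the identical table.

## Distributions and expectations

The algebraic distance satisfies `d = n − c − p/2`, so the distribution
over any universe is a direct marginal of the corresponding table:
`count(d) = Σ_{c+p/2 = n−d} H(·)`.  Counts are keyed by `2d` to keep
half-integer support exact; probabilities and expectations are exact
rationals, rendered as decimals with half-even rounding on request
(default 2 places).  Only the algebraic distance is distributed this way:
the tables do not separate even from odd paths, so DCJ-distance
distributions are out of scope (the pairwise DCJ distance of two concrete
genomes is of course available).

Universe sizes: `(2n−1)!!` perfect matchings for circular genomes; the
involution count on `2n` vertices for the general and linear-identity
universes (the involution-number formula is often quoted loosely as "the
telephone number T(n)", but the argument must be the vertex count `2n`, not
`n` — the package is explicit about this); for the fixed-linear universe no
closed form is assumed — the table total is used, and tests confirm it
equals `C(2n, 2ℓₐ)·(2(n−ℓₐ)−1)!!`.

For circular genomes the cycle generating polynomial
`Σ_c H_C(n,c)·x^c = x(x+2)(x+4)⋯(x+2n−2)` follows from the recurrence, and
differentiating at `x = 1` gives the analytic expectation

    E[Xₙ] = n − Σ_{j=0}^{n−1} 1/(2j+1),

kept in the library as an independent cross-check: tests assert exact
rational equality with the table-based expectation for all `n ≤ 50`.
Because the odd harmonic sum diverges, `n − E[Xₙ]` grows without bound
(≈ ½·ln n), so `E` does not converge to `n − k` for a constant `k`.

At `n = 100` the four scenarios give (computed by `scripts/acceptance.py`):
circular 96.7157 (= closed form), general 95.2230, linear identity with
`ℓ = 1` 94.7914, fixed linear with `ℓᵢ = ℓₐ = 1` 97.0457.  A value of
95.22 sometimes quoted for random *circular* genomes at `n = 100` is
actually the general-universe expectation — the circular universe gives
96.72, and the package reports both rather than reconciling them silently.

## Brute-force oracle

The oracle enumerates every matching on `2n` labelled vertices (perfect,
all, or with a fixed number of unsaturated vertices) by a deterministic
rule — the smallest unvisited vertex is either skipped or paired with each
larger partner — guaranteeing each matching exactly once without hashing.
Tabulating `decompose(M, M_identity)` over the enumeration realises the
count definitions literally and is the ground truth the recurrences are
certified against: bit-exact agreement for all four families, every
`ℓ, ℓᵢ, ℓₐ`, at `n ≤ 6` (≈ 1.1 million decompositions) in the acceptance
suite, with `n ≤ 4` re-checked in the unit suite.  Enumeration is capped at
16 vertices by design; the oracle deliberately contains no counting
shortcuts.

Uniform samplers cover sizes beyond enumeration: perfect matchings by
sequential random pairing; general matchings by the exact count-split rule
(the smallest free vertex among `v` is left unmatched with probability
`M(v−1)/M(v)`, using integer draws, with `M` the matching count); fixed
unsaturated by drawing the saturated vertex set uniformly (every such set
carries the same number of perfect matchings) and matching it uniformly.
The seed is an explicit argument — no hidden global state.

## What the tests do and do not show

The certification is exhaustive but small-`n`: recurrence/oracle agreement
at `n ≤ 6` certifies every coefficient of the recurrences (any wrong
coefficient shows up by `n = 3`–`4`), and identities proven for all `n`
(sum rules, Stirling closed form, the expectation closed form) are checked
far beyond.  The Monte-Carlo concordance test (10⁴ uniform circular genomes
at `n = 10`, fixed seed, 3σ per histogram bin) ties the samplers to the
exact distributions at a size enumeration cannot reach.  None of this
involves real biological gene orders: the package is exact combinatorics on
the uniform null model, and says nothing about the distance distribution of
genomes related by evolution rather than by chance.  Equal gene content
with no duplicates is assumed throughout; no rearrangement scenario
reconstruction is attempted.

## Numerical and interface choices

* Counts serialize as decimal strings in JSON (they overflow 64-bit
  integers near `n = 11` already for the circular family); TSV and JSON
  table/distribution forms round-trip exactly.
* CLI exit codes: 0 success, 1 verification failure, 2 usage error; data on
  stdout, logging on stderr.
* GRIMM-dialect I/O accepts `$`/`@` chromosome terminators and the `∘`
  telomere notation on input; the writer emits the canonical `$`/`@` form.
* The acceptance script derives all randomness from its `--seed` argument;
  problem sizes there (oracle certification at `n ≤ 5`, expectations at
  `n = 100`, 10⁴ Monte-Carlo draws at `n = 10`) are the package's standard
  demonstration sizes, chosen to certify every family and still run on a
  laptop in seconds.
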