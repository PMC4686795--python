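import random

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from hultman import Chromosome, Genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def count_components(num_vertices: int, edges) -> int:
    """Independent component counter (union-find), used as a cross-check of
    the traversal in `decompose`."""
    parent = list(range(num_vertices + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    return len({find(v) for v in range(1, num_vertices + 1)})


def random_genome(rng: random.Random, n: int) -> Genome:
    """A uniform-ish random genome on genes 1..n: random signed order, random
    chromosome breaks, random linear/circular flags."""
    genes = [g * rng.choice((-1, 1)) for g in rng.sample(range(1, n + 1), n)]
    breaks = sorted(rng.sample(range(1, n), rng.randint(0, n - 1))) if n > 1 else []
    bounds = [0, *breaks, n]
    chroms = tuple(
        Chromosome(tuple(genes[a:b]), is_linear=rng.random() < 0.5)
        for a, b in zip(bounds, bounds[1:])
    )
    return Genome(chroms)


@st.composite
def genomes(draw, max_genes: int = 7):
    n = draw(st.integers(min_value=1, max_value=max_genes))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    return random_genome(random.Random(seed), n)


@pytest.fixture
def figure_pair():
    """The worked nine-gene example: a circular identity-like genome A and a
    two-chromosome genome B whose breakpoint graph has 2 cycles and 1 path."""
    a = Genome((Chromosome(tuple(range(1, 10)), is_linear=False),))
    b = Genome(
        (
            Chromosome((6, -1, 4, 5, -2), is_linear=False),
            Chromosome((-9, 3, 8, 7), is_linear=True),
        )
    )
    return a, b
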