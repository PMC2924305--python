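import numpy as np
import pytest

from peakscan import Genome, GenomicInterval, simulate


@pytest.fixture(scope="session")
def toy_genome_dict() -> dict[str, str]:
    return simulate.make_genome({"chrA": 50_000, "chrB": 30_000}, seed=11)


@pytest.fixture(scope="session")
def toy_genome(toy_genome_dict) -> Genome:
    return Genome(toy_genome_dict)


@pytest.fixture(scope="session")
def toy_genes(toy_genome_dict):
    return simulate.make_genes(
        {c: len(s) for c, s in toy_genome_dict.items()}, 8, seed=12
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def random_intervals(rng, n, chroms=("chrA", "chrB"), max_pos=40_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out
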