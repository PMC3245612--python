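import numpy as np
import pytest

from splicefuse.io_model import Genome, RunConfig

BASES = "ACGT"


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> Genome:
    chroms = {}
    for name, length in lengths.items():
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, length)]
        chroms[name] = arr.tobytes().decode("ascii")
    return Genome(chroms)


@pytest.fixture
def config() -> RunConfig:
    return RunConfig().validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng) -> Genome:
    return random_genome(rng, {"chrA": 10_000, "chrB": 8_000})
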