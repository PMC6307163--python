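import numpy as np
import pytest

from nvbarcode import benchmark_spec, featurize, generate_dataset


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def benchmark():
    """Seed-1 synthetic benchmark: records, truth table, nv18 features."""
    records, truth = generate_dataset(benchmark_spec(seed=1))
    features = featurize(records)
    return records, truth, features


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
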