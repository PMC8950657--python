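import numpy as np
import pytest

import dhupred as dp


@pytest.fixture(scope="session")
def default_dataset() -> dp.Dataset:
    """Benchmark-shaped synthetic dataset with the strong reference motif."""
    return dp.generate_dataset(dp.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def null_dataset() -> dp.Dataset:
    """Same composition, zero effect size: labels carry no signal."""
    return dp.generate_dataset(dp.SyntheticConfig(effect_size=0.0, seed=11))


@pytest.fixture(scope="session")
def separable_toy():
    """20-point, 2-feature linearly separable toy problem."""
    rng = np.random.default_rng(0)
    X_pos = rng.normal(loc=[5.0, 5.0], scale=0.3, size=(10, 2))
    X_neg = rng.normal(loc=[-5.0, -5.0], scale=0.3, size=(10, 2))
    X = np.vstack([X_pos, X_neg])
    y = np.array([1] * 10 + [0] * 10)
    return X, y


@pytest.fixture()
def tiny_dataset() -> dp.Dataset:
    records = [
        dp.SequenceRecord("s1", "H.sapiens", 1, "GAGACUGAGACUGAGACUGAUGAGACUGAGACUGAGACUGA"),
        dp.SequenceRecord("s2", "E.coli", 0, "A" * 20 + "U" + "C" * 20),
        dp.SequenceRecord("s3", "S.cerevisiae", 1, "G" * 20 + "U" + "A" * 20),
        dp.SequenceRecord("s4", "S.cerevisiae", 0, "C" * 20 + "U" + "G" * 20),
    ]
    return dp.Dataset(tuple(records))


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
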