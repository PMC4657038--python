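import numpy as np
import pytest

from dualscreen import synthdata
from dualscreen.compounds import LabeledDataset


@pytest.fixture(scope="session")
def default_cfg():
    return synthdata.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def planted_dataset(default_cfg):
    """Default planted-signal labeled set used across classifier tests."""
    return synthdata.gen_labeled_compounds(default_cfg)


@pytest.fixture()
def tiny_dataset():
    """Four compounds, two actives; small enough for hand evaluation.

    Feature 1 occurs in one active and one inactive (A_f=1, T_f=2);
    feature 2 occurs in both actives only (A_f=2, T_f=2).
    """
    return LabeledDataset(
        ids=["a1", "a2", "i1", "i2"],
        fingerprints=[
            frozenset({1, 2}),
            frozenset({2}),
            frozenset({1}),
            frozenset({3}),
        ],
        labels=[True, True, False, False],
    )


def random_labeled_dataset(rng, n_max=50, f_max=100):
    """Small random dataset for oracle-equivalence checks."""
    n = int(rng.integers(4, n_max + 1))
    labels = [True, False] + [bool(rng.integers(0, 2)) for _ in range(n - 2)]
    fps = [
        frozenset(
            rng.choice(f_max, size=rng.integers(0, 12), replace=False).tolist()
        )
        for _ in range(n)
    ]
    return LabeledDataset(
        ids=[f"c{i}" for i in range(n)], fingerprints=fps, labels=labels
    )
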