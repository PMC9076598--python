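import numpy as np
import pandas as pd
import pytest

from copredict.rules import DecisionTable
from copredict.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def toy_table() -> DecisionTable:
    """Four visits, two genes; g1 alone separates the classes."""
    return DecisionTable(
        objects=["o1", "o2", "o3", "o4"],
        features=["g1", "g2"],
        X=np.array([[3, 2], [1, 2], [3, 1], [1, 1]]),
        y=np.array(["DA3", "DA1", "DA3", "DA1"], dtype=object),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic cohort shared by preprocessing/model tests."""
    cfg = SimConfig(n_controls=20, n_da1=40, n_da3=40, n_genes=60,
                    n_informative_class=6, subgroup_sizes=(20, 20),
                    n_informative_per_subgroup=4, seed=42)
    return generate(cfg)


def random_table(rng: np.random.Generator, n_obj: int, n_feat: int,
                 n_levels: int = 3) -> DecisionTable:
    """Random small decision table with codes 1..n_levels and binary labels."""
    X = rng.integers(1, n_levels + 1, size=(n_obj, n_feat))
    y = np.array(["DA1", "DA3"], dtype=object)[rng.integers(0, 2, size=n_obj)]
    return DecisionTable(objects=[f"o{i}" for i in range(n_obj)],
                         features=[f"g{j}" for j in range(n_feat)],
                         X=X, y=y)
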