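import numpy as np
import pandas as pd
import pytest

import beemarker as bm


@pytest.fixture(scope="session")
def small_dataset() -> bm.SyntheticDataset:
    """2000-gene, 112-cage dataset with all three planted programs."""
    cfg = bm.SimConfig(
        n_genes=2000,
        n_diet_program=400,
        n_stock_program=100,
        n_weight_program=50,
        seed=1,
    )
    return bm.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def null_dataset_24() -> bm.SyntheticDataset:
    """24-sample dataset with no planted effects (calibration checks)."""
    return bm.simulate_experiment(null_config(seed=5))


def null_config(seed: int, n_genes: int = 2000) -> bm.SimConfig:
    return bm.SimConfig(
        n_genes=n_genes,
        n_colonies_per_stock=1,
        cages_per_colony_per_diet=3,
        n_diet_program=0,
        n_stock_program=0,
        n_weight_program=0,
        diet_lfc=0.0,
        stock_lfc=0.0,
        weight_beta=0.0,
        viral_stock_lfc=0.0,
        seed=seed,
    )


@pytest.fixture
def toy_counts() -> bm.CountMatrix:
    counts = pd.DataFrame(
        [[10, 20], [0, 5], [100, 50]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    biotype = pd.Series(["protein_coding", "lncRNA", "protein_coding"], index=counts.index)
    return bm.CountMatrix(counts, biotype)
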