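import numpy as np
import pandas as pd
import pytest

from mirpathsea import ExpressionMatrix, PhenotypeLabels
from mirpathsea.simulate import SimulationConfig, simulate


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    df = pd.DataFrame(
        [[8.0, 4.0], [2.0, 6.0], [1.0, 1.0]],
        index=["hsa-miR-1", "hsa-miR-2", "hsa-miR-3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(df, log_scale=False)


@pytest.fixture
def two_group_labels() -> PhenotypeLabels:
    ids = [f"c{i}" for i in range(4)] + [f"k{i}" for i in range(4)]
    return PhenotypeLabels(ids, ["case"] * 4 + ["control"] * 4, ("case", "control"))


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study reused across integration-style tests."""
    cfg = SimulationConfig(
        n_mirnas=(80, 80),
        n_genes=4000,
        n_pathways=8,
        pathway_size_range=(20, 40),
        targets_per_mirna_range=(5, 15),
        samples={"A": (10, 8), "B": (10, 10)},
        planted_pathways=[
            ("PW_0001", "down", "A"),
            ("PW_0001", "up", "B"),
            ("PW_0002", "up", "A"),
            ("PW_0002", "down", "B"),
        ],
        effect_size=2.5,
        noise_sd=0.4,
        drivers_per_pathway=4,
        seed=42,
    )
    return simulate(cfg)


def make_expr(values, mirnas=None, samples=None, log_scale=False) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    mirnas = mirnas or [f"m{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=mirnas, columns=samples), log_scale)
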