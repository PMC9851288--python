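import numpy as np
import pandas as pd
import pytest

from bulkcraft.matrixio import ExpressionMatrix, MetadataTable


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {"s1": [10.0, 90.0, 5.0], "s2": [90.0, 10.0, 5.0]},
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def six_sample_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.integers(1, 1000, size=(50, 6)).astype(float),
        index=[f"g{i:02d}" for i in range(50)],
        columns=[f"s{j}" for j in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def six_sample_meta(six_sample_matrix) -> MetadataTable:
    return MetadataTable(
        pd.DataFrame(
            {"condition": ["A", "A", "A", "B", "B", "B"],
             "timepoint": ["0h", "12h", "36h", "0h", "12h", "36h"]},
            index=six_sample_matrix.sample_ids,
        )
    )


@pytest.fixture(scope="session")
def noise_fixture() -> ExpressionMatrix:
    """Low-abundance features are exchangeable uniform counts; high-abundance
    features are identical across samples (perfect correlation)."""
    rng = np.random.default_rng(2024)
    n_noise, n_signal, n_samples = 200, 200, 4
    noise = rng.integers(0, 20, size=(n_noise, n_samples)).astype(float)  # means < 10
    mus = np.linspace(100, 1000, n_signal)
    signal = np.tile(mus[:, None], (1, n_samples))  # means >= 100, rank correlation 1
    data = pd.DataFrame(
        np.vstack([noise, signal]),
        index=[f"n{i:03d}" for i in range(n_noise)] + [f"sig{i:03d}" for i in range(n_signal)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data)
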