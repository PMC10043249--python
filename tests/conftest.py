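import numpy as np
import pytest

from planqa.autoencoder import AEConfig
from planqa.schema import DimColumn, DimMask, EncodedMatrix, default_schema, encode_table
from planqa.synthetic import GenConfig, generate_dataset


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """A small labeled benchmark (60 normal + 6 abnormal)."""
    table, manifest = generate_dataset(GenConfig(n_normal=60, n_abnormal=6, seed=7))
    return table, manifest


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    table, _ = small_dataset
    return encode_table(table, scale="minmax")


@pytest.fixture(scope="session")
def benchmark_runs():
    """Default 557+19 benchmark scored by a depth-6 AE for seeds 0-4.

    Shared by the acceptance separation criterion and the AE-vs-baseline
    ordering property so the expensive trainings happen once.
    """
    from planqa.autoencoder import fit_autoencoder, sample_errors

    runs = []
    for seed in range(5):
        table, _ = generate_dataset(GenConfig(seed=seed))
        data = encode_table(table, scale="minmax")
        labels = table.label_array
        config = AEConfig(depth=6, seed=seed)
        result = fit_autoencoder(data, config)
        scores = sample_errors(result.model, data, config.lambda_weight)
        runs.append((data, labels, scores))
    return runs


@pytest.fixture
def fast_config():
    """Training config small enough for unit tests."""
    return AEConfig(depth=2, latent_dim=4, epochs=40, batch_size=16, seed=0)


def random_mixed_matrix(rng, n_rows=12, n_binary=6, n_cont=5):
    """Random EncodedMatrix-like pair (targets, predictions) for loss tests."""
    cols = []
    for i in range(n_binary):
        cols.append(DimColumn(f"b{i}", f"b{i}", "b", "binary", "x"))
    for i in range(n_cont):
        cols.append(DimColumn(f"c{i}", f"c{i}", "c", "continuous"))
    mask = DimMask(tuple(cols))
    X = np.zeros((n_rows, n_binary + n_cont))
    X[:, :n_binary] = rng.integers(0, 2, size=(n_rows, n_binary))
    X[:, n_binary:] = rng.normal(size=(n_rows, n_cont))
    X_hat = np.zeros_like(X)
    X_hat[:, :n_binary] = rng.uniform(0.05, 0.95, size=(n_rows, n_binary))
    X_hat[:, n_binary:] = rng.normal(size=(n_rows, n_cont))
    return X_hat, X, mask
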