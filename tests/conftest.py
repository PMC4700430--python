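import numpy as np
import pandas as pd
import pytest

from bloodtx.datatypes import ExpressionMatrix, SampleTable
from bloodtx.preprocess import preprocess_pipeline
from bloodtx.simulate import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_probes=800, n_de=30, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One modest synthetic dataset shared by read-only tests."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    filtered, report = preprocess_pipeline(small_dataset.matrix,
                                           small_dataset.samples)
    return filtered, report


@pytest.fixture(scope="session")
def tight_module_dataset():
    """Low-noise dataset whose control module correlations are near-perfect.

    With loading 0.95 and log2 noise 0.1 the planted pairwise Pearson
    correlation in controls is 0.95^2 / (0.95^2 + 0.1^2) ~ 0.99 (the
    rank correlation of a bivariate normal runs slightly lower), so the
    module survives even the stringent display threshold (rho ~ 0.97 at
    14 samples per group).
    """
    cfg = SynthConfig(n_probes=500, n_de=20, loading_control=0.95,
                      noise_sd_log2=0.1, seed=13)
    ds = generate_dataset(cfg)
    filtered, _ = preprocess_pipeline(ds.matrix, ds.samples)
    return ds, filtered


def make_samples(n_pairs: int) -> SampleTable:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append((f"case{i:02d}", "case", f"pair{i:02d}"))
        rows.append((f"ctrl{i:02d}", "control", f"pair{i:02d}"))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"])
    return SampleTable(df.set_index("sample_id"))


def make_matrix(values: np.ndarray, stage: str = "baselined",
                prefix: str = "P") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    n_pairs = n_samples // 2
    cols = []
    for i in range(1, n_pairs + 1):
        cols += [f"case{i:02d}", f"ctrl{i:02d}"]
    df = pd.DataFrame(values,
                      index=[f"{prefix}{i:04d}" for i in range(n_probes)],
                      columns=cols)
    return ExpressionMatrix(df, stage=stage)


@pytest.fixture
def samples4() -> SampleTable:
    return make_samples(2)


@pytest.fixture
def samples14() -> SampleTable:
    return make_samples(14)
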