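import numpy as np
import pandas as pd
import pytest

from protomix.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_tumor=8, n_nat=8, n_genes=40, n_chroms=2, arm_bins=120, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_config():
    return CohortConfig(
        n_tumor=6, n_nat=6, n_genes=30, n_chroms=2, arm_bins=100, seed=7,
        noise_sd={"expression": 0.0, "reporter": 0.0, "lr": 0.0,
                  "baf": 0.0, "cell_score": 0.0},
        flag_rates={},
    )


def make_matrix(rng, n_features=50, n_samples=20, prefix="G", sample_prefix="S"):
    genes = [f"{prefix}{i + 1:03d}" for i in range(n_features)]
    samples = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(rng.normal(0, 1, (n_features, n_samples)),
                        index=genes, columns=samples)
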