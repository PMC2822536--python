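import numpy as np
import pytest

from bimodal import (
    SimulationConfig,
    detect_bimodal,
    normalize_dataset,
    simulate,
)


@pytest.fixture
def tiny_matrix(tmp_path):
    """A 3-gene x 4-sample TSV with one missing cell in the last gene."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\tS3\tS4\n"
        "GRB7\t1.0\t2.0\t8.0\t9.0\n"
        "ESR1\t5.0\t5.5\t4.5\t5.2\n"
        "ERBB2\t0.1\tNA\t7.9\t8.2\n"
    )
    return path


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic study: 2000 genes x 200 samples, 10% bimodal,
    five planted groups of 4-6 genes at 95% mode agreement (seed 1)."""
    config = SimulationConfig(seed=1, group_sizes=(4, 5, 5, 6, 5))
    (dataset,), truth = simulate(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def planted_fits(planted_cohort):
    _, dataset, _ = planted_cohort
    return detect_bimodal(dataset)


@pytest.fixture(scope="session")
def planted_normalized(planted_cohort, planted_fits):
    _, dataset, _ = planted_cohort
    return normalize_dataset(dataset, planted_fits)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
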