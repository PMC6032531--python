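import numpy as np
import pandas as pd
import pytest

from tgsig import ExpressionMatrix, SimulationConfig, simulate_cohort, simulate_network
from tgsig.expression import NON_RESPONDER, RESPONDER


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=300,
        n_responders=6,
        n_nonresponders=6,
        de_fraction=0.05,
        log2_effect=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = simulate_cohort(small_config)
    simulate_network(cohort, small_config)
    return cohort


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples with hand-set group means (log2 scale)."""
    rng = np.random.default_rng(5)
    samples = ["R1", "R2", "R3", "N1", "N2", "N3"]
    labels = pd.Series([RESPONDER] * 3 + [NON_RESPONDER] * 3, index=samples)
    base = rng.normal(7, 1, size=(4, 6)) * 0.1
    data = pd.DataFrame(base + 7.0, index=["A", "B", "C", "D"], columns=samples)
    # gene A: responder values exactly one log2 unit above non-responder values
    data.iloc[0, :3] = data.iloc[0, 3:].to_numpy() + 1.0
    return ExpressionMatrix(data, labels)


def two_group_labels(n_pos: int, n_neg: int) -> np.ndarray:
    return np.array([RESPONDER] * n_pos + [NON_RESPONDER] * n_neg)
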