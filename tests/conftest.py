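import numpy as np
import pandas as pd
import pytest

from rtquant.features import features_table
from rtquant.simulate import (
    SimulationConfig,
    default_truth_coefficients,
    simulate_experiment,
    simulate_library,
    true_readthrough,
)


@pytest.fixture(scope="session")
def small_experiment():
    """Default-condition synthetic run, shared across tests (read-only)."""
    return simulate_experiment(SimulationConfig(n_variants=400, seed=42))


@pytest.fixture(scope="session")
def truth_5000():
    """Noise-free model-recovery dataset: 5000 variants, known f4 truth."""
    contexts = simulate_library(5000, seed=11)
    coefficients = default_truth_coefficients(contexts, ("drugA",), seed=11)
    truth = true_readthrough(contexts, coefficients)
    feats = features_table(contexts, include_controls=False)
    rtp = truth.rtp["drugA"].loc[feats.index]
    return feats, rtp, coefficients["drugA"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_gates():
    from rtquant.sortseq import GateMetadata

    return GateMetadata(
        pd.DataFrame(
            {
                "gate_id": ["g1", "g2", "g3"],
                "pc": [50.0, 30.0, 20.0],
                "fv": [1.0, 10.0, 100.0],
            }
        )
    )
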