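import numpy as np
import pytest

from cmpanel import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """The standard study-sized cohort with a planted 5-protein panel (d=1)."""
    cfg = SimulationConfig(
        n_cases=35, n_proteins=500, n_planted=5, effect_size=1.0, seed=7
    )
    matrices, cohort, truth = generate_cohort(cfg)
    return matrices, cohort, truth


@pytest.fixture(scope="session")
def small_planted():
    """A small, fast cohort with a strong 3-protein panel for workflow tests."""
    cfg = SimulationConfig(
        n_cases=15,
        n_controls=30,
        n_proteins=60,
        n_planted=3,
        effect_size=1.5,
        missing_rate=0.02,
        seed=11,
    )
    matrices, cohort, truth = generate_cohort(cfg)
    return matrices, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
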