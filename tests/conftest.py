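import numpy as np
import pytest
from hypothesis import settings

from harvestvar.simulate import ExperimentDesign, VitalRates, run_experiment

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced simulated experiment (all 7 treatments, 2 replicates,
    30 weeks) for I/O and plumbing tests."""
    design = ExperimentDesign(n_replicates=2, n_weeks=30, master_seed=42)
    return run_experiment(design)


@pytest.fixture(scope="session")
def headline_experiment():
    """Constant and periodic regimes, control vs proportional harvest,
    6 replicates, full 102 weeks — the headline-contrast design."""
    design = ExperimentDesign(
        n_replicates=6, n_weeks=102, master_seed=1,
        treatments=(("constant", "none"), ("constant", "proportional"),
                    ("periodic", "none"), ("periodic", "proportional")))
    return run_experiment(design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
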