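import numpy as np
import pytest

from nfds import ExperimentDesign, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One seeded default 12-line experiment: (trajectories, counts, design)."""
    return generate_experiment(ExperimentDesign(seed=11))


@pytest.fixture(scope="session")
def exact_experiment():
    """Deterministic, effectively infinite-depth experiment (analytic oracle)."""
    design = ExperimentDesign(seed=0, deterministic=True, read_depth_per_snp=10**9)
    return design, generate_experiment(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
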