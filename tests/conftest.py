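import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from toolreach.simulate import CohortDesign, ReachSpec, generate_cohort, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_trial():
    """D = 0.4 m, T = 0.7 s reach with no noise or tremor."""
    spec = ReachSpec(amplitude_D=0.4, duration_T=0.7)
    return spec, generate_trial(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 3 + 4 participant cohort with the default effect structure."""
    design = CohortDesign(n_pd=3, n_control=4, trials_per_session=2, seed=7)
    return generate_cohort(design)
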