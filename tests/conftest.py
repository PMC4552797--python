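import numpy as np
import pytest

from cohortkin import CohortData, WeibullParams, sample, table1_presets


@pytest.fixture
def presets_ok():
    """The fitted parameter sets that are internally consistent (suspect
    30C shape excluded; its moment-matched replacement included)."""
    return [(lab, p) for lab, p, suspect in table1_presets() if not suspect]


@pytest.fixture
def params_25c():
    return WeibullParams(0.7118, 3.4663)


@pytest.fixture
def cohort_25c(params_25c):
    """A large continuous-recording cohort from the 25C parameters."""
    return CohortData(sample(params_25c, 5000, seed=20250922), "25C")


@pytest.fixture
def random_param_data():
    """Factory for (params, ages) draws spanning the plausible range."""

    def make(seed, n=100):
        rng = np.random.default_rng(seed)
        p = WeibullParams(
            float(np.exp(rng.uniform(np.log(0.1), np.log(5.0)))),
            float(np.exp(rng.uniform(np.log(0.3), np.log(6.0)))),
        )
        return p, sample(p, n, seed=rng)

    return make
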