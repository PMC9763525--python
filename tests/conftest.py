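import pytest

from prrtdose.cohort import CohortSpec, make_cohort
from prrtdose.pipeline import run_calibration


@pytest.fixture(scope="session")
def calibration():
    """Noise-free recovery calibration on the six-sphere phantom set."""
    return run_calibration(seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with exact mono-exponential kinetics and no noise."""
    spec = CohortSpec(
        n_patients=6,
        noise_cv=0.0,
        half_life_cv=0.0,
        organ_uptake_cv=0.0,
        seed=3,
    )
    return make_cohort(spec)
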