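import numpy as np
import pytest

from gratiomap.cohort import BiomarkerSpec, CohortConfig, build_cohort, cohort_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample cohort with a slope+offset biomarker, shared across tests."""
    config = CohortConfig(
        seed=7,
        n_samples=60,
        axons_per_sample=200,
        biomarker_specs=(
            BiomarkerSpec("perfect", alpha=1.0, beta=0.0),
            BiomarkerSpec("slope_only", alpha=0.8, beta=0.0),
            BiomarkerSpec("offset", alpha=1.0, beta=0.08),
        ),
    )
    samples = build_cohort(config)
    return config, samples, cohort_frame(samples)
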