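import numpy as np
import pytest

from tgctkit.io_formats import segments_by_sample
from tgctkit.methylation_deconv import (
    correct_beta_matrix,
    estimate_lymphocyte_fraction,
    mixture_fractions,
)
from tgctkit.synthetic_cohort import SimulationConfig, generate_cohort

#: Config of the default study-condition cohort used across tests.
DEFAULT_CONFIG = SimulationConfig(n_samples=120, rng_seed=1)

#: Smaller cohort for structural tests where effect sizes do not matter.
SMALL_CONFIG = SimulationConfig(
    n_samples=30, n_probes=800, n_signature_probes=60, rng_seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(DEFAULT_CONFIG)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_deconv(default_cohort):
    """Lymphocyte estimates and corrected beta for the default cohort."""
    estimates = estimate_lymphocyte_fraction(
        default_cohort.beta, default_cohort.probe_annotation)
    fractions = mixture_fractions(estimates)
    corrected = correct_beta_matrix(
        default_cohort.beta, fractions, default_cohort.probe_annotation)
    return {"estimates": estimates, "fractions": fractions,
            "corrected": corrected}


@pytest.fixture(scope="session")
def default_segments_by_sample(default_cohort):
    return segments_by_sample(default_cohort.segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
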