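import numpy as np
import pytest

from demsa import (
    SampleProfile,
    SimulationConfig,
    builtin_catalog,
    generate_experiment,
)

CODES = builtin_catalog().codes


def make_profile(values, sample_id="s1", treatment="T", replicate=1):
    """Build a 31-substrate profile from a short list, zero-padding the rest."""
    values = list(values)
    responses = {
        code: float(values[i]) if i < len(values) else 0.0
        for i, code in enumerate(CODES)
    }
    return SampleProfile(sample_id, treatment, replicate, responses)


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic experiment (5 treatments x 4 replicates)."""
    return generate_experiment(SimulationConfig(seed=20260927 % 2**31))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
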