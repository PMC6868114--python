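import numpy as np
import pytest

from bimhmm import (
    IndividualEffects,
    TrialDesign,
    reference_parameters,
    simulate_trial,
)


@pytest.fixture
def ref_pop():
    return reference_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_trial(ref_pop):
    """20 subjects x 12 weeks, reference parameters, fixed seed."""
    design = TrialDesign.weekly(n_per_arm=10, duration=12)
    return simulate_trial(ref_pop, design, seed=101)


@pytest.fixture
def zero_eta():
    return IndividualEffects.zero()
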