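"""Shared fixtures: the packaged reference model and a reusable ensemble.

Session scope keeps the (symbolically compiled) reference model and the
random-enzyme ensemble shared across test modules.
"""

import numpy as np
import pytest

from colikinetics import build_reference_model, excess_glucose_model
from colikinetics import ensemble as ens


@pytest.fixture(scope="session")
def ref_model():
    return build_reference_model()


@pytest.fixture(scope="session")
def ref_state(ref_model):
    return ref_model.steady_state()


@pytest.fixture(scope="session")
def excess_model(ref_model):
    return excess_glucose_model(ref_model)


@pytest.fixture(scope="session")
def excess_state(excess_model):
    return excess_model.steady_state()


@pytest.fixture(scope="session")
def small_ensemble(excess_model):
    """120 random enzyme-level steady states under excess glucose."""
    samples = ens.sample_enzyme_levels(excess_model, 120, seed=11)
    return ens.ensemble_steady_states(excess_model, samples)
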