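import warnings

import numpy as np
import pytest

from sced import ClassifierConfig, train_classifier
from sced.graphs import ABGraph, ShortPhaseWarning


def make_graph(phase_a, phase_b, direction=1, id="g"):
    """Build an ABGraph, silencing the short-phase advisory warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortPhaseWarning)
        return ABGraph(id=id, phase_a=phase_a, phase_b=phase_b, direction=direction)


@pytest.fixture(scope="session")
def default_model():
    """One classifier trained on the default synthetic corpus, shared
    across tests (training is deterministic, so sharing is safe)."""
    return train_classifier(ClassifierConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20220427)
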