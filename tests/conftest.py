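"""Shared fixtures: synthetic atlases, scenarios, and a group template.

Everything is generated programmatically; expensive objects (the
32-subject reference template) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from corticograd import Scenario, build_template, compute_fc, generate_atlas
from corticograd.synthetic import generate_reference_timeseries


@pytest.fixture(scope="session")
def atlas100():
    return generate_atlas(100, seed=0)


@pytest.fixture(scope="session")
def default_scenario():
    return Scenario(seed=1)


@pytest.fixture(scope="session")
def template32(atlas100, default_scenario):
    """Group gradient template from the default 32-subject reference set."""
    refs = generate_reference_timeseries(atlas100, default_scenario)
    return build_template([compute_fc(ts) for ts in refs], k=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
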