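"""Shared fixtures: synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from allokin.dmd import build_go_model, run_dmd
from allokin.synthetic import make_allatom_helix, make_two_lobe_toy


@pytest.fixture(scope="session")
def two_lobe():
    return make_two_lobe_toy(20, 20, seed=1)


@pytest.fixture(scope="session")
def two_lobe_ensemble(two_lobe):
    """Moderate-length DMD run of the two-lobe toy (shared to save time)."""
    model = build_go_model(two_lobe)
    return run_dmd(
        model, two_lobe, n_events=200_000, temperature=1.0, nu=1.0,
        snapshot_every=500, seed=11,
    )


@pytest.fixture(scope="session")
def helix12():
    return make_allatom_helix(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
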