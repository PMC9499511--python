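"""Shared fixtures: synthetic datasets are generated programmatically and
expensive fits are session-scoped so several tests can interrogate the same
model."""

from __future__ import annotations

import numpy as np
import pytest

from srptrack.geometry import CellGeometry, theoretical_cytosol_profile
from srptrack.hmm import coarse_grain, fit_hmm
from srptrack.simulate import markov_switching_tracks, wildtype_rate_matrix
from srptrack.spatial import synthetic_membrane_reference

WT_D = (0.05, 1.7, 4.3)
WT_OCC = (0.28, 0.56, 0.16)
WT_DWELL_BOUND = 1.0
WT_DWELL_FREE = 1.9


@pytest.fixture(scope="session")
def geom():
    return CellGeometry()


@pytest.fixture(scope="session")
def cytosol_ref(geom):
    return theoretical_cytosol_profile(geom)


@pytest.fixture(scope="session")
def membrane_ref():
    return synthetic_membrane_reference(n=150_000, seed=424242)


@pytest.fixture(scope="session")
def wildtype_tracks():
    """~42k displacement steps from the wild-type three-state chain."""
    return markov_switching_tracks(
        WT_D,
        rate_matrix=wildtype_rate_matrix(WT_OCC, WT_DWELL_BOUND, WT_DWELL_FREE),
        frame_dt=0.02,
        n_tracks=1450,
        mean_track_len=30,
        loc_error=0.03,
        seed=20_001,
    )


@pytest.fixture(scope="session")
def wildtype_fit(wildtype_tracks):
    """The shared 3-state fit of the wild-type dataset (5 restarts)."""
    model = fit_hmm(wildtype_tracks, K=3, exposure=0.0, n_restarts=5, seed=77)
    return model, coarse_grain(model)
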