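"""Shared fixtures: synthetic sessions reused across test modules.

All sessions are generated at fixed seeds so the suite is deterministic.
"""

import numpy as np
import pytest

from swmaze import generate_session, segment_trajectories, track_from_session
from swmaze.core import LightEffect, NeuronSpec, SessionConfig, gaussian_field


def tuned_roster(n=20, peak=20.0, sigma=8.0, baseline=1.0, **kw):
    """Place cells with field centers spread along the 0-80 cm track."""
    return [NeuronSpec(baseline_rate=baseline,
                       tuning=gaussian_field(80.0 * i / max(n - 1, 1), sigma, peak),
                       **kw)
            for i in range(n)]


@pytest.fixture(scope="session")
def standard_session():
    """40-trial, 20-unit session with mixed tuning (the reference fixture)."""
    neurons = []
    for i in range(20):
        neurons.append(NeuronSpec(
            baseline_rate=1.0,
            tuning=gaussian_field(80.0 * i / 19.0, 8.0, 15.0),
            goal_gain=2.5 if i % 5 == 0 else 1.0,
            preferred_goal="L" if i % 2 else "R",
            theta_kappa=2.0 if i % 4 == 0 else 0.0,
            cell_type="int" if i % 6 == 0 else "pyr",
        ))
    cfg = SessionConfig(n_trials=40, p_error=0.0, seed=11)
    return generate_session(cfg, neurons=neurons)


@pytest.fixture(scope="session")
def standard_track(standard_session):
    return track_from_session(standard_session)


@pytest.fixture(scope="session")
def standard_segments(standard_session, standard_track):
    return segment_trajectories(standard_session, standard_track)


@pytest.fixture(scope="session")
def decoder_session():
    """25 sharply tuned cells, 40 trials: the decoder-recovery fixture."""
    neurons = tuned_roster(25, peak=25.0, sigma=6.0, baseline=0.5)
    cfg = SessionConfig(n_trials=40, seed=2, include_lfp=False)
    return generate_session(cfg, neurons=neurons)


@pytest.fixture(scope="session")
def decoder_setup(decoder_session):
    track = track_from_session(decoder_session)
    segments = segment_trajectories(decoder_session, track)
    return decoder_session, track, segments
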