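"""Shared fixtures: hand-built toy tracks and module-scoped simulations.

Simulated fixtures use reduced frame rates and session lengths so the
whole suite stays fast; the generative model is otherwise the default
configuration.
"""

import numpy as np
import pytest
from hypothesis import settings

import openfield as of

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

ARENA_W, ARENA_H = 50.0, 40.0


def make_track(x, y, fps=10.0, arena_w=ARENA_W, arena_h=ARENA_H, t=None):
    """TrackingSeries from coordinate arrays on a regular time grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if t is None:
        t = np.arange(n) / fps
    return of.TrackingSeries(frame=np.arange(n), t=np.asarray(t, dtype=float),
                             x=x, y=y, fps=fps,
                             arena_w=arena_w, arena_h=arena_h)


def straight_track(n=100, v_cm_s=6.0, fps=10.0, x0=5.0, y0=20.0):
    """Constant-velocity path along +x."""
    step = v_cm_s / fps
    x = x0 + step * np.arange(n)
    return make_track(x, np.full(n, y0), fps=fps)


@pytest.fixture(scope="session")
def default_protocol():
    return of.StimProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """600-s session: one unstimulated and one stimulated 5-min block."""
    return of.StimProtocol(session_len_s=600.0)


@pytest.fixture(scope="session")
def sim_effect_session(default_protocol):
    """Full-length simulated session with the default transient effect
    (suppression gain 0.5 plus stimulation-gated rest switching)."""
    cfg = of.SimConfig(fps=20.0)
    schedule = of.make_schedule(default_protocol)
    track, events, records, truth = of.simulate_session(
        cfg, schedule, seed=11, session_len_s=default_protocol.session_len_s)
    return cfg, track, events, records, truth


@pytest.fixture(scope="session")
def sim_null_session(default_protocol):
    """Same schedule, but stimulation has no effect on the dynamics."""
    cfg = of.SimConfig(fps=20.0, g_stim=1.0, stim_rest_rate=0.0)
    schedule = of.make_schedule(default_protocol)
    track, events, records, truth = of.simulate_session(
        cfg, schedule, seed=12, session_len_s=default_protocol.session_len_s)
    return cfg, track, events, records, truth
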