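"""Synthetic open-field session generator.

The movement model is deliberately the simplest stochastic process that
exhibits every statistical feature the analysis modules measure; it is
*not* a claim about real mouse locomotion.  Its ingredients:

* a mean-reverting (Ornstein-Uhlenbeck) intended speed with mean
  ``mu_v``, reversion rate ``theta`` and noise ``sigma_v`` — this is
  what makes prior-speed conditioning exhibit regression toward the
  mean, the artifact the sham-block correction must cancel;
* a continuous-time behavioral-state chain over {walking, rearing,
  resting, grooming, digging}, each state scaling the intended speed by
  a multiplier (resting/grooming are immobile);
* a persistent random-walk heading with reflection at the walls and an
  optional drift toward the nearest wall (``w_wall``) producing
  thigmotaxis;
* a transient stimulation effect: a gain that relaxes toward ``g_stim``
  with time constant ``tau_on_s`` while light is on and back toward 1
  with ``tau_off_s`` after offset, multiplying the intended speed
  (matching suppression kinetics in which most of the decrease is
  reached within a second), plus an optional stimulation-gated extra
  hazard of switching from a mobile state to resting;
* a long-term drift: ``lambda_drift`` cm/s is added to ``mu_v`` for
  every *previously experienced* stimulated session, persisting whether
  or not the current session is stimulated.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical seed and config give identical
output.  The per-frame dynamics run in a numba-compiled loop fed with
pre-drawn random arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .io_formats import (
    EthogramRecord,
    SessionManifest,
    StimEvent,
    TrackingSeries,
    write_ethogram,
    write_events,
    write_manifest,
    write_tracking,
)
from .protocol import StimProtocol, make_schedule, make_sham_schedule
from .roi_analysis import ROI

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortDesign",
    "MouseSpec",
    "simulate_session",
    "simulate_roi_session",
    "simulate_cohort",
]

#: State coding used by the jitted loop (order matters).
STATE_NAMES = ("walking", "rearing", "resting", "grooming", "digging")
_MOBILE_CODES = (0, 1)


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters; defaults emulate the study's conditions.

    Speed scale: a mean intended walking speed of 6 cm/s reproduces the
    observed ~6 cm/s pre-stimulation speeds; ``g_stim = 0.5`` reproduces
    the roughly twofold transient suppression; ``lambda_drift = 0.15``
    cm/s per stimulated session reproduces the reported session-by-group
    interaction slope.  For an unaffected (wild-type-like) animal set
    ``g_stim = 1`` and ``stim_rest_rate = lambda_drift = 0``.
    """

    arena_w: float = 50.0
    arena_h: float = 40.0
    fps: float = 60.0
    # mean-reverting intended speed
    mu_v: float = 6.0          # cm/s
    theta: float = 0.6         # 1/s reversion rate
    sigma_v: float = 3.0       # cm/s/sqrt(s) noise
    # heading random walk and thigmotaxis
    heading_sigma: float = 1.8  # rad/sqrt(s)
    w_wall: float = 1.0         # cm/s drift toward nearest wall (0 = none)
    # behavioral states: exit rates (1/s) and speed multipliers
    state_exit_rates: tuple = (0.15, 0.5, 0.25, 0.4, 0.4)
    state_multipliers: tuple = (1.0, 0.2, 0.0, 0.0, 0.1)
    # row-stochastic transition targets (diagonal 0), rows in STATE_NAMES order
    state_transitions: tuple = (
        (0.0, 0.25, 0.35, 0.25, 0.15),
        (0.8, 0.0, 0.0667, 0.0667, 0.0666),
        (0.8, 0.0667, 0.0, 0.0667, 0.0666),
        (0.8, 0.0667, 0.0667, 0.0, 0.0666),
        (0.8, 0.0667, 0.0667, 0.0666, 0.0),
    )
    # transient stimulation effect
    g_stim: float = 0.5        # multiplicative suppression gain in [0, 1]
    tau_on_s: float = 0.5
    tau_off_s: float = 1.5
    freq_scaling: bool = False  # scale suppression with pulse_hz / ref_hz
    ref_hz: float = 25.0
    stim_rest_rate: float = 0.3  # extra mobile->resting hazard (1/s) during light
    # long-term facilitation
    lambda_drift: float = 0.15  # cm/s added to mu_v per prior stimulated session

    def __post_init__(self):
        if not (0.0 <= self.g_stim <= 1.0):
            raise ValueError("g_stim must be in [0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if min(self.state_exit_rates) < 0 or self.stim_rest_rate < 0:
            raise ValueError("rates must be non-negative")

    def effective_gain(self, pulse_hz: float) -> float:
        """Suppression gain for a train of the given pulse rate."""
        if not self.freq_scaling:
            return self.g_stim
        depth = (1.0 - self.g_stim) * min(pulse_hz / self.ref_hz, 1.0)
        return 1.0 - depth


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters of one emitted session."""

    mu_v: float
    g_stim: float
    lambda_term: float   # drift already accumulated (cm/s)
    seed_key: tuple
    states: np.ndarray = field(repr=False, default=None)  # type: ignore


@dataclass(frozen=True)
class MouseSpec:
    mouse_id: str
    genotype: str = "SERT-Cre"   # "SERT-Cre" or "WT"
    group: str = "G1"            # "G1", "G2" or "none"


@dataclass(frozen=True)
class CohortDesign:
    """Which sessions each group receives stimulation in (1-based)."""

    mice: tuple
    n_sessions: int
    stim_sessions: dict  # group -> iterable of 1-based session indices

    @classmethod
    def longterm_default(cls, n_sessions: int = 24,
                         g2_start: int = 24) -> "CohortDesign":
        """The two-group long-term design: G1 stimulated from session 1,
        G2 only from ``g2_start`` on; each group 3 affected + 2 control
        mice."""
        mice = tuple(
            [MouseSpec(f"g1m{i}", "SERT-Cre", "G1") for i in range(1, 4)]
            + [MouseSpec(f"g1w{i}", "WT", "G1") for i in range(1, 3)]
            + [MouseSpec(f"g2m{i}", "SERT-Cre", "G2") for i in range(1, 4)]
            + [MouseSpec(f"g2w{i}", "WT", "G2") for i in range(1, 3)]
        )
        return cls(
            mice=mice,
            n_sessions=n_sessions,
            stim_sessions={
                "G1": tuple(range(1, n_sessions + 1)),
                "G2": tuple(range(g2_start, n_sessions + 1)),
            },
        )


# ---------------------------------------------------------------------------
# Jitted per-frame dynamics
# ---------------------------------------------------------------------------


@njit(cache=True)
def _step_loop(n, dt, mu, theta, sigma, g_target, tau_on, tau_off,
               heading_sigma, w_wall, arena_w, arena_h,
               exit_rates, mults, trans_cum, rest_rate,
               stim_mask, roi_mode, rx0, ry0, rx1, ry1,
               x_init, y_init, h_init, s_init, v_init,
               z_v, z_h, u_fire, u_pick):
    x = np.empty(n)
    y = np.empty(n)
    state = np.zeros(n, np.int8)
    gain = np.empty(n)
    stim_on = np.zeros(n, np.bool_)
    sqdt = np.sqrt(dt)

    x[0] = x_init
    y[0] = y_init
    h = h_init
    v_ou = v_init
    g = 1.0
    s_cur = s_init
    state[0] = s_init
    gain[0] = 1.0

    for i in range(1, n):
        if roi_mode:
            lit = (rx0 <= x[i - 1]) and (x[i - 1] < rx1) \
                and (ry0 <= y[i - 1]) and (y[i - 1] < ry1)
        else:
            lit = stim_mask[i]
        stim_on[i] = lit

        # state chain: base exit hazard plus stimulation-gated hazard to rest
        boost = rest_rate if (lit and s_cur <= 1) else 0.0
        total = exit_rates[s_cur] + boost
        if u_fire[i] < total * dt:
            if boost > 0.0 and u_fire[i] < boost * dt:
                s_cur = 2  # resting
            else:
                u = u_pick[i]
                row = trans_cum[s_cur]
                nxt = 0
                while row[nxt] < u and nxt < 4:
                    nxt += 1
                s_cur = nxt
        state[i] = s_cur

        # mean-reverting intended speed
        v_ou = v_ou + theta * (mu - v_ou) * dt + sigma * sqdt * z_v[i]
        if v_ou < 0.0:
            v_ou = 0.0

        # transient gain relaxation
        if lit:
            g = g + dt / tau_on * (g_target - g)
        else:
            g = g + dt / tau_off * (1.0 - g)
        gain[i] = g

        speed = v_ou * mults[s_cur] * g

        # heading persistence + step
        h = h + heading_sigma * sqdt * z_h[i]
        nx = x[i - 1] + np.cos(h) * speed * dt
        ny = y[i - 1] + np.sin(h) * speed * dt

        # thigmotaxis: drift toward the nearest wall
        if w_wall > 0.0:
            dl = x[i - 1]
            dr = arena_w - x[i - 1]
            db = y[i - 1]
            dtp = arena_h - y[i - 1]
            m = min(min(dl, dr), min(db, dtp))
            if m > 0.5:  # no pull when already at a wall
                step = w_wall * dt
                if dl == m:
                    nx -= step
                elif dr == m:
                    nx += step
                elif db == m:
                    ny -= step
                else:
                    ny += step

        # reflect at walls (heading bounces too)
        if nx < 0.0:
            nx = -nx
            h = np.pi - h
        elif nx > arena_w:
            nx = 2.0 * arena_w - nx
            h = np.pi - h
        if ny < 0.0:
            ny = -ny
            h = -h
        elif ny > arena_h:
            ny = 2.0 * arena_h - ny
            h = -h
        # guard against double reflection overshoot at corners
        if nx < 0.0:
            nx = 0.0
        if nx > arena_w:
            nx = arena_w
        if ny < 0.0:
            ny = 0.0
        if ny > arena_h:
            ny = arena_h

        x[i] = nx
        y[i] = ny

    return x, y, state, gain, stim_on


# ---------------------------------------------------------------------------
# Session-level drivers
# ---------------------------------------------------------------------------


def _seed_key(seed) -> tuple:
    """Flatten an int or tuple-of-ints seed into a SeedSequence key."""
    if isinstance(seed, (tuple, list)):
        out = []
        for s in seed:
            out.extend(_seed_key(s))
        return tuple(out)
    return (int(seed),)


def _transition_cumsum(cfg: SimConfig) -> np.ndarray:
    rows = np.array(cfg.state_transitions, dtype=float)
    rows = rows / rows.sum(axis=1, keepdims=True)
    return np.cumsum(rows, axis=1)


def _stationary_state_probs(cfg: SimConfig) -> np.ndarray:
    """Stationary distribution of the behavioral-state chain.

    Solves pi Q = 0 for the continuous-time generator built from the
    exit rates and jump matrix; if every exit rate is zero the chain
    never leaves walking.
    """
    r = np.array(cfg.state_exit_rates, dtype=float)
    if np.all(r == 0):
        return np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    P = np.array(cfg.state_transitions, dtype=float)
    P = P / P.sum(axis=1, keepdims=True)
    Q = (P * r[:, None]) - np.diag(r)
    A = np.vstack([Q.T, np.ones(len(r))])
    b = np.r_[np.zeros(len(r)), 1.0]
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _run(cfg: SimConfig, session_len_s: float, stim_mask, roi, g_target, rng):
    n = int(round(session_len_s * cfg.fps))
    dt = 1.0 / cfg.fps
    z_v = rng.standard_normal(n)
    z_h = rng.standard_normal(n)
    u_fire = rng.random(n)
    u_pick = rng.random(n)
    x0 = rng.uniform(0.25, 0.75) * cfg.arena_w
    y0 = rng.uniform(0.25, 0.75) * cfg.arena_h
    h0 = rng.uniform(0.0, 2.0 * np.pi)
    # start from the stationary law so early blocks are statistically
    # exchangeable with late ones (no burn-in transient)
    s0 = int(rng.choice(len(STATE_NAMES), p=_stationary_state_probs(cfg)))
    sd_v = cfg.sigma_v / np.sqrt(2.0 * cfg.theta) if cfg.theta > 0 else 0.0
    v0 = max(0.0, rng.normal(cfg.mu_v, sd_v))
    if roi is None:
        roi_mode = False
        rx0 = ry0 = rx1 = ry1 = 0.0
        mask = stim_mask if stim_mask is not None else np.zeros(n, np.bool_)
    else:
        roi_mode = True
        rx0, ry0 = roi.x0, roi.y0
        rx1, ry1 = roi.x0 + roi.w, roi.y0 + roi.h
        mask = np.zeros(n, np.bool_)
    x, y, state, gain, stim_on = _step_loop(
        n, dt, cfg.mu_v, cfg.theta, cfg.sigma_v, g_target,
        cfg.tau_on_s, cfg.tau_off_s, cfg.heading_sigma, cfg.w_wall,
        cfg.arena_w, cfg.arena_h,
        np.array(cfg.state_exit_rates, dtype=float),
        np.array(cfg.state_multipliers, dtype=float),
        _transition_cumsum(cfg), cfg.stim_rest_rate,
        mask, roi_mode, rx0, ry0, rx1, ry1,
        x0, y0, h0, s0, v0, z_v, z_h, u_fire, u_pick,
    )
    t = np.arange(n) / cfg.fps
    track = TrackingSeries(frame=np.arange(n), t=t, x=x, y=y,
                           fps=cfg.fps, arena_w=cfg.arena_w,
                           arena_h=cfg.arena_h)
    return track, state, stim_on


def _states_to_records(state: np.ndarray, fps: float) -> list[EthogramRecord]:
    dt = 1.0 / fps
    records = []
    start = 0
    for i in range(1, len(state) + 1):
        if i == len(state) or state[i] != state[start]:
            records.append(EthogramRecord(
                onset_s=start * dt, offset_s=i * dt,
                state=STATE_NAMES[state[start]],
            ))
            start = i
    return records


def _stim_mask_from_schedule(schedule, n, fps) -> np.ndarray:
    t = np.arange(n) / fps
    mask = np.zeros(n, np.bool_)
    for ev in schedule:
        if ev.kind == "real":
            mask |= (t >= ev.onset_s) & (t < ev.offset_s)
    return mask


def simulate_session(
    cfg: SimConfig,
    schedule: Sequence[StimEvent],
    seed,
    session_len_s: float | None = None,
):
    """Simulate one open-field session under a train schedule.

    Returns ``(TrackingSeries, events, ethogram_records, GroundTruth)``.
    The events are the real trains of the schedule (shams pass through
    untouched but do not drive the gain).  ``seed`` may be an int or a
    tuple of ints (entropy key).
    """
    if session_len_s is None:
        session_len_s = max((e.offset_s for e in schedule), default=300.0)
        session_len_s = float(np.ceil(session_len_s / 300.0) * 300.0)
    n = int(round(session_len_s * cfg.fps))
    g_target = cfg.effective_gain(
        schedule[0].pulse_hz if schedule else cfg.ref_hz)
    key = _seed_key(seed)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    mask = _stim_mask_from_schedule(schedule, n, cfg.fps)
    track, state, _ = _run(cfg, session_len_s, mask, None, g_target, rng)
    records = _states_to_records(state, cfg.fps)
    truth = GroundTruth(mu_v=cfg.mu_v, g_stim=g_target, lambda_term=0.0,
                        seed_key=key, states=state)
    return track, list(schedule), records, truth


def simulate_roi_session(
    cfg: SimConfig,
    roi: ROI,
    seed,
    session_len_s: float = 900.0,
    stimulated: bool = True,
    pulse_hz: float = 25.0,
    amplitude_mw: float = 20.0,
):
    """Simulate a closed-loop ROI conditioning session.

    Light is on exactly while the centroid is inside the ROI (when
    ``stimulated``); no attraction or repulsion toward the ROI is ever
    injected, so any occupancy change the analysis finds is produced by
    the slowing dynamics alone.  The returned events are one continuous
    train per ROI visit.
    """
    roi.validate_inside(cfg.arena_w, cfg.arena_h)
    g_target = cfg.effective_gain(pulse_hz) if stimulated else 1.0
    run_cfg = cfg if stimulated else replace(
        cfg, g_stim=1.0, stim_rest_rate=0.0)
    key = _seed_key(seed)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    track, state, stim_on = _run(run_cfg, session_len_s, None, roi,
                                 g_target, rng)
    # events = maximal in-ROI intervals, from the same membership test
    inside = roi.contains(track.x, track.y)
    events = []
    d = np.diff(inside.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if inside[0]:
        starts.insert(0, 0)
    if inside[-1]:
        ends.append(len(track))
    for i0, i1 in zip(starts, ends):
        if stimulated:
            events.append(StimEvent(
                onset_s=float(track.t[i0]),
                duration_s=float((i1 - i0) / cfg.fps),
                pulse_hz=pulse_hz, amplitude_mw=amplitude_mw,
                kind="real", block_idx=0,
            ))
    truth = GroundTruth(mu_v=cfg.mu_v, g_stim=g_target, lambda_term=0.0,
                        seed_key=key, states=state)
    return track, events, truth


def iter_cohort_sessions(
    cfg: SimConfig,
    design: CohortDesign,
    seed,
    protocol: StimProtocol | None = None,
):
    """Yield simulated cohort sessions in memory (no files).

    Same generative model and seeding as :func:`simulate_cohort`; each
    yielded dict plugs straight into ``longterm.table_from_sessions``.
    """
    if protocol is None:
        protocol = StimProtocol()
    real_schedule = make_schedule(protocol)
    sham_schedule = make_sham_schedule(protocol)
    for mi, mouse in enumerate(design.mice):
        stim_set = set(design.stim_sessions.get(mouse.group, ()))
        affected = mouse.genotype == "SERT-Cre"
        n_prior_stim = 0
        for sess in range(1, design.n_sessions + 1):
            stim_today = sess in stim_set
            mu = cfg.mu_v + (cfg.lambda_drift * n_prior_stim if affected else 0.0)
            sess_cfg = replace(
                cfg, mu_v=mu,
                g_stim=cfg.g_stim if affected else 1.0,
                stim_rest_rate=cfg.stim_rest_rate if affected else 0.0,
            )
            schedule = real_schedule if stim_today else sham_schedule
            track, events, records, truth = simulate_session(
                sess_cfg, schedule, seed=(seed, mi, sess),
                session_len_s=protocol.session_len_s,
            )
            yield {
                "mouse_id": mouse.mouse_id,
                "genotype": mouse.genotype,
                "group": mouse.group,
                "session_idx": sess,
                "track": track,
                "events": events,
                "ethogram": records,
                "truth": truth,
                "mu_v": mu,
                "stimulated": stim_today,
                "block_len_s": protocol.block_len_s,
            }
            if stim_today:
                n_prior_stim += 1


def simulate_cohort(
    cfg: SimConfig,
    design: CohortDesign,
    out_dir,
    seed,
    protocol: StimProtocol | None = None,
):
    """Simulate a multi-session cohort and write the full file suite.

    For every mouse-session, ``mu_v`` is incremented by ``lambda_drift``
    per stimulated session the mouse has already experienced (the drift
    persists regardless of same-day stimulation).  Wild-type mice get no
    transient effect and no drift.  Stimulated sessions carry the real
    schedule in their events file; unstimulated sessions carry the
    phase-matched sham schedule, so pre/post windows remain defined.

    Writes tracking/events/ethogram CSVs, ``manifest.csv`` and a
    ``ground_truth.csv`` sidecar under ``out_dir``; returns
    ``(SessionManifest, ground_truth_dataframe)``.
    """
    import pandas as pd

    if protocol is None:
        protocol = StimProtocol()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for s in iter_cohort_sessions(cfg, design, seed, protocol):
        stem = f"{s['mouse_id']}_s{s['session_idx']:02d}"
        write_tracking(out_dir / f"{stem}_tracking.csv", s["track"])
        write_events(out_dir / f"{stem}_events.csv", s["events"])
        write_ethogram(out_dir / f"{stem}_ethogram.csv", s["ethogram"])
        rows.append({
            "mouse_id": s["mouse_id"],
            "genotype": s["genotype"],
            "group": s["group"],
            "session_idx": s["session_idx"],
            "tracking_path": str(out_dir / f"{stem}_tracking.csv"),
            "events_path": str(out_dir / f"{stem}_events.csv"),
            "ethogram_path": str(out_dir / f"{stem}_ethogram.csv"),
        })
        truth_rows.append({
            "mouse_id": s["mouse_id"],
            "session_idx": s["session_idx"],
            "mu_v": s["mu_v"],
            "g_stim": s["truth"].g_stim if s["stimulated"] else 1.0,
            "stimulated": s["stimulated"],
            "lambda_term": s["mu_v"] - cfg.mu_v,
        })
    manifest = SessionManifest(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)
    write_manifest(out_dir / "manifest.csv", manifest)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth
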