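"""Behavioral-state probability analysis around stimulation.

Ethogram records are non-overlapping scored intervals; not all time is
scored, so state probabilities may sum to less than 1.  States group
into mobile (walking, rearing, jumping) and immobile (resting, digging,
grooming, scratching).  Records straddling an analysis window
contribute in proportion to their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    ETHOGRAM_STATES,
    IMMOBILE_STATES,
    MOBILE_STATES,
    EthogramRecord,
    StimEvent,
    ValidationError,
)

__all__ = [
    "StateProbabilities",
    "MOBILE_STATES",
    "IMMOBILE_STATES",
    "state_probability",
    "mobility_trace",
    "state_at",
]


@dataclass(frozen=True)
class StateProbabilities:
    """Scored-time fraction per state within a set of windows."""

    probabilities: dict  # state -> probability
    total_window_s: float

    def __post_init__(self):
        for s, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0 + 1e-12):
                raise ValidationError(f"probability out of range for {s}: {p}")
        if sum(self.probabilities.values()) > 1.0 + 1e-9:
            raise ValidationError("state probabilities sum above 1")

    def grouped(self, states: Sequence[str]) -> float:
        return float(sum(self.probabilities.get(s, 0.0) for s in states))

    @property
    def p_mobile(self) -> float:
        return self.grouped(MOBILE_STATES)

    @property
    def p_immobile(self) -> float:
        return self.grouped(IMMOBILE_STATES)


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def state_probability(
    records: Sequence[EthogramRecord],
    windows: Sequence[tuple[float, float]],
    states: Sequence[str] = ETHOGRAM_STATES,
) -> StateProbabilities:
    """Probability of each state within the pooled windows.

    probability = scored time in state inside the windows / total window
    time.  Window-straddling records contribute their overlap only.
    """
    total = float(sum(b - a for a, b in windows))
    if total <= 0:
        raise ValidationError("windows have zero total length")
    acc = {s: 0.0 for s in states if s != "unscored"}
    for rec in records:
        if rec.state not in acc:
            continue
        for a, b in windows:
            acc[rec.state] += _overlap(rec.onset_s, rec.offset_s, a, b)
    return StateProbabilities(
        probabilities={s: v / total for s, v in acc.items()},
        total_window_s=total,
    )


def state_at(records: Sequence[EthogramRecord], t: float) -> str:
    """State scored at time t (records are half-open); 'unscored' if none."""
    for rec in records:
        if rec.onset_s <= t < rec.offset_s:
            return rec.state
    return "unscored"


def mobility_trace(
    records: Sequence[EthogramRecord],
    events: Sequence[StimEvent],
    t_range: tuple[float, float] = (-5.0, 10.0),
    bin_s: float = 0.5,
):
    """P(mobile) and P(immobile) as functions of time from onset.

    For each time bin (sampled at its centre relative to each event's
    onset) the fractions of events whose scored state is mobile or
    immobile are returned; unscored time counts in neither, so the two
    traces sum to at most 1 at every bin.

    Returns ``(t_rel, p_mobile, p_immobile, n_events)``.
    """
    if not events:
        raise ValidationError("need at least one event")
    edges = np.arange(t_range[0], t_range[1] + bin_s / 2, bin_s)
    t_rel = (edges[:-1] + edges[1:]) / 2.0
    recs = sorted(records, key=lambda r: r.onset_s)
    onsets = np.array([r.onset_s for r in recs])
    offsets = np.array([r.offset_s for r in recs])
    codes = np.array([1 if r.state in MOBILE_STATES
                      else (-1 if r.state in IMMOBILE_STATES else 0)
                      for r in recs])
    mobile = np.zeros(len(t_rel))
    immobile = np.zeros(len(t_rel))
    for ev in events:
        ts = ev.onset_s + t_rel
        idx = np.searchsorted(onsets, ts, side="right") - 1
        valid = (idx >= 0) & (ts < offsets[np.clip(idx, 0, None)])
        c = np.where(valid, codes[np.clip(idx, 0, None)], 0)
        mobile += c == 1
        immobile += c == -1
    n = len(events)
    return t_rel, mobile / n, immobile / n, n
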