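"""ROI-contingent stimulation metrics.

Closed-loop place conditioning delivers light for the entire excursion
of the body centroid inside a rectangle (default 13 x 10.5 cm, centered
in the arena).  Occupancy alone cannot distinguish a place preference
from locomotor slowing; the dissociation comes from the entry and exit
rates:

* ``entry_rate = n_entries / time spent outside the ROI``
* ``exit_rate  = n_exits  / time spent inside the ROI``

A pure slowing effect inflates occupancy and depresses the exit rate
while leaving the entry rate unchanged; a place preference would also
raise the entry rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import SessionManifest, TrackingSeries, ValidationError
from .kinematics import SpeedSeries

__all__ = [
    "ROI",
    "ROISessionMetrics",
    "SESSION_LABELS",
    "roi_visits",
    "roi_metrics",
    "roi_protocol_table",
]

#: The five sessions of the conditioning protocol, in order: baseline,
#: three stimulated days, and a final unstimulated test day.
SESSION_LABELS = ("pre", "ST1", "ST2", "ST3", "post")


@dataclass(frozen=True)
class ROI:
    """Conditioning rectangle ``[x0, x0+w) x [y0, y0+h)`` in cm."""

    x0: float
    y0: float
    w: float = 13.0
    h: float = 10.5

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValidationError("ROI width and height must be positive")

    @classmethod
    def centered(cls, arena_w: float = 50.0, arena_h: float = 40.0,
                 w: float = 13.0, h: float = 10.5) -> "ROI":
        return cls(x0=(arena_w - w) / 2.0, y0=(arena_h - h) / 2.0, w=w, h=h)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x >= self.x0) & (x < self.x0 + self.w)
                & (y >= self.y0) & (y < self.y0 + self.h))

    def validate_inside(self, arena_w: float, arena_h: float) -> None:
        if (self.x0 < 0 or self.y0 < 0
                or self.x0 + self.w > arena_w or self.y0 + self.h > arena_h):
            raise ValidationError("ROI extends outside the arena")


@dataclass(frozen=True)
class ROISessionMetrics:
    """Per-session ROI summary; rates are NaN when their denominator is 0."""

    occupancy_s: float
    n_entries: int
    n_exits: int
    entry_rate: float      # 1/s, n_entries / time outside
    exit_rate: float       # 1/s, n_exits / time inside
    speed_inside: float    # cm/s
    speed_outside: float   # cm/s
    session_len_s: float
    label: str | None = None


def roi_visits(track: TrackingSeries, roi: ROI,
               min_dwell_s: float = 0.0) -> list[tuple[float, float]]:
    """Maximal ``[entry_t, exit_t)`` intervals with the centroid in the ROI.

    A visit open at session end is closed at the last timestamp plus one
    frame period.  ``min_dwell_s`` (default 0: no debounce) drops visits
    shorter than the given dwell, for noisy tracking.
    """
    inside = roi.contains(track.x, track.y)
    if not inside.any():
        return []
    d = np.diff(inside.astype(np.int8))
    entries = list(np.flatnonzero(d == 1) + 1)
    exits = list(np.flatnonzero(d == -1) + 1)
    if inside[0]:
        entries.insert(0, 0)
    end_t = float(track.t[-1]) + 1.0 / track.fps
    visits = []
    for k, i0 in enumerate(entries):
        t_in = float(track.t[i0])
        t_out = float(track.t[exits[k]]) if k < len(exits) else end_t
        if t_out - t_in >= min_dwell_s:
            visits.append((t_in, t_out))
    return visits


def roi_metrics(
    visits: Sequence[tuple[float, float]],
    track: TrackingSeries,
    speed: SpeedSeries,
    session_len_s: float,
    roi: ROI | None = None,
    label: str | None = None,
) -> ROISessionMetrics:
    """Session-level ROI metrics from a visit list.

    Entries are transitions into the ROI after session start; exits are
    transitions out before session end (a visit that begins at t=0 is
    not an entry, one running to the end is not an exit), so
    ``n_entries - n_exits`` is always in {-1, 0, 1}.
    """
    if session_len_s <= 0:
        raise ValidationError("session_len_s must be positive")
    occupancy = float(sum(b - a for a, b in visits))
    t0 = float(track.t[0])
    end_t = float(track.t[-1]) + 1.0 / track.fps
    n_entries = sum(1 for a, _ in visits if a > t0)
    n_exits = sum(1 for _, b in visits if b < end_t)
    time_out = session_len_s - occupancy
    entry_rate = n_entries / time_out if time_out > 0 else np.nan
    exit_rate = n_exits / occupancy if occupancy > 0 else np.nan

    if roi is not None:
        inside = roi.contains(track.x, track.y)
    else:
        inside = np.zeros(len(track), dtype=bool)
        for a, b in visits:
            inside |= (track.t >= a) & (track.t < b)
    v = speed.v
    ok = ~np.isnan(v)
    v_in = v[inside & ok]
    v_out = v[~inside & ok]
    return ROISessionMetrics(
        occupancy_s=occupancy,
        n_entries=n_entries,
        n_exits=n_exits,
        entry_rate=entry_rate,
        exit_rate=exit_rate,
        speed_inside=float(v_in.mean()) if v_in.size else np.nan,
        speed_outside=float(v_out.mean()) if v_out.size else np.nan,
        session_len_s=session_len_s,
        label=label,
    )


def roi_protocol_table(
    manifest: SessionManifest,
    roi: ROI,
    session_len_s: float,
    labels: Sequence[str] = SESSION_LABELS,
    filter_len: int = 5,
) -> pd.DataFrame:
    """Per-mouse-per-session ROI metrics across the 5-day protocol.

    Sessions in the manifest are mapped to labels by ``session_idx``
    (1 -> first label, ...).  Returns a tidy DataFrame with one row per
    mouse-session plus genotype; aggregate with
    ``df.groupby(["genotype", "label"])`` for cohort means.
    """
    from .io_formats import read_events, read_tracking
    from .kinematics import compute_speed

    rows = []
    for _, r in manifest.table.iterrows():
        idx = int(r["session_idx"])
        if not (1 <= idx <= len(labels)):
            raise ValidationError(
                f"session_idx {idx} has no label (expected 1..{len(labels)})"
            )
        track = read_tracking(r["tracking_path"])
        speed = compute_speed(track, filter_len=filter_len)
        visits = roi_visits(track, roi)
        m = roi_metrics(visits, track, speed, session_len_s, roi=roi,
                        label=labels[idx - 1])
        rows.append({
            "mouse_id": r["mouse_id"],
            "genotype": r["genotype"],
            "session_idx": idx,
            "label": m.label,
            "occupancy_s": m.occupancy_s,
            "entry_rate": m.entry_rate,
            "exit_rate": m.exit_rate,
            "speed_inside": m.speed_inside,
            "speed_outside": m.speed_outside,
        })
    return pd.DataFrame(rows)
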