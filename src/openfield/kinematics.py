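"""Speed computation, median smoothing, and peri-event windowing.

Speed at frame ``i`` is the centroid displacement from frame ``i-1`` to
``i`` times the frame rate; the first frame (and any frame following a
tracking gap) is undefined (NaN).  The raw speed is then smoothed with a
five-frame running median; at the series boundaries the window shrinks
symmetrically instead of padding, so the filter is deterministic and
never invents data.

Peri-event statistics use half-open windows relative to stimulation
onset: pre = ``[-2, 0)`` s and post = ``[+1, +3)`` s by default.  A frame
belongs to a window when its timestamp falls inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import StimEvent, TrackingSeries, ValidationError

__all__ = [
    "SpeedSeries",
    "WindowSpec",
    "EventStats",
    "compute_speed",
    "event_windows",
    "peri_event_trace",
    "cohort_peri_event_trace",
]


@dataclass(frozen=True)
class SpeedSeries:
    """Per-frame smoothed speed (cm/s); NaN marks undefined frames."""

    t: np.ndarray
    v: np.ndarray
    filter_len: int

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if len(self.t) != len(self.v):
            raise ValidationError("t and v must have equal length")
        valid = self.v[~np.isnan(self.v)]
        if valid.size and valid.min() < 0:
            raise ValidationError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class WindowSpec:
    """Pre/post analysis windows relative to event onset (seconds).

    Defaults: pre ``[-2, 0)``, post ``[+1, +3)``.
    """

    pre_start_s: float = -2.0
    pre_len_s: float = 2.0
    post_start_s: float = 1.0
    post_len_s: float = 2.0

    def __post_init__(self):
        if self.pre_len_s <= 0 or self.post_len_s <= 0:
            raise ValidationError("window lengths must be positive")
        if self.pre_start_s + self.pre_len_s > 0:
            raise ValidationError("pre window must end at or before onset")
        if self.pre_start_s + self.pre_len_s > self.post_start_s:
            raise ValidationError("pre and post windows must not overlap")

    def pre_interval(self, onset: float) -> tuple[float, float]:
        a = onset + self.pre_start_s
        return a, a + self.pre_len_s

    def post_interval(self, onset: float) -> tuple[float, float]:
        a = onset + self.post_start_s
        return a, a + self.post_len_s


@dataclass(frozen=True)
class EventStats:
    """Pre/post mean speeds for one event; ``delta = v_post - v_pre``."""

    event: StimEvent
    v_pre: float
    v_post: float
    zone_at_onset: str | None = None
    block_idx: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.block_idx is None:
            object.__setattr__(self, "block_idx", self.event.block_idx)

    @property
    def delta(self) -> float:
        return self.v_post - self.v_pre

    def with_zone(self, zone: str) -> "EventStats":
        return EventStats(self.event, self.v_pre, self.v_post, zone, self.block_idx)


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------


def _shrunken_median(v: np.ndarray, filter_len: int) -> np.ndarray:
    """Running median with a symmetric window that shrinks at the ends.

    NaNs (gaps) are excluded from each window's median, but a NaN centre
    stays NaN so undefined frames never acquire a value.
    """
    import warnings

    n = len(v)
    k = filter_len // 2
    out = np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        if n >= filter_len:
            sw = np.lib.stride_tricks.sliding_window_view(v, filter_len)
            out[k:n - k] = np.nanmedian(sw, axis=1)
        for i in range(min(k, n)):          # shrunken boundary windows
            h = min(i, n - 1 - i)
            out[i] = np.nanmedian(v[i - h:i + h + 1])
        for i in range(max(n - k, k), n):
            h = min(i, n - 1 - i)
            out[i] = np.nanmedian(v[i - h:i + h + 1])
    out[np.isnan(v)] = np.nan
    return out


def compute_speed(track: TrackingSeries, filter_len: int = 5) -> SpeedSeries:
    """Frame-wise speed from centroid displacement, median-smoothed.

    ``v[i] = ||p[i] - p[i-1]|| * fps``; the first frame, and every frame
    immediately after a flagged tracking gap, is NaN.  The median filter
    (default five frames) removes single-frame tracking glitches.
    """
    if filter_len % 2 != 1 or filter_len < 1:
        raise ValidationError(f"filter_len must be odd and >= 1, got {filter_len}")
    n = len(track)
    if n < filter_len:
        raise ValidationError(
            f"need at least filter_len={filter_len} frames, got {n}"
        )
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    v = np.full(n, np.nan)
    v[1:] = np.hypot(dx, dy) * track.fps
    # speed is undefined across a gap: frame i is the arrival frame of
    # the interval (i-1, i), so gap_after[i-1] masks v[i]
    v[1:][track.gap_after[:-1]] = np.nan
    return SpeedSeries(t=track.t, v=_shrunken_median(v, filter_len),
                       filter_len=filter_len)


# ---------------------------------------------------------------------------
# Peri-event windows
# ---------------------------------------------------------------------------


def _window_mean(speed: SpeedSeries, a: float, b: float) -> float:
    """Mean speed over frames with t in [a, b); NaN if any frame undefined."""
    sel = (speed.t >= a) & (speed.t < b)
    if not sel.any():
        return np.nan
    vals = speed.v[sel]
    if np.isnan(vals).any():
        return np.nan
    return float(vals.mean())


def event_windows(
    speed: SpeedSeries,
    events: Sequence[StimEvent],
    spec: WindowSpec = WindowSpec(),
    block_len_s: float | None = None,
    zone_at: Callable[[float], str] | None = None,
) -> list[EventStats]:
    """Per-event pre/post mean speeds.

    Events are dropped (and counted via the ``n_dropped`` attribute of
    the returned list) when a window falls outside the session, crosses
    a block boundary (if ``block_len_s`` given), or overlaps a tracking
    gap.  ``zone_at(onset)`` optionally tags each event with the arena
    zone at stimulation onset.

    Raises :class:`ValidationError` when no event survives, which almost
    always means the window spec or schedule does not match the data.
    """
    t0, t1 = float(speed.t[0]), float(speed.t[-1])
    out: list[EventStats] = []
    dropped = 0
    for ev in events:
        (a0, a1) = spec.pre_interval(ev.onset_s)
        (b0, b1) = spec.post_interval(ev.onset_s)
        if a0 < t0 or b1 > t1 + 1e-9:
            dropped += 1
            continue
        if block_len_s is not None:
            blocks = {int(np.floor(t / block_len_s)) for t in
                      (a0, a1 - 1e-9, b0, b1 - 1e-9)}
            if len(blocks) > 1:
                dropped += 1
                continue
        v_pre = _window_mean(speed, a0, a1)
        v_post = _window_mean(speed, b0, b1)
        if np.isnan(v_pre) or np.isnan(v_post):
            dropped += 1
            continue
        zone = zone_at(ev.onset_s) if zone_at is not None else None
        out.append(EventStats(ev, v_pre, v_post, zone))
    if not out:
        raise ValidationError(
            f"no usable events (all {dropped} dropped): check that the "
            "window spec and schedule match the session"
        )

    class _StatsList(list):
        pass

    result = _StatsList(out)
    result.n_dropped = dropped
    return result


def peri_event_trace(
    speed: SpeedSeries,
    events: Sequence[StimEvent],
    t_range: tuple[float, float] = (-5.0, 10.0),
    fps: float | None = None,
):
    """Event-aligned mean speed trace.

    Returns ``(t_rel, mean, sem, n_events)`` where ``t_rel`` is time from
    stimulation onset sampled at the frame period.  Frames falling in
    tracking gaps are excluded per time bin.
    """
    if not events:
        raise ValidationError("need at least one event")
    if fps is None:
        dts = np.diff(speed.t)
        fps = 1.0 / float(np.median(dts))
    dt = 1.0 / fps
    offsets = np.arange(int(np.floor(t_range[0] / dt)),
                        int(np.ceil(t_range[1] / dt)) + 1)
    t_rel = offsets * dt
    rows = np.full((len(events), len(offsets)), np.nan)
    for j, ev in enumerate(events):
        # nearest frame to onset; event-relative sampling on the frame grid
        i0 = int(np.searchsorted(speed.t, ev.onset_s))
        if i0 >= len(speed.t):
            continue
        idx = i0 + offsets
        ok = (idx >= 0) & (idx < len(speed.t))
        rows[j, ok] = speed.v[idx[ok]]
    import warnings as _warnings

    n = np.sum(~np.isnan(rows), axis=0)
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows, axis=0)
        sd = np.nanstd(rows, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return t_rel, mean, sem, len(events)


def cohort_peri_event_trace(per_mouse_traces):
    """Average per-mouse traces (equal time grids) with across-mouse SEM."""
    arrs = [m for (_, m, _, _) in per_mouse_traces]
    t_rel = per_mouse_traces[0][0]
    stack = np.vstack(arrs)
    mean = np.nanmean(stack, axis=0)
    sem = (np.nanstd(stack, axis=0, ddof=1) / np.sqrt(stack.shape[0])
           if stack.shape[0] > 1 else np.full_like(mean, np.nan))
    return t_rel, mean, sem, stack.shape[0]
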