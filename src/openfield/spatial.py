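"""Arena zone geometry and thigmotaxis measures.

The arena is partitioned into four zones:

* **edges** — a thin strip (default 2 cm) along every wall, shown in
  gray in occupancy maps and excluded from center/periphery statistics
  by default;
* **corners** — the four ``band x band`` squares at the corners
  (default 10 cm), minus the edge strip;
* **periphery** — the remaining band along the walls;
* **center** — the interior rectangle.

Zone boundaries are resolved with strict ``<`` comparisons against the
distance-to-wall thresholds, so every point maps to exactly one zone
(a point exactly at a threshold belongs to the more interior zone).

The normalized center distance of a point is its distance from the
arena's geometric center divided by the distance from the center to the
wall along the same ray, which equals
``max(|x - cx| / (W/2), |y - cy| / (H/2))`` for a rectangle; wall
midpoints and corners both map to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import TrackingSeries, ValidationError
from .kinematics import EventStats, SpeedSeries

__all__ = [
    "ZoneMap",
    "ZONES",
    "classify_zone",
    "occupancy_fractions",
    "center_distance",
    "center_distance_cdf",
    "center_travel_fraction",
    "zone_conditioned_effects",
]

ZONES = ("center", "periphery", "corners", "edges")


@dataclass(frozen=True)
class ZoneMap:
    """Arena partition parameters (cm)."""

    arena_w: float = 50.0
    arena_h: float = 40.0
    edge_margin_cm: float = 2.0
    band_cm: float = 10.0

    def __post_init__(self):
        if not (0 < self.edge_margin_cm < self.band_cm):
            raise ValidationError("need 0 < edge_margin_cm < band_cm")
        if self.band_cm * 2 >= min(self.arena_w, self.arena_h):
            raise ValidationError("band too wide: no center region remains")

    def classify(self, x, y) -> np.ndarray:
        """Vectorized zone labels for points inside the arena."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any((x < 0) | (x > self.arena_w) | (y < 0) | (y > self.arena_h)):
            raise ValidationError("point(s) outside arena")
        dx = np.minimum(x, self.arena_w - x)   # distance to nearest x wall
        dy = np.minimum(y, self.arena_h - y)
        d = np.minimum(dx, dy)
        out = np.full(np.shape(x), "periphery", dtype=object)
        out[(dx < self.band_cm) & (dy < self.band_cm)] = "corners"
        out[(dx >= self.band_cm) & (dy >= self.band_cm)] = "center"
        out[d < self.edge_margin_cm] = "edges"
        return out


def classify_zone(x: float, y: float, zonemap: ZoneMap) -> str:
    """Zone label of a single point (error if outside the arena)."""
    return str(zonemap.classify(np.atleast_1d(x), np.atleast_1d(y))[0])


def occupancy_fractions(
    track: TrackingSeries,
    zonemap: ZoneMap,
    block_len_s: float | None = None,
):
    """Time-weighted fractional occupancy per zone.

    Each frame contributes one frame period.  Returns a dict
    ``zone -> fraction`` (summing to 1), or with ``block_len_s`` a list
    of such dicts, one per block.
    """
    labels = zonemap.classify(track.x, track.y)

    def fractions(sel):
        n = sel.sum()
        return {z: float(np.sum(labels[sel] == z)) / n if n else np.nan
                for z in ZONES}

    if block_len_s is None:
        return fractions(np.ones(len(track), dtype=bool))
    blocks = np.floor(track.t / block_len_s).astype(int)
    return [fractions(blocks == b) for b in range(blocks.max() + 1)]


def center_distance(track: TrackingSeries) -> np.ndarray:
    """Per-frame distance from arena center, ray-normalized to the wall."""
    cx, cy = track.arena_w / 2.0, track.arena_h / 2.0
    return np.maximum(np.abs(track.x - cx) / cx, np.abs(track.y - cy) / cy)


def center_distance_cdf(track: TrackingSeries, n_points: int = 201):
    """Empirical CDF of the normalized center distance over frames.

    Returns ``(grid, cdf)`` with grid spanning [0, 1]; the CDF is
    non-decreasing and reaches 1 at the right edge.
    """
    d = np.sort(center_distance(track))
    grid = np.linspace(0.0, 1.0, n_points)
    cdf = np.searchsorted(d, grid, side="right") / len(d)
    return grid, cdf


def center_travel_fraction(
    track: TrackingSeries,
    zonemap: ZoneMap,
    block_len_s: float | None = None,
):
    """Fraction of path length travelled in the center zone (per block).

    Each displacement segment ``(i-1) -> i`` is assigned to the zone of
    its arrival frame (the same convention used for speed); segments
    across tracking gaps are excluded.  Blocks with zero total distance
    are flagged as NaN.
    """
    labels = zonemap.classify(track.x, track.y)
    seg = np.hypot(np.diff(track.x), np.diff(track.y))
    seg[track.gap_after[:-1]] = 0.0
    seg_zone = labels[1:]
    seg_t = track.t[1:]

    def fraction(sel) -> float:
        total = seg[sel].sum()
        if total == 0:
            return np.nan
        return float(seg[sel & (seg_zone == "center")].sum() / total)

    if block_len_s is None:
        return fraction(np.ones(len(seg), dtype=bool))
    blocks = np.floor(seg_t / block_len_s).astype(int)
    return [fraction(blocks == b) for b in range(blocks.max() + 1)]


def zone_conditioned_effects(
    event_stats: Sequence[EventStats],
    include_edges: bool = False,
):
    """Per-zone pre/post speed summary of zone-tagged events.

    Returns a dict ``zone -> (mean_pre, mean_post, mean_delta, n)``;
    zones with no events are present with ``n = 0`` and NaN means.
    Edge-zone events are excluded unless ``include_edges``.
    """
    zones = ZONES if include_edges else tuple(z for z in ZONES if z != "edges")
    out = {}
    for z in zones:
        sel = [s for s in event_stats if s.zone_at_onset == z]
        if sel:
            pre = float(np.mean([s.v_pre for s in sel]))
            post = float(np.mean([s.v_post for s in sel]))
            out[z] = (pre, post, post - pre, len(sel))
        else:
            out[z] = (np.nan, np.nan, np.nan, 0)
    return out
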