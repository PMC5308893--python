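"""Transient stimulation-effect quantification.

The central methodological point of this module is the mean-reversion
correction: conditioning post-stimulation speed on pre-stimulation speed
produces regression toward the mean even without any stimulation, so the
raw per-quartile delta is biased.  The correction subtracts, quartile by
quartile, the delta measured at phase-matched sham events in the
non-stimulated blocks ("delta-of-delta"), which cancels the reversion
exactly under the null and isolates the stimulation effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import ValidationError
from .kinematics import EventStats
from .stats import TestResult, pearson

__all__ = [
    "QuartileConditioningResult",
    "mouse_delta",
    "cohort_delta",
    "speed_distribution",
    "quartile_conditioning",
    "cohort_quartile_conditioning",
    "dose_response",
]

N_QUARTILES = 4


@dataclass(frozen=True)
class QuartileConditioningResult:
    """Per-quartile conditioning summary for one mouse.

    ``cuts`` are the three quartile cut points of the real-event
    pre-speed distribution (linear-interpolation quantiles); sham events
    are binned by the same cuts so real and sham quartiles are
    comparable.  Empty quartiles carry NaN and are flagged by a zero
    count.  All arrays have length 4 (quartiles Q1..Q4, slowest first).
    """

    cuts: np.ndarray            # 3 cut points, cm/s
    pre_real: np.ndarray        # mean pre speed per quartile, real events
    post_real: np.ndarray       # mean post speed per quartile, real events
    delta_real: np.ndarray
    pre_sham: np.ndarray
    post_sham: np.ndarray
    delta_sham: np.ndarray
    delta_of_delta: np.ndarray  # delta_real - delta_sham
    n_real: np.ndarray          # event counts per quartile
    n_sham: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.cuts) < -1e-12):
            raise ValidationError("quartile cut points must be non-decreasing")

    @property
    def empty_quartiles(self) -> list[int]:
        """0-based quartile indices with no real or no sham events."""
        return [q for q in range(N_QUARTILES)
                if self.n_real[q] == 0 or self.n_sham[q] == 0]


def mouse_delta(stats: Sequence[EventStats]) -> tuple[float, float, float]:
    """Mean pre speed, mean post speed and their difference for one mouse."""
    if len(stats) < 1:
        raise ValidationError("need at least one event")
    v_pre = float(np.mean([s.v_pre for s in stats]))
    v_post = float(np.mean([s.v_post for s in stats]))
    return v_pre, v_post, v_post - v_pre


def cohort_delta(per_mouse: Sequence[Sequence[EventStats]]):
    """Unweighted across-mouse mean +/- SEM of (v_pre, v_post, delta).

    Per-mouse statistics are computed first, then averaged with equal
    weight per mouse.
    """
    rows = np.array([mouse_delta(s) for s in per_mouse])
    mean = rows.mean(axis=0)
    sem = (rows.std(axis=0, ddof=1) / np.sqrt(len(rows))
           if len(rows) > 1 else np.full(3, np.nan))
    return tuple(mean), tuple(sem)


def speed_distribution(values, bin_width_cm_s: float = 1.0,
                       v_max: float | None = None):
    """Normalized speed histogram: returns ``(bin_edges, probabilities)``.

    Probabilities sum to 1 over the occupied range.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("no speed values to histogram")
    if bin_width_cm_s <= 0:
        raise ValidationError("bin width must be positive")
    hi = v_max if v_max is not None else max(v.max(), bin_width_cm_s)
    edges = np.arange(0.0, hi + bin_width_cm_s, bin_width_cm_s)
    if edges[-1] <= v.max():
        edges = np.append(edges, edges[-1] + bin_width_cm_s)
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts / counts.sum()


def _quartile_of(v: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Quartile index 0..3; values at a cut point go to the lower quartile."""
    return np.searchsorted(cuts, v, side="left")


def quartile_conditioning(
    real_stats: Sequence[EventStats],
    sham_stats: Sequence[EventStats],
) -> QuartileConditioningResult:
    """Prior-speed quartile conditioning with sham-block correction.

    Quartile cut points (25/50/75 %, linear interpolation between order
    statistics) are computed from the pooled pre-speed distribution of
    this mouse's *real* events; both real and sham events are then binned
    by those cuts, per-quartile deltas computed separately, and the sham
    delta subtracted from the real delta ("delta-of-delta").
    """
    if len(real_stats) < N_QUARTILES or len(sham_stats) < N_QUARTILES:
        raise ValidationError(
            f"need >= {N_QUARTILES} real and sham events, got "
            f"{len(real_stats)} / {len(sham_stats)}"
        )
    pre_real_all = np.array([s.v_pre for s in real_stats])
    cuts = np.quantile(pre_real_all, [0.25, 0.5, 0.75], method="linear")

    def per_quartile(stats):
        pre = np.array([s.v_pre for s in stats])
        post = np.array([s.v_post for s in stats])
        q = _quartile_of(pre, cuts)
        mp = np.full(N_QUARTILES, np.nan)
        mo = np.full(N_QUARTILES, np.nan)
        n = np.zeros(N_QUARTILES, dtype=int)
        for i in range(N_QUARTILES):
            sel = q == i
            n[i] = sel.sum()
            if n[i]:
                mp[i] = pre[sel].mean()
                mo[i] = post[sel].mean()
        return mp, mo, mo - mp, n

    pre_r, post_r, d_r, n_r = per_quartile(real_stats)
    pre_s, post_s, d_s, n_s = per_quartile(sham_stats)
    return QuartileConditioningResult(
        cuts=cuts,
        pre_real=pre_r, post_real=post_r, delta_real=d_r,
        pre_sham=pre_s, post_sham=post_s, delta_sham=d_s,
        delta_of_delta=d_r - d_s,
        n_real=n_r, n_sham=n_s,
    )


def cohort_quartile_conditioning(results: Sequence[QuartileConditioningResult]):
    """Across-mouse mean +/- SEM of delta-of-delta per quartile.

    The sham subtraction is applied mouse by mouse (each mouse's own
    sham deltas); quartiles empty for a mouse are excluded from that
    quartile's cohort mean, with the per-quartile mouse count reported.

    Returns ``(mean, sem, n_mice_per_quartile)``, arrays of length 4.
    """
    import warnings

    dd = np.array([r.delta_of_delta for r in results])
    ok = ~np.isnan(dd)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(dd, axis=0)
        sd = np.nanstd(dd, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mean, sem, n


def dose_response(freq_delta_pairs) -> TestResult:
    """Pearson correlation of per-mouse delta speed against pulse frequency.

    ``freq_delta_pairs`` is an iterable of ``(frequency_hz, delta)``
    pooled across mice; requires at least three distinct frequency
    levels.
    """
    pairs = np.asarray(list(freq_delta_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("expected (frequency, delta) pairs")
    freqs = pairs[:, 0]
    if len(np.unique(freqs)) < 3:
        raise ValidationError("need >= 3 frequency levels")
    return pearson(freqs, pairs[:, 1])
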