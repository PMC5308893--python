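"""Speed computation, median filtering, and peri-event windows."""

import numpy as np
import pytest

import openfield as of
from openfield.io_formats import ValidationError
from openfield.kinematics import _shrunken_median

from conftest import make_track, straight_track


def brute_speed(track):
    """Unfiltered displacement speed, first frame undefined."""
    v = np.full(len(track), np.nan)
    for i in range(1, len(track)):
        v[i] = np.hypot(track.x[i] - track.x[i - 1],
                        track.y[i] - track.y[i - 1]) * track.fps
    return v


class TestComputeSpeed:
    def test_stationary_zero(self):
        tr = make_track(np.full(20, 10.0), np.full(20, 10.0))
        sp = of.compute_speed(tr)
        assert np.all(sp.v[1:] == 0)
        assert np.isnan(sp.v[0])

    def test_constant_velocity_is_filter_fixed_point(self):
        tr = straight_track(n=50, v_cm_s=6.0, fps=60.0, x0=1.0)
        sp = of.compute_speed(tr)
        np.testing.assert_allclose(sp.v[1:], 6.0, atol=1e-9)

    def test_single_frame_glitch_rejected_by_median(self):
        x = 5.0 + 0.05 * np.arange(60)
        x[30] += 10.0  # one-frame tracking glitch
        tr = make_track(x, np.full(60, 20.0), fps=10.0)
        raw = brute_speed(tr)
        filt = of.compute_speed(tr).v
        assert np.nanmax(raw) > 50        # oracle: spike present unfiltered
        assert np.nanmax(filt) < 5        # and absent after the median
        # away from the glitch the filter is the identity on constant speed
        np.testing.assert_allclose(filt[2:28], raw[2:28], atol=1e-9)

    def test_matches_bruteforce_when_unfiltered(self):
        rng = np.random.default_rng(3)
        tr = make_track(np.cumsum(rng.normal(0, 0.2, 40)) + 25,
                        np.cumsum(rng.normal(0, 0.2, 40)) + 20)
        sp = of.compute_speed(tr, filter_len=1)
        np.testing.assert_allclose(sp.v[1:], brute_speed(tr)[1:], atol=1e-12)

    def test_gap_masks_speed(self):
        t = np.arange(20) / 10.0
        t[10:] += 0.3  # dropout between frames 9 and 10
        tr = make_track(np.linspace(5, 10, 20), np.full(20, 20.0), t=t)
        sp = of.compute_speed(tr)
        assert np.isnan(sp.v[10])
        assert not np.isnan(sp.v[11])

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(5)
        dx = rng.normal(0, 0.3, 40)
        dy = rng.normal(0, 0.3, 40)
        tr1 = make_track(20 + np.cumsum(dx), 20 + np.cumsum(dy))
        # rotate the path 90 degrees (x,y) -> (-y,x) and translate
        tr2 = make_track(25 - np.cumsum(dy), 10 + np.cumsum(dx))
        v1 = of.compute_speed(tr1).v
        v2 = of.compute_speed(tr2).v
        np.testing.assert_allclose(v1[1:], v2[1:], atol=1e-9)

    def test_even_filter_rejected(self):
        tr = straight_track(10)
        with pytest.raises(ValidationError):
            of.compute_speed(tr, filter_len=4)


def test_shrunken_median_boundary_bruteforce():
    """Boundary frames use the symmetric shrunken window, verified per frame."""
    rng = np.random.default_rng(7)
    v = rng.uniform(0, 10, 11)
    out = _shrunken_median(v, 5)
    for i in range(len(v)):
        h = min(2, i, len(v) - 1 - i)
        assert out[i] == np.median(v[i - h:i + h + 1])


class TestEventWindows:
    def test_constant_speed_zero_delta(self):
        x = 1.0 + 0.6 * np.arange(1200)
        tr = make_track(x, np.full(1200, 20.0), fps=10.0, arena_w=1000.0)
        ev = [of.StimEvent(50.0, 3.0)]
        stats = of.event_windows(of.compute_speed(tr), ev)
        assert stats[0].delta == pytest.approx(0.0, abs=1e-6)

    def test_piecewise_constant_oracle(self):
        # 6 cm/s before onset at t=30, 3 cm/s after; hand integration:
        # pre [28,30) mean 6, post [31,33) mean 3, delta -3
        fps = 10.0
        n = 600
        t = np.arange(n) / fps
        spd = np.where(t < 30.0, 6.0, 3.0)   # speed at the arrival frame
        x = np.empty(n)
        x[0] = 1.0
        x[1:] = 1.0 + np.cumsum(spd[1:] / fps)
        tr = make_track(x, np.full(n, 20.0), fps=fps, arena_w=1000.0)
        stats = of.event_windows(of.compute_speed(tr, filter_len=1),
                                 [of.StimEvent(30.0, 3.0)])
        s = stats[0]
        assert s.v_pre == pytest.approx(6.0, abs=1e-6)
        assert s.v_post == pytest.approx(3.0, abs=1e-6)
        assert s.delta == pytest.approx(-3.0, abs=1e-6)

    def test_default_window_placement(self):
        """Event at t=100 s uses pre [98,100) and post [101,103)."""
        spec = of.WindowSpec()
        assert spec.pre_interval(100.0) == (98.0, 100.0)
        assert spec.post_interval(100.0) == (101.0, 103.0)

    def test_block_crossing_events_dropped_and_counted(self):
        x = 1.0 + 0.3 * np.arange(3000)
        tr = make_track(x, np.full(3000, 20.0), fps=10.0, arena_w=1000.0)
        sp = of.compute_speed(tr)
        evs = [of.StimEvent(100.0, 3.0), of.StimEvent(299.0, 3.0)]  # 2nd spans t=300
        stats = of.event_windows(sp, evs, block_len_s=300.0)
        assert len(stats) == 1
        assert stats.n_dropped == 1

    def test_empty_result_raises(self):
        tr = straight_track(n=50, fps=10.0)
        sp = of.compute_speed(tr)
        with pytest.raises(ValidationError, match="window spec"):
            of.event_windows(sp, [of.StimEvent(1000.0, 3.0)])

    def test_delta_matches_bruteforce_on_random_walk(self):
        rng = np.random.default_rng(9)
        x = 25 + np.cumsum(rng.normal(0, 0.1, 2000))
        y = 20 + np.cumsum(rng.normal(0, 0.1, 2000))
        tr = make_track(np.clip(x, 0, 50), np.clip(y, 0, 40), fps=10.0)
        sp = of.compute_speed(tr, filter_len=1)
        ev = of.StimEvent(100.0, 3.0)
        stats = of.event_windows(sp, [ev])
        v = brute_speed(tr)
        pre = v[(tr.t >= 98.0) & (tr.t < 100.0)].mean()
        post = v[(tr.t >= 101.0) & (tr.t < 103.0)].mean()
        assert stats[0].v_pre == pytest.approx(pre, abs=1e-10)
        assert stats[0].v_post == pytest.approx(post, abs=1e-10)
        assert stats[0].delta == pytest.approx(post - pre, abs=1e-10)


class TestPeriEventTrace:
    def test_constant_speed_flat_trace(self):
        x = 1.0 + 0.3 * np.arange(480)
        tr = make_track(x, np.full(480, 20.0), fps=10.0, arena_w=1000.0)
        sp = of.compute_speed(tr)
        t_rel, mean, sem, n = of.peri_event_trace(sp, [of.StimEvent(20.0, 3.0),
                                                       of.StimEvent(30.0, 3.0)])
        sel = ~np.isnan(mean)
        np.testing.assert_allclose(mean[sel], 3.0, atol=1e-9)
        assert n == 2

    def test_single_event_equals_raw_aligned_speed(self):
        rng = np.random.default_rng(13)
        x = np.clip(25 + np.cumsum(rng.normal(0, 0.1, 400)), 0, 50)
        tr = make_track(x, np.full(400, 20.0), fps=10.0)
        sp = of.compute_speed(tr)
        ev = of.StimEvent(20.0, 3.0)
        t_rel, mean, _, _ = of.peri_event_trace(sp, [ev], t_range=(-2, 2))
        i0 = int(np.searchsorted(sp.t, 20.0))
        k = len(t_rel) // 2
        np.testing.assert_allclose(mean[k], sp.v[i0], atol=1e-12)

    def test_time_zero_is_onset(self, sim_effect_session):
        cfg, track, events, _, _ = sim_effect_session
        sp = of.compute_speed(track)
        t_rel, mean, _, _ = of.peri_event_trace(sp, events, t_range=(-4, 8))
        # suppression kinetics: mean speed in [2,3] s after onset well below
        # mean in [-4,-1] s before
        pre = mean[(t_rel >= -4) & (t_rel <= -1)].mean()
        post = mean[(t_rel >= 2) & (t_rel <= 3)].mean()
        assert post < 0.7 * pre


def test_window_spec_validation():
    with pytest.raises(ValidationError):
        of.WindowSpec(pre_start_s=-1.0, pre_len_s=2.0)  # pre ends after onset
    with pytest.raises(ValidationError):
        of.WindowSpec(post_start_s=-0.5, post_len_s=2.0)  # overlaps pre
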