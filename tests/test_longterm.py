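"""Cross-session table, the session-by-group regression, and the two
short-vs-long-term correlation procedures."""

import numpy as np
import pandas as pd
import pytest

import openfield as of
from openfield.io_formats import ValidationError
from openfield.longterm import (
    fit_longterm,
    short_long_correlation_A,
    short_long_correlation_B,
)


def toy_table(rows):
    df = pd.DataFrame(rows)
    if "delta" not in df.columns:
        df["delta"] = df["v_post"] - df["v_pre"] if "v_post" in df.columns else 0.0
    return df


class TestFitLongterm:
    def test_exact_linear_data_exact_coefficients(self):
        """Noiseless v_pre = 5 + 0.1 n for group 1, constant 5 for group
        0 gives beta = (5, 0, 0, 0.1) to machine precision."""
        rows = []
        for n in range(1, 11):
            rows.append({"mouse_id": "a", "group": 1, "session_idx": n,
                         "v_pre": 5.0 + 0.1 * n})
            rows.append({"mouse_id": "b", "group": 0, "session_idx": n,
                         "v_pre": 5.0})
        fit = fit_longterm(toy_table(rows))
        np.testing.assert_allclose(fit.beta, [5.0, 0.0, 0.0, 0.1], atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(31)
        rows = []
        for m, g in (("a", 1), ("b", 1), ("c", 0), ("d", 0)):
            for n in range(1, 13):
                rows.append({"mouse_id": m, "group": g, "session_idx": n,
                             "v_pre": 5 + 0.2 * n * g + rng.normal(0, 0.5)})
        tab = toy_table(rows)
        fit = fit_longterm(tab)
        s = tab["session_idx"].to_numpy(float)
        g = tab["group"].to_numpy(float)
        X = np.column_stack([np.ones_like(s), s, g, s * g])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ tab["v_pre"].to_numpy())
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-10)

    def test_missing_group_rejected(self):
        rows = [{"mouse_id": "a", "group": 1, "session_idx": n, "v_pre": 5.0}
                for n in range(1, 5)]
        with pytest.raises(ValidationError, match="group 0"):
            fit_longterm(toy_table(rows))

    def test_permuted_group_labels_null_interaction(self):
        """Random group labels on drifting data leave beta3 centred at 0."""
        rng = np.random.default_rng(33)
        b3 = []
        for _ in range(200):
            rows = []
            perm = rng.permutation([1, 1, 0, 0])
            for m, g in zip("abcd", perm):
                for n in range(1, 9):
                    rows.append({"mouse_id": m, "group": int(g),
                                 "session_idx": n,
                                 "v_pre": 5 + 0.15 * n + rng.normal(0, 0.3)})
            b3.append(fit_longterm(toy_table(rows)).beta[3])
        assert abs(np.mean(b3)) < 3 * np.std(b3) / np.sqrt(len(b3)) + 1e-3


class TestEarlyLate:
    def make(self, drift):
        rows = []
        rng = np.random.default_rng(35)
        for m in ("a", "b", "c"):
            for n in range(1, 25):
                rows.append({"mouse_id": m, "group": 1, "session_idx": n,
                             "v_pre": 5 + drift * n + rng.normal(0, 0.1),
                             "delta": -2 + rng.normal(0, 0.1)})
        return toy_table(rows)

    def test_identical_early_late_zero_difference(self):
        tab = self.make(0.0)
        per_mouse, test = of.early_late_contrast(tab)
        assert abs((per_mouse["late"] - per_mouse["early"]).mean()) < 0.1
        assert test.p > 0.05

    def test_drift_late_above_early_delta_unchanged(self):
        tab = self.make(0.15)
        per_mouse, test = of.early_late_contrast(tab, field="v_pre")
        assert (per_mouse["late"] > per_mouse["early"]).all()
        assert test.p < 0.05
        _, test_d = of.early_late_contrast(tab, field="delta")
        assert test_d.p > 0.05


class TestCorrelationProcedures:
    def test_pair_count_index_arithmetic(self):
        # 4 sessions per mouse: interior sessions 2 and 3 -> 2 pairs each
        rows = []
        rng = np.random.default_rng(37)
        for m in ("a", "b"):
            for n in range(1, 5):
                rows.append({"mouse_id": m, "group": 1, "session_idx": n,
                             "v_pre": rng.normal(5, 1),
                             "delta": rng.normal(-2, 0.5)})
        resA = short_long_correlation_A(toy_table(rows))
        assert resA.n_pairs == 4  # 2 per mouse
        resB = short_long_correlation_B(toy_table(rows))
        assert resB.n_pairs == 6  # (sessions - 1) x mice

    def test_perfectly_linear_vpre_gives_zero_r2_in_B(self):
        rows = []
        rng = np.random.default_rng(39)
        for m in ("a", "b"):
            for n in range(1, 9):
                rows.append({"mouse_id": m, "group": 1, "session_idx": n,
                             "v_pre": 4 + 0.2 * n,
                             "delta": rng.normal(-2, 0.5)})
        res = short_long_correlation_B(toy_table(rows))
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_independent_suppression_r2_near_zero_in_A(self):
        rng = np.random.default_rng(41)
        rows = []
        for m in range(3):
            for n in range(1, 25):
                rows.append({"mouse_id": f"m{m}", "group": 1,
                             "session_idx": n,
                             "v_pre": 5 + 0.1 * n + rng.normal(0, 0.5),
                             "delta": rng.normal(-2, 0.5)})
        res = short_long_correlation_A(toy_table(rows))
        assert res.n_pairs == 66  # 22 interior sessions x 3 mice
        assert res.r_squared < 0.1

    def test_planted_coupling_recovered_in_B(self):
        """Next-day residual built as c * delta(n) + noise: procedure B
        recovers c within its standard error."""
        rng = np.random.default_rng(43)
        c = 0.8
        rows = []
        for m in range(3):
            resid_next = 0.0
            for n in range(1, 25):
                delta = rng.normal(-2, 0.6)
                v = 5 + 0.1 * n + resid_next + rng.normal(0, 0.05)
                rows.append({"mouse_id": f"m{m}", "group": 1,
                             "session_idx": n, "v_pre": v, "delta": delta})
                resid_next = c * (delta + 2.0)  # centred coupling
        res = short_long_correlation_B(toy_table(rows))
        assert res.slope == pytest.approx(c, abs=0.25)
        assert res.p < 1e-4

    def test_procedures_agree_in_sign_on_coupled_data(self):
        rng = np.random.default_rng(45)
        rows = []
        for m in range(3):
            carry = 0.0
            for n in range(1, 25):
                delta = rng.normal(-2, 0.6)
                rows.append({"mouse_id": f"m{m}", "group": 1,
                             "session_idx": n,
                             "v_pre": 5 + carry + rng.normal(0, 0.1),
                             "delta": delta})
                carry = 0.7 * (delta + 2.0)
        tab = toy_table(rows)
        a = short_long_correlation_A(tab)
        b = short_long_correlation_B(tab)
        assert np.sign(a.slope) == np.sign(b.slope)

    def test_too_few_pairs(self):
        rows = [{"mouse_id": "a", "group": 1, "session_idx": n,
                 "v_pre": 5.0, "delta": -2.0} for n in (1, 2)]
        with pytest.raises(ValidationError):
            short_long_correlation_A(toy_table(rows))


class TestTableFromSimulation:
    def test_table_shape_and_cross_module_delta(self, short_protocol):
        """Simulated 2-mouse x 3-session cohort: 6 rows, and the delta
        column equals an independent recomputation via mouse_delta."""
        mice = (of.MouseSpec("a", "SERT-Cre", "G1"),
                of.MouseSpec("b", "SERT-Cre", "G2"))
        design = of.CohortDesign(mice=mice, n_sessions=3,
                                 stim_sessions={"G1": (1, 2, 3), "G2": ()})
        cfg = of.SimConfig(fps=15.0)
        sessions = list(of.iter_cohort_sessions(cfg, design, seed=47,
                                                protocol=short_protocol))
        tab = of.table_from_sessions(sessions)
        assert len(tab) == 6
        assert set(tab["session_idx"]) == {1, 2, 3}
        # cross-module consistency on the first stimulated session
        s0 = sessions[0]
        speed = of.compute_speed(s0["track"])
        stats = of.event_windows(speed, s0["events"],
                                 block_len_s=short_protocol.block_len_s)
        v_pre, v_post, delta = of.mouse_delta(stats)
        row = tab[(tab["mouse_id"] == "a") & (tab["session_idx"] == 1)].iloc[0]
        assert row["v_pre"] == pytest.approx(v_pre, abs=1e-10)
        assert row["delta"] == pytest.approx(delta, abs=1e-10)

    def test_file_roundtrip_matches_memory(self, tmp_path, short_protocol):
        mice = (of.MouseSpec("a", "SERT-Cre", "G1"),
                of.MouseSpec("b", "WT", "G2"))
        design = of.CohortDesign(mice=mice, n_sessions=2,
                                 stim_sessions={"G1": (1, 2), "G2": ()})
        cfg = of.SimConfig(fps=15.0)
        manifest, truth = of.simulate_cohort(cfg, design, tmp_path, seed=49,
                                             protocol=short_protocol)
        tab_disk = of.build_longterm_table(
            manifest, block_len_s=short_protocol.block_len_s)
        tab_mem = of.table_from_sessions(
            of.iter_cohort_sessions(cfg, design, seed=49,
                                    protocol=short_protocol))
        for col in ("v_pre", "v_post", "v_firstblock", "delta"):
            np.testing.assert_allclose(tab_disk[col], tab_mem[col], atol=1e-6)
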