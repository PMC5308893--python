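"""Cross-session analysis of long-term locomotor facilitation.

Per mouse-session baselines (mean pre-window speed, mean post-window
speed, their difference, and mean speed in the first block) feed an
ordinary least-squares regression

    speed = b0 + b1*session + b2*group + b3*session*group

with group coded 1 for the continuously stimulated cohort (G1) and 0
for the delayed cohort (G2); b3, the session-by-group interaction, is
the per-session facilitation attributable to stimulation history.
Session enters 1-based and uncentered.

Two complementary correlation procedures test whether the size of the
transient suppression on day n predicts short-term baseline changes:

* procedure A regresses ``v_pre(n+1) - v_pre(n-1)`` on ``delta(n)``;
* procedure B first removes each mouse's linear session trend from
  ``v_pre`` and regresses the residual at session n+1 on ``delta(n)``.

Both pool mouse-session pairs across mice; p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import (
    SessionManifest,
    ValidationError,
    read_events,
    read_tracking,
)
from .kinematics import WindowSpec, compute_speed, event_windows
from .stats import TestResult, paired_compare

__all__ = [
    "LongTermFit",
    "RegressionResult",
    "build_longterm_table",
    "fit_longterm",
    "early_late_contrast",
    "short_long_correlation_A",
    "short_long_correlation_B",
]

EARLY_SESSIONS = (1, 6)
LATE_SESSIONS = (19, 24)


@dataclass(frozen=True)
class LongTermFit:
    """OLS coefficients of the session-by-group regression."""

    beta: np.ndarray       # (b0, b1, b2, b3)
    p: np.ndarray          # per-coefficient two-sided p-values
    conf_int: np.ndarray   # (4, 2) 95% confidence intervals
    r_squared: float
    n: int

    def predict(self, session, group):
        session = np.asarray(session, dtype=float)
        group = np.asarray(group, dtype=float)
        b = self.beta
        return b[0] + b[1] * session + b[2] * group + b[3] * session * group


@dataclass(frozen=True)
class RegressionResult:
    """Slope regression summary for the correlation procedures."""

    slope: float
    intercept: float
    r_squared: float
    p: float          # two-sided p of the slope against the constant model
    n_pairs: int


def session_baselines(
    track,
    events,
    spec: WindowSpec = WindowSpec(),
    block_len_s: float = 300.0,
    filter_len: int = 5,
) -> dict:
    """v_pre, v_post, v_firstblock and delta for one session.

    Pre/post windows are taken at the session's real events, or at its
    sham events when the session was not stimulated (the windows stay
    defined either way).
    """
    speed = compute_speed(track, filter_len=filter_len)
    real = [e for e in events if e.kind == "real"]
    use = real if real else [e for e in events if e.kind == "sham"]
    if not use:
        raise ValidationError("no events in session")
    stats = event_windows(speed, use, spec, block_len_s=block_len_s)
    in_first = ~np.isnan(speed.v) & (track.t < block_len_s)
    v_pre = float(np.mean([s.v_pre for s in stats]))
    v_post = float(np.mean([s.v_post for s in stats]))
    return {
        "v_pre": v_pre,
        "v_post": v_post,
        "v_firstblock": float(speed.v[in_first].mean()),
        "delta": v_post - v_pre,
        "stimulated": bool(real),
    }


def table_from_sessions(sessions) -> pd.DataFrame:
    """Assemble the long-term table from in-memory sessions.

    ``sessions`` yields dicts with keys mouse_id, genotype, group
    ("G1"/"G2" or already 0/1), session_idx, track, events (plus
    optional window-spec overrides under "spec", "block_len_s",
    "filter_len").
    """
    rows = []
    for s in sessions:
        kw = {k: s[k] for k in ("spec", "block_len_s", "filter_len") if k in s}
        try:
            base = session_baselines(s["track"], s["events"], **kw)
        except ValidationError as exc:
            warnings.warn(
                f"session ({s['mouse_id']}, {s['session_idx']}) excluded: {exc}"
            )
            continue
        g = s["group"]
        rows.append({
            "mouse_id": s["mouse_id"],
            "genotype": s.get("genotype", "SERT-Cre"),
            "group": g if g in (0, 1) else (1 if g == "G1" else 0),
            "session_idx": int(s["session_idx"]),
            **base,
        })
    if not rows:
        raise ValidationError("no analyzable sessions")
    return pd.DataFrame(rows).sort_values(
        ["mouse_id", "session_idx"]).reset_index(drop=True)


def build_longterm_table(
    manifest: SessionManifest,
    spec: WindowSpec = WindowSpec(),
    block_len_s: float = 300.0,
    filter_len: int = 5,
) -> pd.DataFrame:
    """One row per mouse-session with baseline and stimulated speeds.

    Columns: mouse_id, genotype, group (1 for G1, 0 for G2), session_idx,
    v_pre, v_post, v_firstblock, delta, stimulated.  Sessions that cannot
    be read or analyzed are excluded with a warning.
    """
    def sessions():
        for _, r in manifest.table.iterrows():
            try:
                track = read_tracking(r["tracking_path"])
                events = read_events(r["events_path"])
            except (ValidationError, OSError) as exc:
                warnings.warn(
                    f"session ({r['mouse_id']}, {r['session_idx']}) "
                    f"excluded: {exc}"
                )
                continue
            yield {
                "mouse_id": r["mouse_id"],
                "genotype": r["genotype"],
                "group": r["group"],
                "session_idx": r["session_idx"],
                "track": track,
                "events": events,
                "spec": spec,
                "block_len_s": block_len_s,
                "filter_len": filter_len,
            }

    return table_from_sessions(sessions())


def fit_longterm(table: pd.DataFrame, value: str = "v_pre") -> LongTermFit:
    """OLS fit of ``value ~ session + group + session*group``."""
    need = {value, "session_idx", "group"}
    if not need <= set(table.columns):
        raise ValidationError(f"table missing columns: {need - set(table.columns)}")
    if table["session_idx"].nunique() < 2:
        raise ValidationError("need >= 2 distinct sessions")
    for g in (0, 1):
        if not (table["group"] == g).any():
            raise ValidationError(
                f"group {g} absent: session x group interaction unidentifiable"
            )
    s = table["session_idx"].to_numpy(dtype=float)
    g = table["group"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(s), s, g, s * g])
    res = sm.OLS(table[value].to_numpy(dtype=float), X).fit()
    return LongTermFit(
        beta=np.asarray(res.params),
        p=np.asarray(res.pvalues),
        conf_int=np.asarray(res.conf_int()),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
    )


def early_late_contrast(
    table: pd.DataFrame,
    field: str = "v_pre",
    early: tuple[int, int] = EARLY_SESSIONS,
    late: tuple[int, int] = LATE_SESSIONS,
    group: int | None = None,
) -> tuple[pd.DataFrame, TestResult]:
    """Per-mouse early-window vs late-window means with a paired test.

    ``early`` and ``late`` are inclusive session ranges.  Mice missing
    either window are excluded with a warning.  Returns the per-mouse
    table and the paired comparison across mice.
    """
    df = table if group is None else table[table["group"] == group]
    rows = []
    for mouse, sub in df.groupby("mouse_id"):
        e = sub[(sub["session_idx"] >= early[0]) & (sub["session_idx"] <= early[1])]
        l = sub[(sub["session_idx"] >= late[0]) & (sub["session_idx"] <= late[1])]
        if e.empty or l.empty:
            warnings.warn(f"mouse {mouse} missing an early/late window; excluded")
            continue
        rows.append({"mouse_id": mouse,
                     "early": float(e[field].mean()),
                     "late": float(l[field].mean())})
    if len(rows) < 2:
        raise ValidationError("need >= 2 mice with both windows populated")
    per_mouse = pd.DataFrame(rows)
    test = paired_compare(per_mouse["late"], per_mouse["early"])
    return per_mouse, test


def _slope_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # a (numerically) constant response or predictor carries no
    # association: report a flat fit rather than 0/0 noise
    if np.ptp(y) < 1e-10 * max(1.0, np.max(np.abs(y))) or np.ptp(x) == 0.0:
        return RegressionResult(slope=0.0, intercept=float(np.mean(y)),
                                r_squared=0.0, p=1.0, n_pairs=len(y))
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p=float(res.pvalues[1]),
        n_pairs=int(res.nobs),
    )


def short_long_correlation_A(table: pd.DataFrame,
                             per_mouse: bool = False):
    """Across-session speed change vs same-day stimulation effect.

    For each interior session n of each mouse, pairs
    ``(delta(n), v_pre(n+1) - v_pre(n-1))``; first and last sessions are
    excluded.  Pairs pool across mice by default (``per_mouse=True``
    returns a dict of per-mouse results instead).
    """
    def pairs_for(sub: pd.DataFrame):
        sub = sub.sort_values("session_idx")
        s = sub["session_idx"].to_numpy()
        vp = sub["v_pre"].to_numpy()
        dl = sub["delta"].to_numpy()
        xs, ys = [], []
        idx = {int(v): i for i, v in enumerate(s)}
        for n in s:
            n = int(n)
            if (n - 1) in idx and (n + 1) in idx:
                xs.append(dl[idx[n]])
                ys.append(vp[idx[n + 1]] - vp[idx[n - 1]])
        return xs, ys

    if per_mouse:
        return {m: _slope_regression(*pairs_for(sub))
                for m, sub in table.groupby("mouse_id")
                if len(pairs_for(sub)[0]) >= 3}
    xs, ys = [], []
    for _, sub in table.groupby("mouse_id"):
        a, b = pairs_for(sub)
        xs.extend(a)
        ys.extend(b)
    if len(xs) < 3:
        raise ValidationError(f"need >= 3 pairs, got {len(xs)}")
    return _slope_regression(np.array(xs), np.array(ys))


def short_long_correlation_B(table: pd.DataFrame,
                             per_mouse: bool = False):
    """Detrended next-day baseline residual vs stimulation effect.

    Each mouse's ``v_pre`` is first regressed on session index; the
    residual at session n+1 is then paired with ``delta(n)`` (the last
    session has no successor and is excluded as a predictor).
    """
    def pairs_for(sub: pd.DataFrame):
        sub = sub.sort_values("session_idx")
        s = sub["session_idx"].to_numpy(dtype=float)
        vp = sub["v_pre"].to_numpy()
        dl = sub["delta"].to_numpy()
        if len(s) < 3:
            return [], []
        coef = np.polyfit(s, vp, 1)
        resid = vp - np.polyval(coef, s)
        idx = {int(v): i for i, v in enumerate(s)}
        xs, ys = [], []
        for n in s:
            n = int(n)
            if (n + 1) in idx:
                xs.append(dl[idx[n]])
                ys.append(resid[idx[n + 1]])
        return xs, ys

    if per_mouse:
        return {m: _slope_regression(*pairs_for(sub))
                for m, sub in table.groupby("mouse_id")
                if len(pairs_for(sub)[0]) >= 3}
    xs, ys = [], []
    for _, sub in table.groupby("mouse_id"):
        a, b = pairs_for(sub)
        xs.extend(a)
        ys.extend(b)
    if len(xs) < 3:
        raise ValidationError(f"need >= 3 pairs, got {len(xs)}")
    return _slope_regression(np.array(xs), np.array(ys))
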