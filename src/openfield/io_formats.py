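"""Validated readers and writers for every file the pipeline touches.

All on-disk formats are plain CSV (comma-separated, ``.`` decimal, UTF-8)
with ``#``-prefixed metadata lines before the header.  Conventions used
throughout the package:

* frames are 0-based integers; time is seconds from session start;
* arena coordinates are centimetres, origin at the bottom-left corner,
  ``0 <= x <= arena_w`` and ``0 <= y <= arena_h``;
* block indices are 0-based.

Tracking gaps (frame intervals longer than one nominal frame period) are
flagged on read and excluded from downstream speed computation; they are
never silently interpolated.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrackingSeries",
    "StimEvent",
    "EthogramRecord",
    "SessionManifest",
    "FormatError",
    "ValidationError",
    "ETHOGRAM_STATES",
    "read_tracking",
    "write_tracking",
    "read_events",
    "write_events",
    "read_ethogram",
    "write_ethogram",
    "read_manifest",
    "write_manifest",
    "load_config",
]

#: Allowed behavioral states for ethogram records.
ETHOGRAM_STATES = (
    "walking",
    "rearing",
    "jumping",
    "resting",
    "digging",
    "grooming",
    "scratching",
    "unscored",
)

#: States counted as mobile / immobile in grouped analyses.  Jumping and
#: scratching are in the schema but occur too rarely to analyze on their
#: own; they remain members of their groups unless filtered out.
MOBILE_STATES = ("walking", "rearing", "jumping")
IMMOBILE_STATES = ("resting", "digging", "grooming", "scratching")

GAP_TOL_S = 1e-6


class FormatError(ValueError):
    """A file could not be parsed; message carries file/line context."""


class ValidationError(ValueError):
    """A file parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackingSeries:
    """Time-stamped 2-D centroid path in arena coordinates.

    Attributes
    ----------
    frame, t, x, y
        Parallel arrays: 0-based frame index, time in seconds, position
        in cm (origin bottom-left).
    fps
        Nominal acquisition rate (frames/s).
    arena_w, arena_h
        Arena dimensions in cm.
    gap_after
        Boolean array, same length; ``gap_after[i]`` is True when the
        interval from frame ``i`` to frame ``i+1`` exceeds the nominal
        frame period (a tracking dropout).  The last element is False.
    """

    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    arena_w: float
    arena_h: float
    gap_after: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("frame", "t", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.t)
        if not (len(self.frame) == len(self.x) == len(self.y) == n):
            raise ValidationError("tracking arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("t must be strictly increasing")
        bad = np.flatnonzero(
            (self.x < 0) | (self.x > self.arena_w)
            | (self.y < 0) | (self.y > self.arena_h)
        )
        if bad.size:
            frames = ", ".join(str(int(self.frame[i])) for i in bad[:10])
            raise ValidationError(
                f"coordinates outside arena at frame(s) {frames}"
                + (" ..." if bad.size > 10 else "")
            )
        if self.gap_after is None:
            gaps = np.zeros(n, dtype=bool)
            if n >= 2:
                gaps[:-1] = np.diff(self.t) > 1.0 / self.fps + GAP_TOL_S
            object.__setattr__(self, "gap_after", gaps)
        else:
            object.__setattr__(self, "gap_after", np.asarray(self.gap_after, dtype=bool))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_after.sum())

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass(frozen=True)
class StimEvent:
    """One stimulation train (real) or its phase-matched sham placeholder."""

    onset_s: float
    duration_s: float
    pulse_hz: float = 25.0
    pulse_width_ms: float = 10.0
    amplitude_mw: float = 5.0
    kind: str = "real"
    block_idx: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.pulse_hz < 0:
            raise ValidationError(f"pulse_hz must be >= 0, got {self.pulse_hz}")
        if self.kind not in ("real", "sham"):
            raise ValidationError(f"kind must be 'real' or 'sham', got {self.kind!r}")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def n_pulses(self) -> int:
        """Pulse count of the train (duration x pulse rate)."""
        return int(round(self.duration_s * self.pulse_hz))


@dataclass(frozen=True)
class EthogramRecord:
    """One scored behavioral interval ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float
    state: str

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValidationError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )
        if self.state not in ETHOGRAM_STATES:
            raise ValidationError(
                f"unknown state {self.state!r}; allowed: {', '.join(ETHOGRAM_STATES)}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SessionManifest:
    """Cohort table: one row per (mouse, session) with file paths."""

    table: pd.DataFrame

    REQUIRED = ("mouse_id", "genotype", "group", "session_idx",
                "tracking_path", "events_path")
    GENOTYPES = ("SERT-Cre", "WT")
    GROUPS = ("G1", "G2", "none")

    def __post_init__(self):
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if "ethogram_path" not in df.columns:
            df["ethogram_path"] = ""
        bad_g = set(df["genotype"]) - set(self.GENOTYPES)
        if bad_g:
            raise ValidationError(f"unknown genotype(s): {sorted(bad_g)}")
        bad_grp = set(df["group"]) - set(self.GROUPS)
        if bad_grp:
            raise ValidationError(f"unknown group(s): {sorted(bad_grp)}")
        if (df["session_idx"] < 1).any():
            raise ValidationError("session_idx must be >= 1")
        dup = df.duplicated(subset=["mouse_id", "session_idx"])
        if dup.any():
            rows = df.loc[dup, ["mouse_id", "session_idx"]].values.tolist()
            raise ValidationError(f"duplicate (mouse_id, session_idx): {rows}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mice(self) -> list[str]:
        return list(dict.fromkeys(self.table["mouse_id"]))


# ---------------------------------------------------------------------------
# Low-level CSV helpers
# ---------------------------------------------------------------------------


def _split_meta(path) -> tuple[dict, str, int]:
    """Return (metadata dict, CSV body, number of metadata lines)."""
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    body_lines = []
    n_meta = 0
    for i, line in enumerate(text.splitlines()):
        if line.startswith("#"):
            if body_lines:
                raise FormatError(f"{path}:{i + 1}: metadata line after header")
            n_meta += 1
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines), n_meta


def _read_body(path, body: str, n_meta: int, columns: Sequence[str],
               dtypes: dict | None = None) -> pd.DataFrame:
    if not body.strip():
        raise FormatError(f"{path}: no CSV header found")
    try:
        df = pd.read_csv(io.StringIO(body), dtype=dtypes)
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    # numeric coercion with line-number reporting (header is line n_meta+1)
    for c in columns:
        if dtypes and dtypes.get(c) is str:
            continue
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            line = int(bad[0]) + n_meta + 2
            raise FormatError(
                f"{path}:{line}: malformed value {df.loc[bad[0], c]!r} in column {c!r}"
            )
        if coerced.isna().any() and df[c].isna().any():
            line = int(df.index[df[c].isna()][0]) + n_meta + 2
            raise FormatError(f"{path}:{line}: missing value in column {c!r}")
        df[c] = coerced
    return df


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


def read_tracking(path) -> TrackingSeries:
    """Read a tracking CSV (``frame,t,x,y`` plus ``# fps=…`` metadata).

    Gaps in the timestamp sequence are flagged on the returned series
    (``gap_after``), not interpolated.  Raises :class:`FormatError` for
    malformed rows (with line numbers) and :class:`ValidationError` for
    out-of-arena coordinates or non-monotonic time.
    """
    meta, body, n_meta = _split_meta(path)
    for key in ("fps", "arena_w", "arena_h"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata line '# {key}=...'")
    df = _read_body(path, body, n_meta, ("frame", "t", "x", "y"))
    try:
        return TrackingSeries(
            frame=df["frame"].to_numpy(dtype=np.int64),
            t=df["t"].to_numpy(dtype=float),
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            fps=float(meta["fps"]),
            arena_w=float(meta["arena_w"]),
            arena_h=float(meta["arena_h"]),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_tracking(path, track: TrackingSeries) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# fps={track.fps:g}\n")
        fh.write(f"# arena_w={track.arena_w:g}\n")
        fh.write(f"# arena_h={track.arena_h:g}\n")
        # 9 decimals keeps frame-period differences well inside the gap
        # tolerance after a write/read round trip
        pd.DataFrame(
            {"frame": track.frame, "t": track.t, "x": track.x, "y": track.y}
        ).to_csv(fh, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Stimulation events
# ---------------------------------------------------------------------------

_EVENT_COLS = ("onset_s", "duration_s", "pulse_hz", "pulse_width_ms",
               "amplitude_mw", "kind", "block_idx")


def _check_real_overlap(events: Sequence[StimEvent], path=None) -> None:
    prefix = f"{path}: " if path else ""
    real = sorted((e for e in events if e.kind == "real"), key=lambda e: e.onset_s)
    for a, b in zip(real, real[1:]):
        if b.onset_s < a.offset_s - GAP_TOL_S:
            raise ValidationError(
                f"{prefix}real events overlap: onsets {a.onset_s} and {b.onset_s}"
            )
    sham = [e for e in events if e.kind == "sham"]
    for s in sham:
        for r in real:
            if s.onset_s < r.offset_s and r.onset_s < s.offset_s:
                raise ValidationError(
                    f"{prefix}sham event at {s.onset_s} overlaps real event at {r.onset_s}"
                )


def read_events(path) -> list[StimEvent]:
    """Read a stimulation-events CSV, sorted by onset; kind defaults to real."""
    meta, body, n_meta = _split_meta(path)
    if not body.strip():
        raise FormatError(f"{path}: no CSV header found")
    df = _read_body(path, body, n_meta, [c for c in _EVENT_COLS if c != "kind"],
                    dtypes={"kind": str})
    if "kind" not in df.columns:
        df["kind"] = "real"
    df["kind"] = df["kind"].fillna("real")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(StimEvent(
                onset_s=float(row["onset_s"]),
                duration_s=float(row["duration_s"]),
                pulse_hz=float(row["pulse_hz"]),
                pulse_width_ms=float(row["pulse_width_ms"]),
                amplitude_mw=float(row["amplitude_mw"]),
                kind=str(row["kind"]),
                block_idx=int(row["block_idx"]),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{int(i) + n_meta + 2}: {exc}") from exc
    events.sort(key=lambda e: (e.onset_s, e.kind))
    _check_real_overlap(events, path)
    return events


def write_events(path, events: Sequence[StimEvent]) -> None:
    _check_real_overlap(events)
    df = pd.DataFrame(
        [{c: getattr(e, c) for c in _EVENT_COLS} for e in sorted(
            events, key=lambda e: (e.onset_s, e.kind))],
        columns=list(_EVENT_COLS),
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Ethogram
# ---------------------------------------------------------------------------


def read_ethogram(path) -> list[EthogramRecord]:
    """Read ethogram CSV (``onset_s,offset_s,state``); records must not overlap."""
    meta, body, n_meta = _split_meta(path)
    df = _read_body(path, body, n_meta, ("onset_s", "offset_s"), dtypes={"state": str})
    if "state" not in df.columns:
        raise FormatError(f"{path}: missing column(s) ['state']")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(EthogramRecord(
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                state=str(row["state"]),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{int(i) + n_meta + 2}: {exc}") from exc
    records.sort(key=lambda r: r.onset_s)
    for a, b in zip(records, records[1:]):
        if b.onset_s < a.offset_s - GAP_TOL_S:
            raise ValidationError(
                f"{path}: overlapping records at {a.onset_s} and {b.onset_s}"
            )
    return records


def write_ethogram(path, records: Sequence[EthogramRecord]) -> None:
    recs = sorted(records, key=lambda r: r.onset_s)
    for a, b in zip(recs, recs[1:]):
        if b.onset_s < a.offset_s - GAP_TOL_S:
            raise ValidationError(
                f"overlapping records at {a.onset_s} and {b.onset_s}"
            )
    df = pd.DataFrame(
        [{"onset_s": r.onset_s, "offset_s": r.offset_s, "state": r.state}
         for r in recs],
        columns=["onset_s", "offset_s", "state"],
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Manifest and config
# ---------------------------------------------------------------------------


def read_manifest(path) -> SessionManifest:
    meta, body, n_meta = _split_meta(path)
    if not body.strip():
        raise FormatError(f"{path}: no CSV header found")
    try:
        df = pd.read_csv(io.StringIO(body), dtype={
            "mouse_id": str, "genotype": str, "group": str,
            "tracking_path": str, "events_path": str, "ethogram_path": str,
        })
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        return SessionManifest(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_manifest(path, manifest: SessionManifest) -> None:
    cols = list(SessionManifest.REQUIRED) + ["ethogram_path"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        manifest.table[cols].to_csv(fh, index=False)


def load_config(path) -> dict:
    """Load the YAML config holding protocol / simulator / zone parameters."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
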