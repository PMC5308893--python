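"""Block/train stimulation schedules and phase-matched sham events.

A session is divided into alternating no-stimulation / stimulation blocks
(by default six 5-min blocks starting with no stimulation).  Within each
stimulated block, fixed-length pulse trains are delivered at a fixed
period (default 3-s trains every 10 s), giving 90 trains and 270 s of
stimulation in a standard 30-min session.

Sham events occupy the non-stimulated blocks at exactly the same
within-block phase as the real trains, so that under the null hypothesis
real and sham events are exchangeable.

Two presets are provided because the source protocols used 25 Hz pulses
in the standard open-field assay and 20 Hz in the long-term assay; both
are retained and neither is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import StimEvent, ValidationError

__all__ = [
    "StimProtocol",
    "STANDARD_PROTOCOL",
    "LONGTERM_PROTOCOL",
    "make_schedule",
    "make_sham_schedule",
    "stimulated_blocks",
    "total_stim_time",
]


@dataclass(frozen=True)
class StimProtocol:
    """Parameters of the block/train stimulation protocol.

    Defaults are the standard 30-min open-field protocol: six 5-min
    blocks starting unstimulated, 3-s trains every 10 s, 25 Hz pulses of
    10 ms at 5 mW.
    """

    session_len_s: float = 1800.0
    block_len_s: float = 300.0
    first_block_stimulated: bool = False
    train_len_s: float = 3.0
    train_period_s: float = 10.0
    pulse_hz: float = 25.0
    pulse_width_ms: float = 10.0
    amplitude_mw: float = 5.0

    def __post_init__(self):
        if not (self.train_len_s < self.train_period_s <= self.block_len_s):
            raise ValidationError(
                "need train_len_s < train_period_s <= block_len_s, got "
                f"{self.train_len_s}, {self.train_period_s}, {self.block_len_s}"
            )
        n = self.session_len_s / self.block_len_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"session_len_s ({self.session_len_s}) must be an integer "
                f"multiple of block_len_s ({self.block_len_s})"
            )

    @property
    def n_blocks(self) -> int:
        return int(round(self.session_len_s / self.block_len_s))

    @property
    def trains_per_block(self) -> int:
        return int(self.block_len_s // self.train_period_s)


#: Standard open-field protocol (25 Hz pulses).
STANDARD_PROTOCOL = StimProtocol()

#: Long-term (multi-week) protocol variant with 20 Hz pulses.
LONGTERM_PROTOCOL = StimProtocol(pulse_hz=20.0)


def stimulated_blocks(protocol: StimProtocol) -> list[int]:
    """0-based indices of the stimulated blocks (1,3,5 under defaults)."""
    start = 0 if protocol.first_block_stimulated else 1
    return list(range(start, protocol.n_blocks, 2))


def _block_events(protocol: StimProtocol, block: int, kind: str) -> list[StimEvent]:
    t0 = block * protocol.block_len_s
    events = []
    for k in range(protocol.trains_per_block):
        onset = t0 + k * protocol.train_period_s
        # invariant train_len < period <= block_len keeps every train
        # wholly inside its block; assert rather than truncate
        assert onset + protocol.train_len_s <= t0 + protocol.block_len_s
        events.append(StimEvent(
            onset_s=onset,
            duration_s=protocol.train_len_s,
            pulse_hz=protocol.pulse_hz,
            pulse_width_ms=protocol.pulse_width_ms,
            amplitude_mw=protocol.amplitude_mw,
            kind=kind,
            block_idx=block,
        ))
    return events


def make_schedule(protocol: StimProtocol) -> list[StimEvent]:
    """Real stimulation trains, deterministic, sorted by onset.

    Under defaults: 3 stimulated blocks x 30 trains = 90 events totalling
    270 s of stimulation per 30-min session.
    """
    events: list[StimEvent] = []
    for block in stimulated_blocks(protocol):
        events.extend(_block_events(protocol, block, "real"))
    return events


def make_sham_schedule(protocol: StimProtocol) -> list[StimEvent]:
    """Sham events in the non-stimulated blocks, phase-matched to trains.

    Each sham onset is ``block_start + k * train_period_s`` — the same
    within-block phase as the real trains — so the sham multiset of
    onsets modulo block length equals the real one.
    """
    stim = set(stimulated_blocks(protocol))
    events: list[StimEvent] = []
    for block in range(protocol.n_blocks):
        if block not in stim:
            events.extend(_block_events(protocol, block, "sham"))
    return events


def total_stim_time(events) -> float:
    """Summed duration (s) of the real events in a schedule."""
    return float(sum(e.duration_s for e in events if e.kind == "real"))
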