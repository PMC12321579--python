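"""Core session data model.

All event and spike times are seconds (float) from session start; sample
indices are 0-based; every interval is half-open ``[start, end)``.  LFP
amplitudes are microvolts after scaling.  An event whose time equals an
interval boundary belongs to the interval whose start it equals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

REGIONS = ("HC", "MPFC", "OTHER")
CHANNEL_KINDS = ("LFP", "ACCEL", "STIM")
STATES = ("NREM", "REM", "WAKE")
EVENT_KINDS = ("IED", "SPINDLE", "DOWN", "STIM", "AIED")
CELL_CLASSES = ("PYR", "INT", "UNCLASSIFIED")
CONDITIONS = ("BASELINE", "KINDLED_ONLY", "SHAM", "CLOSED_LOOP", "AIED")

#: canonical analysis sampling rate (Hz); sessions at other rates are
#: resampled on read.
ANALYSIS_FS_HZ = 1250.0


@dataclass(frozen=True)
class ChannelInfo:
    """One recorded channel: label, anatomical region, signal kind, scale."""

    label: str
    region: str = "OTHER"
    kind: str = "LFP"
    uv_per_bit: float = 1.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if not self.uv_per_bit > 0:
            raise ValueError("uv_per_bit must be > 0")


@dataclass
class SessionMeta:
    session_id: str
    fs_hz: float
    n_samples: int
    channels: list[ChannelInfo]
    day_index: int = 0
    condition: str = "BASELINE"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be > 0")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.day_index < 0:
            raise ValueError("day_index must be >= 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")


@dataclass
class StateIntervals:
    """Sorted, non-overlapping behavioural-state intervals ``[start, end)``."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def for_state(self, state: str) -> list[tuple[float, float]]:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        return [(s, e) for s, e, st in self.intervals if st == state]

    def duration(self, state: str) -> float:
        return float(sum(e - s for s, e in self.for_state(state)))

    def state_at(self, t: float) -> Optional[str]:
        for s, e, st in self.intervals:
            if s <= t < e:
                return st
        return None

    def mask(self, state: str, n_samples: int, fs_hz: float) -> np.ndarray:
        """Boolean sample mask for one state (half-open intervals)."""
        m = np.zeros(n_samples, dtype=bool)
        for s, e in self.for_state(state):
            i0 = max(0, int(np.ceil(s * fs_hz - 1e-9)))
            i1 = min(n_samples, int(np.ceil(e * fs_hz - 1e-9)))
            m[i0:i1] = True
        return m


@dataclass
class Event:
    peak_s: float
    start_s: float
    end_s: float
    channel: str
    amplitude_uv: float = 0.0
    kind: str = "IED"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventSeries:
    """Homogeneous, peak-sorted collection of detected or injected events."""

    events: list[Event] = field(default_factory=list)
    kind: str = "IED"
    region: str = "OTHER"
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.asarray([ev.peak_s for ev in self.events], dtype=float)

    def sort(self) -> "EventSeries":
        self.events.sort(key=lambda ev: ev.peak_s)
        return self

    @classmethod
    def from_times(
        cls,
        times: Iterable[float],
        kind: str = "IED",
        region: str = "OTHER",
        channel: str = "",
        width_s: float = 0.0,
        amplitudes: Optional[Sequence[float]] = None,
        params: Optional[dict] = None,
    ) -> "EventSeries":
        times = sorted(float(t) for t in times)
        amps = list(amplitudes) if amplitudes is not None else [0.0] * len(times)
        evs = [
            Event(t, t - width_s / 2, t + width_s / 2, channel, a, kind)
            for t, a in zip(times, amps)
        ]
        return cls(events=evs, kind=kind, region=region, params=dict(params or {}))


@dataclass
class SpikeUnit:
    unit_id: str
    spike_times_s: np.ndarray
    region: str = "OTHER"
    cell_class: str = "UNCLASSIFIED"

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass
class SessionBundle:
    """One recording session: LFP matrix, states, spikes, events, truth."""

    meta: SessionMeta
    lfp: np.ndarray  # (n_samples, n_channels), microvolts
    states: StateIntervals = field(default_factory=StateIntervals)
    units: list[SpikeUnit] = field(default_factory=list)
    event_series: dict[str, EventSeries] = field(default_factory=dict)
    ground_truth: Optional[object] = None  # synth.GroundTruth when simulated

    def channel(self, label: str) -> np.ndarray:
        return self.lfp[:, self.meta.channel_index(label)]

    def channels_of(self, region: Optional[str] = None, kind: str = "LFP") -> list[str]:
        return [
            ch.label
            for ch in self.meta.channels
            if ch.kind == kind and (region is None or ch.region == region)
        ]

    @property
    def duration_s(self) -> float:
        return self.meta.duration_s


def validate_session(bundle: SessionBundle) -> list[str]:
    """Check every model invariant; returns violation messages (never raises)."""
    v: list[str] = []
    meta = bundle.meta
    if bundle.lfp.shape != (meta.n_samples, meta.n_channels):
        v.append(
            f"lfp shape {bundle.lfp.shape} != meta ({meta.n_samples}, {meta.n_channels})"
        )
    labels = [ch.label for ch in meta.channels]
    if len(set(labels)) != len(labels):
        v.append("duplicate channel labels")
    ivs = bundle.states.intervals
    for s, e, st in ivs:
        if not s < e:
            v.append(f"state interval [{s}, {e}) empty or inverted")
        if st not in STATES:
            v.append(f"unknown state {st!r}")
    for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
        if s1 < s0:
            v.append("state intervals not sorted")
        if s1 < e0:
            v.append(f"state intervals overlap at {s1}")
    dur = meta.duration_s
    for unit in bundle.units:
        t = unit.spike_times_s
        if t.size and np.any(np.diff(t) <= 0):
            v.append(f"unit {unit.unit_id}: spike times not strictly increasing")
    for key, series in bundle.event_series.items():
        pk = series.peak_times
        if pk.size and np.any(np.diff(pk) < 0):
            v.append(f"series {key}: events not sorted by peak")
        for ev in series:
            if ev.kind != series.kind:
                v.append(f"series {key}: mixed event kinds")
                break
        if pk.size and (pk.max() >= dur + 1e-9) and dur > 0:
            v.append(f"series {key}: event beyond session end")
        for ev in series:
            if not (ev.start_s <= ev.peak_s <= ev.end_s):
                v.append(f"series {key}: start<=peak<=end violated at {ev.peak_s}")
                break
    return v


def slice_by_state(bundle: SessionBundle, state: str) -> list[tuple[float, float]]:
    """Half-open intervals of one behavioural state, sorted and disjoint."""
    return bundle.states.for_state(state)


def memory_performance(retrieved: int, available: int) -> float:
    """Reward-retrieval performance: 100 * retrieved / available."""
    if available <= 0:
        raise ValueError("available must be > 0")
    if not 0 <= retrieved <= available:
        raise ValueError("need 0 <= retrieved <= available")
    return 100.0 * retrieved / available


def modulated_fraction_pct(n_modulated: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of units modulated, truncated (floored) to `decimals` places."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    pct = 100.0 * n_modulated / n_total
    scale = 10.0**decimals
    return float(np.floor(pct * scale) / scale)


__all__ = [
    "ANALYSIS_FS_HZ",
    "CELL_CLASSES",
    "CHANNEL_KINDS",
    "CONDITIONS",
    "ChannelInfo",
    "EVENT_KINDS",
    "Event",
    "EventSeries",
    "REGIONS",
    "STATES",
    "SessionBundle",
    "SessionMeta",
    "SpikeUnit",
    "StateIntervals",
    "memory_performance",
    "modulated_fraction_pct",
    "slice_by_state",
    "validate_session",
    "replace",
]
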