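"""Offline detectors: sleep states, MUA, IEDs, spindles and DOWN states.

All detectors operate on the canonical 1250 Hz bundle, use zero-phase
(forward-backward) Butterworth filters so event timing is preserved, and
compute baseline statistics on NREM samples.  Samples inside stimulation
artifact blanks are excluded from baselines and candidate events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .types import Event, EventSeries, SessionBundle, StateIntervals

MAD_SCALE = 1.4826


@dataclass
class DownState:
    """One accepted DOWN state on the 0.5-6 Hz z-scored cortical LFP."""

    t_start: float
    t_peak: float
    t_end: float
    z_peak: float
    z_end: float
    mua_validated: Optional[bool] = None
    pathological: bool = False

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _highpass(x: np.ndarray, fs: float, lo: float, order: int = 4) -> np.ndarray:
    sos = butter(order, lo, btype="highpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def stim_blank_intervals(
    bundle: SessionBundle, channel: Optional[str] = None, pad_s: float = 0.05
) -> list[tuple[float, float]]:
    """Blanking windows around stimulation artifacts (200 ms + padding).

    Artifacts live on the stimulated (cortical) channel; when ``channel``
    is given only stim events recorded on that channel are blanked, so
    e.g. hippocampal detection is unaffected.
    """
    series = bundle.event_series.get("stim")
    if series is None or not len(series):
        return []
    return [
        (ev.start_s - pad_s, ev.end_s + pad_s)
        for ev in series
        if channel is None or ev.channel == channel
    ]


def interpolate_blanks(
    x: np.ndarray, fs: float, blanks: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Linearly interpolate across blanked windows (artifact removal
    before any filtering, so filter ringing cannot leak out of the blank)."""
    if not blanks:
        return x
    y = x.copy()
    n = y.size
    for s, e in blanks:
        a = max(0, int(s * fs))
        b = min(n, int(np.ceil(e * fs)))
        if b <= a:
            continue
        left = y[a - 1] if a > 0 else y[min(b, n - 1)]
        right = y[b] if b < n else y[max(a - 1, 0)]
        y[a:b] = np.linspace(left, right, b - a, endpoint=False)
    return y


def _blank_mask(
    blanks: Sequence[tuple[float, float]], n: int, fs: float
) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    for s, e in blanks:
        a = max(0, int(s * fs))
        b = min(n, int(np.ceil(e * fs)))
        m[a:b] = True
    return m


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# sleep scoring


def score_sleep(
    bundle: SessionBundle,
    window_s: float = 1.0,
    r_rem: float = 2.0,
    d_nrem: float = -0.5,
    motion_z: float = 3.0,
    assume_immobile: bool = False,
) -> StateIntervals:
    """Window-based NREM/REM/WAKE scoring with 5-window majority smoothing.

    Per window: WAKE if robust-z of log motion power exceeds ``motion_z``;
    else REM if the hippocampal-theta / cortical-delta power ratio exceeds
    ``r_rem``; else NREM if the z-scored log delta power of the cortical
    LFP exceeds ``d_nrem``; remaining windows are scored WAKE.  This is a
    simplified threshold re-specification of delta/theta-ratio scoring;
    thresholds are tuned for the synthetic generator and exposed here.
    """
    fs = bundle.meta.fs_hz
    mpfc = bundle.channels_of("MPFC")
    hc = bundle.channels_of("HC")
    accel = [ch.label for ch in bundle.meta.channels if ch.kind == "ACCEL"]
    if not mpfc or not hc:
        raise ValueError("need at least one mPFC and one HC LFP channel")
    if not accel and not assume_immobile:
        raise ValueError("no accelerometer channel; pass --assume-immobile to proceed")

    w = int(round(window_s * fs))
    n_win = bundle.lfp.shape[0] // w
    if n_win == 0:
        return StateIntervals()

    def win_power(x: np.ndarray) -> np.ndarray:
        return (x[: n_win * w] ** 2).reshape(n_win, w).mean(axis=1)

    delta = win_power(_bandpass(bundle.channel(mpfc[0]), fs, 0.5, 4.0))
    theta = win_power(_bandpass(bundle.channel(hc[0]), fs, 5.0, 8.0))
    eps = 1e-12

    if accel and not assume_immobile:
        mp = np.log10(win_power(bundle.channel(accel[0])) + eps)
        med = np.median(mp)
        mad = MAD_SCALE * np.median(np.abs(mp - med)) + eps
        wake = (mp - med) / mad > motion_z
    else:
        wake = np.zeros(n_win, dtype=bool)

    ratio = theta / (delta + eps)
    rem = ~wake & (ratio > r_rem)

    ld = np.log10(delta + eps)
    ref = ld[~wake]
    mu, sd = (ref.mean(), ref.std()) if ref.size else (0.0, 0.0)
    # degenerate delta (e.g. an empty signal) cannot satisfy the criterion
    dz = (ld - mu) / sd if sd > 0 else np.full(n_win, -np.inf)
    nrem = ~wake & ~rem & (dz > d_nrem)

    labels = np.where(wake, 0, np.where(rem, 1, np.where(nrem, 2, 0)))
    labels = _majority_smooth(labels, 5)

    names = {0: "WAKE", 1: "REM", 2: "NREM"}
    out = []
    i = 0
    while i < n_win:
        j = i
        while j < n_win and labels[j] == labels[i]:
            j += 1
        end = bundle.duration_s if j == n_win else j * window_s
        out.append((i * window_s, end, names[int(labels[i])]))
        i = j
    return StateIntervals(intervals=out)


def _majority_smooth(labels: np.ndarray, k: int) -> np.ndarray:
    half = k // 2
    out = labels.copy()
    for i in range(labels.size):
        seg = labels[max(0, i - half) : i + half + 1]
        vals, counts = np.unique(seg, return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        out[i] = labels[i] if labels[i] in winners else winners[0]
    return out


# ---------------------------------------------------------------------------
# MUA


def detect_mua(
    bundle: SessionBundle,
    channel: str,
    band: tuple[float, float] = (80.0, 300.0),
    thr_mult: float = 5.0,
) -> np.ndarray:
    """Threshold-crossing peak times on the band-filtered rectified signal.

    Threshold is ``thr_mult * median(|filtered|) / 0.6745``; peaks are
    suprathreshold samples where the discrete derivative of the rectified
    trace changes sign (shift-compare).
    """
    fs = bundle.meta.fs_hz
    lo, hi = band
    if hi >= fs / 2:
        warnings.warn(f"band upper edge {hi} >= Nyquist; clipping")
        hi = fs / 2 * 0.95
    x = np.abs(_bandpass(bundle.channel(channel), fs, lo, hi))
    med = np.median(x)
    thr = thr_mult * med / 0.6745
    if thr <= 0:
        return np.empty(0)
    above = x > thr
    d = np.diff(x)
    peak = np.r_[False, (d[:-1] > 0) & (d[1:] <= 0), False]
    return np.nonzero(above & peak)[0] / fs


# ---------------------------------------------------------------------------
# IED detection


def detect_ied(
    bundle: SessionBundle,
    channel: str,
    nrem_only: bool = True,
    k_detect: float = 5.0,
    k_reject_low: float = 10.0,
    k_reject_high: float = 100.0,
    merge_s: float = 0.1,
    robust: bool = False,
) -> EventSeries:
    """Four-step IED detector.

    (1) zero-phase 50-85 Hz bandpass + rectification -> envelope;
    (2) candidates where envelope > median + ``k_detect`` * SD (SD over
    NREM baseline excluding candidate epochs, two-pass; ``robust`` swaps
    SD for 1.4826*MAD); (3) reject unless the |>15 Hz| waveform within
    +-50 ms of the peak exceeds baseline mean + ``k_reject_low`` * SD;
    (4) reject amplitudes above mean + ``k_reject_high`` * SD (artifact).
    Candidates closer than ``merge_s`` are merged keeping the larger peak.
    """
    fs = bundle.meta.fs_hz
    n = bundle.lfp.shape[0]
    nrem_mask = bundle.states.mask("NREM", n, fs)
    if nrem_mask.sum() / fs < 60.0:
        raise ValueError("less than 60 s of NREM: baseline statistics unreliable")
    blanks = stim_blank_intervals(bundle, channel)
    x = interpolate_blanks(bundle.channel(channel), fs, blanks)
    blank = _blank_mask(blanks, n, fs)
    base_mask = nrem_mask & ~blank

    env = np.abs(_bandpass(x, fs, 50.0, 85.0))
    med = np.median(env[base_mask])

    def spread(mask: np.ndarray) -> float:
        v = env[mask]
        if robust:
            return MAD_SCALE * float(np.median(np.abs(v - np.median(v))))
        return float(v.std())

    thr1 = med + k_detect * spread(base_mask)
    pass1 = env > thr1
    # second pass: exclude candidate epochs (+-100 ms) from the SD estimate
    excl = np.zeros(n, dtype=bool)
    pad = int(0.1 * fs)
    for a, b in _runs(pass1):
        excl[max(0, a - pad) : min(n, b + pad)] = True
    refined = base_mask & ~excl
    if refined.sum() / fs < 30.0:
        refined = base_mask
    thr = med + k_detect * spread(refined)

    cand_mask = env > thr
    if nrem_only:
        cand_mask &= nrem_mask
    cand_mask &= ~blank
    regions = _runs(cand_mask)
    peaks = [(a + int(np.argmax(env[a:b])), a, b) for a, b in regions]

    # merge candidates closer than merge_s, keeping the larger envelope peak
    merged: list[tuple[int, int, int]] = []
    for pk, a, b in peaks:
        if merged and (pk - merged[-1][0]) / fs < merge_s:
            if env[pk] > env[merged[-1][0]]:
                merged[-1] = (pk, merged[-1][1], b)
            else:
                merged[-1] = (merged[-1][0], merged[-1][1], b)
        else:
            merged.append((pk, a, b))

    hp_signed = _highpass(x, fs, 15.0)
    hp = np.abs(hp_signed)
    # baseline mean/SD of the signed high-passed trace (mean ~ 0)
    hp_mu, hp_sd = float(hp_signed[refined].mean()), float(hp_signed[refined].std())
    lo_thr = hp_mu + k_reject_low * hp_sd
    hi_thr = hp_mu + k_reject_high * hp_sd

    half = int(0.05 * fs)
    events = []
    for pk, a, b in merged:
        amp = float(hp[max(0, pk - half) : min(n, pk + half + 1)].max())
        if amp <= lo_thr or amp > hi_thr:
            continue
        events.append(
            Event(
                peak_s=pk / fs,
                start_s=a / fs,
                end_s=b / fs,
                channel=channel,
                amplitude_uv=amp,
                kind="IED",
            )
        )
    region = next(
        (c.region for c in bundle.meta.channels if c.label == channel), "OTHER"
    )
    params = {
        "k_detect": k_detect,
        "k_reject_low": k_reject_low,
        "k_reject_high": k_reject_high,
        "merge_s": merge_s,
        "robust": robust,
        "nrem_only": nrem_only,
    }
    return EventSeries(events=events, kind="IED", region=region, params=params).sort()


# ---------------------------------------------------------------------------
# spindle detection


def detect_spindles(
    bundle: SessionBundle,
    channel: str,
    ied_series: Optional[EventSeries] = None,
    ied_excl_s: float = 0.2,
    k_floor: float = 2.0,
    k_peak_lo: float = 4.0,
    k_peak_hi: float = 14.0,
    merge_gap_s: float = 0.25,
    dur_bounds_s: tuple[float, float] = (0.35, 3.0),
) -> EventSeries:
    """Spindle detector on the 10-20 Hz analytic-signal envelope.

    Baseline mean/SD are computed on NREM samples excluding
    ``+-ied_excl_s`` around each cortical IED peak (and stimulation
    blanks).  Candidate regions are envelope >= baseline + 2 SD with an
    interior peak in [4 SD, 14 SD]; events separated by less than 250 ms
    are merged; the 350-3000 ms duration filter is applied after merging.
    """
    fs = bundle.meta.fs_hz
    n = bundle.lfp.shape[0]
    nrem_mask = bundle.states.mask("NREM", n, fs)
    blanks = stim_blank_intervals(bundle, channel)
    x = interpolate_blanks(bundle.channel(channel), fs, blanks)
    blank = _blank_mask(blanks, n, fs)

    filt = _bandpass(x, fs, 10.0, 20.0)
    env = np.abs(hilbert(filt))

    base_mask = nrem_mask & ~blank
    if ied_series is not None and len(ied_series):
        pad = int(ied_excl_s * fs)
        for t in ied_series.peak_times:
            c = int(t * fs)
            base_mask[max(0, c - pad) : min(n, c + pad + 1)] = False
    if base_mask.sum() / fs < 60.0:
        raise ValueError("less than 60 s of usable NREM baseline")
    # robust baseline: at physiological spindle densities the events
    # themselves inflate a plain mean/SD, so the floor chases its own tail
    v = env[base_mask]
    mu = float(np.median(v))
    sd = float(MAD_SCALE * np.median(np.abs(v - mu)))

    floor = mu + k_floor * sd
    peak_lo, peak_hi = mu + k_peak_lo * sd, mu + k_peak_hi * sd

    cand = (env >= floor) & nrem_mask & ~blank
    regions = []
    for a, b in _runs(cand):
        pk = float(env[a:b].max())
        if peak_lo <= pk <= peak_hi:
            regions.append([a, b])

    merged: list[list[int]] = []
    for a, b in regions:
        if merged and (a - merged[-1][1]) / fs < merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        dur = (b - a) / fs
        if not dur_bounds_s[0] <= dur <= dur_bounds_s[1]:
            continue
        pk = a + int(np.argmax(env[a:b]))
        events.append(
            Event(
                peak_s=pk / fs,
                start_s=a / fs,
                end_s=b / fs,
                channel=channel,
                amplitude_uv=float(env[pk]),
                kind="SPINDLE",
            )
        )
    params = {
        "k_floor": k_floor,
        "k_peak_lo": k_peak_lo,
        "k_peak_hi": k_peak_hi,
        "merge_gap_s": merge_gap_s,
        "dur_bounds_s": list(dur_bounds_s),
        "ied_excl_s": ied_excl_s,
    }
    return EventSeries(events=events, kind="SPINDLE", region="MPFC", params=params).sort()


# ---------------------------------------------------------------------------
# DOWN states


def detect_down_states(
    bundle: SessionBundle,
    lfp_channel: str,
    mua_times: Optional[np.ndarray] = None,
    ied_hc: Optional[EventSeries] = None,
    dur_bounds_s: tuple[float, float] = (0.15, 0.5),
    path_window_s: float = 0.2,
    mua_frac: float = 0.5,
) -> list[DownState]:
    """DOWN states from derivative zero-crossing triples of z-scored
    0.5-6 Hz cortical LFP.

    A local-min -> local-max -> local-min triple (t_start, t_peak, t_end)
    is accepted when Z(t_peak) > 1 and Z(t_end) < -1.5, or Z(t_peak) > 2
    and Z(t_end) < 0, with duration in ``dur_bounds_s``.  ``mua_validated``
    is true when the MUA rate in t_peak +- 100 ms falls below ``mua_frac``
    of the session NREM MUA rate; ``pathological`` is true when an HC IED
    peak lies within ``path_window_s`` before t_start.
    """
    fs = bundle.meta.fs_hz
    n = bundle.lfp.shape[0]
    nrem_mask = bundle.states.mask("NREM", n, fs)
    blanks = stim_blank_intervals(bundle, lfp_channel)
    x = interpolate_blanks(bundle.channel(lfp_channel), fs, blanks)
    blank = _blank_mask(blanks, n, fs)
    filt = _bandpass(x, fs, 0.5, 6.0)
    base = filt[nrem_mask & ~blank]
    if base.size == 0 or base.std() == 0:
        return []
    z = (filt - base.mean()) / base.std()

    dz = np.diff(z)
    sign = np.sign(dz)
    sign[sign == 0] = 1
    flips = np.nonzero(np.diff(sign))[0] + 1
    minima = flips[sign[flips] > 0]  # upward derivative crossing: local min
    maxima = flips[sign[flips] < 0]

    mua_times = np.asarray(mua_times, dtype=float) if mua_times is not None else None
    if mua_times is None or mua_times.size == 0:
        if mua_times is not None and mua_times.size == 0:
            warnings.warn("empty MUA list: mua_validated left unset")
        nrem_rate = None
        mua_times = None
    else:
        nrem_s = nrem_mask.sum() / fs
        in_nrem = np.array(
            [bundle.states.state_at(t) == "NREM" for t in mua_times]
        )
        nrem_rate = in_nrem.sum() / nrem_s if nrem_s > 0 else 0.0

    ied_t = ied_hc.peak_times if ied_hc is not None and len(ied_hc) else np.empty(0)

    out: list[DownState] = []
    for m in maxima:
        i = np.searchsorted(minima, m)
        if i == 0 or i == minima.size:
            continue
        a, b = minima[i - 1], minima[i]
        dur = (b - a) / fs
        if not dur_bounds_s[0] <= dur <= dur_bounds_s[1]:
            continue
        zp, ze = float(z[m]), float(z[b])
        if not ((zp > 1.0 and ze < -1.5) or (zp > 2.0 and ze < 0.0)):
            continue
        if not nrem_mask[m] or blank[max(0, a - 1) : min(n, b + 1)].any():
            continue
        t_start, t_peak, t_end = a / fs, m / fs, b / fs
        validated = None
        if mua_times is not None and nrem_rate is not None:
            cnt = np.searchsorted(mua_times, t_peak + 0.1) - np.searchsorted(
                mua_times, t_peak - 0.1
            )
            validated = bool(nrem_rate > 0 and (cnt / 0.2) < mua_frac * nrem_rate)
        path = bool(
            ied_t.size
            and np.any((ied_t >= t_start - path_window_s) & (ied_t <= t_start))
        )
        out.append(DownState(t_start, t_peak, t_end, zp, ze, validated, path))
    return out


def classify_transitions(
    downs: Sequence[DownState],
) -> tuple[list[DownState], list[DownState]]:
    """Split DOWN states into (pathological, physiological) sublists."""
    path = [d for d in downs if d.pathological]
    phys = [d for d in downs if not d.pathological]
    return path, phys


def downs_to_series(downs: Sequence[DownState], channel: str = "") -> EventSeries:
    events = [
        Event(d.t_peak, d.t_start, d.t_end, channel, abs(d.z_peak), "DOWN")
        for d in downs
    ]
    return EventSeries(
        events=events,
        kind="DOWN",
        region="MPFC",
        params={"pathological": [d.pathological for d in downs]},
    ).sort()


__all__ = [
    "DownState",
    "classify_transitions",
    "detect_down_states",
    "detect_ied",
    "detect_mua",
    "detect_spindles",
    "downs_to_series",
    "score_sleep",
    "stim_blank_intervals",
]
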