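"""Seeded synthetic-session generator.

Produces NREM-dominated multichannel sessions with injected hippocampal
IEDs, coupled cortical DOWN-state -> spindle sequences, independent
cortical IEDs, event-modulated spike trains, an accelerometer channel and
full ground truth, plus a day-indexed kindling schedule for multi-day
cohorts.  Everything is reproducible from ``(params, seed)``; per-day
seeds of a cohort derive from the master seed and the day index so days
can be regenerated independently.

Amplitudes are defined relative to the channel baseline (zero mean); the
generator does not model a reference montage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .types import (
    ChannelInfo,
    EventSeries,
    SessionBundle,
    SessionMeta,
    SpikeUnit,
    StateIntervals,
)

# ---------------------------------------------------------------------------
# parameters


@dataclass
class GenParams:
    """All knobs of a single synthetic session."""

    fs_hz: float = 1250.0
    duration_s: float = 600.0

    # background signal (per-channel pink noise + state-dependent bands)
    noise_sd_uv: float = 40.0
    hc_hf_noise_sd_uv: float = 40.0  # >100 Hz multiunit-band activity on HC
    so_amp_uv: float = 120.0  # 0.5-4 Hz slow oscillation on mPFC during NREM
    theta_amp_uv: float = 90.0  # 5-8 Hz on HC during REM (and WAKE, weaker)
    sharp_noise_sd_uv: float = 6.0  # high-band component scaled by sharpness_gain
    sharpness_gain: float = 1.0

    # hippocampal IEDs
    hc_ied_rate_per_min: float = 3.0
    hc_ied_amp_uv: tuple[float, float] = (500.0, 2500.0)
    hc_ied_sharp_ms: float = 40.0
    hc_ied_slow_ms: float = 250.0
    ied_refractory_s: float = 1.0

    # HC IED -> cortical DOWN -> spindle coupling
    p_couple: float = 0.7
    couple_lag_mean_s: float = 0.15
    couple_lag_sd_s: float = 0.03

    # cortical DOWN states
    down_amp_uv: float = 420.0
    down_pos_s: float = 0.16  # positive-lobe width
    down_neg_s: float = 0.16  # trailing negative (UP onset) lobe width
    down_background_rate_per_min: float = 18.0

    # spindles
    spindle_freq_hz: tuple[float, float] = (10.0, 16.0)
    spindle_dur_s: tuple[float, float] = (0.5, 1.5)
    spindle_amp_uv: float = 72.0
    spindle_amp_jitter_uv: float = 6.0
    spindle_background_rate_per_min: float = 8.0
    spindle_delay_s: float = 0.05  # gap between DOWN end and spindle start

    # independent mPFC IEDs
    ind_mpfc_ied_rate_per_min: float = 0.0
    mpfc_ied_amp_uv: tuple[float, float] = (400.0, 1500.0)

    # spiking units (all mPFC)
    n_pyr: int = 8
    n_int: int = 2
    pyr_rate_hz: float = 1.5
    int_rate_hz: float = 8.0
    ied_gain: float = 5.0
    ied_gain_dur_s: float = 0.05
    down_suppression: float = 0.1
    up_path_gain: float = 2.0
    up_phys_gain: float = 1.2

    # motion channel
    sleep_accel_sd: float = 10.0
    wake_accel_sd: float = 300.0

    # behavioural state schedule (block cycle NREM/REM/NREM/WAKE)
    nrem_bout_s: float = 300.0
    rem_bout_s: float = 60.0
    wake_bout_s: float = 60.0

    def validate(self) -> None:
        if not 0.0 <= self.p_couple <= 1.0:
            raise ValueError("p_couple must lie in [0, 1]")
        for name in (
            "hc_ied_rate_per_min",
            "down_background_rate_per_min",
            "spindle_background_rate_per_min",
            "ind_mpfc_ied_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


@dataclass
class KindlingSchedule:
    """Per-day generator parameters encoding epilepsy progression."""

    days: list[tuple[int, GenParams]]
    condition: str = "KINDLED_ONLY"

    def __post_init__(self) -> None:
        idx = [d for d, _ in self.days]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("day_index must be strictly increasing")

    @property
    def day_indices(self) -> list[int]:
        return [d for d, _ in self.days]


@dataclass
class GroundTruth:
    """Injected-event record of one generated session."""

    events: dict[str, EventSeries]
    coupled_mask: np.ndarray  # per HC IED: coupling drawn
    cancelled_mask: np.ndarray  # per HC IED: coupled sequence cancelled by stim
    links: list[dict]  # {"ied": i, "down": j, "spindle": k} into event series
    unit_gains: dict[str, float]
    params: GenParams
    seed: int
    snr: float = float("nan")

    def times(self, key: str) -> np.ndarray:
        return self.events[key].peak_times if key in self.events else np.empty(0)


# ---------------------------------------------------------------------------
# schedule


def make_kindling_schedule(
    condition: str, n_days: int, seed: int = 0, base: Optional[GenParams] = None
) -> KindlingSchedule:
    """Deterministic multi-day parameter schedule.

    Kindled-family conditions share identical event statistics: HC IED rate
    rises steeply over days 1-10, coupling probability falls from ~0.7 to
    ~0.2 over days 10-20, independent mPFC IED rate rises from ~0 after
    day 10 and the sharpness gain rises monotonically.  BASELINE yields a
    flat schedule.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    base = base if base is not None else GenParams()
    days: list[tuple[int, GenParams]] = []
    flat = condition == "BASELINE"
    for d in range(n_days):
        if flat:
            days.append((d, replace(base)))
            continue
        # sigmoidal HC IED rise over days 1-10; day 0 is baseline-like
        rate = 0.5 + 5.5 / (1.0 + math.exp(-(d - 5.0)))
        # coupling decays over days 10-20
        if d <= 10:
            p_couple = 0.7
        else:
            p_couple = max(0.2, 0.7 - 0.05 * (d - 10))
        # independent mPFC IEDs emerge after day 10
        ind_rate = 0.0 if d <= 10 else min(3.0, 0.35 * (d - 10))
        gain = 1.0 + 0.15 * d
        days.append(
            (
                d,
                replace(
                    base,
                    hc_ied_rate_per_min=rate,
                    p_couple=p_couple,
                    ind_mpfc_ied_rate_per_min=ind_rate,
                    sharpness_gain=gain,
                ),
            )
        )
    return KindlingSchedule(days=days, condition=condition)


def day_seed(master_seed: int, day_index: int) -> int:
    """Counter-based per-day seed derivation (stable across cohort edits)."""
    return int(np.random.SeedSequence([master_seed, day_index]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# session plan (injection times before rendering)


@dataclass
class SessionPlan:
    """Resolved injection plan; rendering consumes it unchanged.

    ``attach_stim_effect`` may cancel coupled DOWN/spindle injections
    before rendering (streaming contract: a stimulation at time t only
    affects signal after t, which holds because the cancelled cortical
    sequence always follows the triggering hippocampal IED).
    """

    params: GenParams
    day_index: int
    seed: int
    states: StateIntervals
    ied_hc_t: np.ndarray
    ied_hc_amp: np.ndarray
    coupled: np.ndarray  # bool per HC IED
    couple_eff_u: np.ndarray  # pre-drawn U(0,1) per HC IED for stim efficacy
    cancelled: np.ndarray  # bool per HC IED
    down_start: np.ndarray  # per coupled HC IED (nan where uncoupled)
    bg_down_t: np.ndarray
    spindle_start: np.ndarray  # per coupled HC IED (nan where uncoupled)
    spindle_dur: np.ndarray
    spindle_freq: np.ndarray
    spindle_amp: np.ndarray
    bg_spindle_t: np.ndarray
    bg_spindle_dur: np.ndarray
    bg_spindle_freq: np.ndarray
    bg_spindle_amp: np.ndarray
    ied_mpfc_t: np.ndarray
    ied_mpfc_amp: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def down_dur_s(self) -> float:
        return self.params.down_pos_s + self.params.down_neg_s


def _poisson_times_in_nrem(
    rng: np.random.Generator,
    intervals: list[tuple[float, float]],
    rate_per_min: float,
    margin_lo: float,
    margin_hi: float,
    refractory_s: float = 0.0,
) -> np.ndarray:
    """Homogeneous Poisson times inside NREM intervals, margin-trimmed."""
    if rate_per_min <= 0 or not intervals:
        return np.empty(0)
    lam = rate_per_min / 60.0
    lens = np.array([e - s for s, e in intervals])
    total = lens.sum()
    if refractory_s > 0:
        mean_gap = max(1.0 / lam - refractory_s, 0.02)
        n_max = int(total / (mean_gap + refractory_s) * 2 + 20)
        gaps = rng.exponential(mean_gap, n_max) + refractory_s
        t_cat = np.cumsum(gaps)
        t_cat = t_cat[t_cat < total]
    else:
        n = rng.poisson(lam * total)
        t_cat = np.sort(rng.uniform(0.0, total, n))
    # map concatenated-NREM time back to session time
    offsets = np.concatenate([[0.0], np.cumsum(lens)])
    idx = np.searchsorted(offsets, t_cat, side="right") - 1
    starts = np.array([s for s, _ in intervals])
    t = starts[idx] + (t_cat - offsets[idx])
    # keep events away from interval edges
    keep = (t_cat - offsets[idx] >= margin_lo) & (offsets[idx + 1] - t_cat >= margin_hi)
    return t[keep]


def make_state_schedule(params: GenParams) -> StateIntervals:
    """Block-based NREM/REM/WAKE schedule cycling until the session ends."""
    cycle = [
        ("NREM", params.nrem_bout_s),
        ("REM", params.rem_bout_s),
        ("NREM", params.nrem_bout_s),
        ("WAKE", params.wake_bout_s),
    ]
    out = []
    t = 0.0
    i = 0
    while t < params.duration_s - 1e-9:
        st, dur = cycle[i % len(cycle)]
        end = min(t + dur, params.duration_s)
        if out and out[-1][2] == st:
            out[-1] = (out[-1][0], end, st)
        else:
            out.append((t, end, st))
        t = end
        i += 1
    return StateIntervals(intervals=out)


def plan_session(params: GenParams, day_index: int = 0, seed: int = 0) -> SessionPlan:
    params.validate()
    ss = np.random.SeedSequence([seed, 101])
    rng = np.random.Generator(np.random.PCG64(ss))
    states = make_state_schedule(params)
    nrem = states.for_state("NREM")
    p = params

    ied_t = _poisson_times_in_nrem(
        rng, nrem, p.hc_ied_rate_per_min, 1.0, 3.0, p.ied_refractory_s
    )
    n_ied = ied_t.size
    ied_amp = rng.uniform(*p.hc_ied_amp_uv, n_ied)
    coupled = rng.random(n_ied) < p.p_couple
    couple_eff_u = rng.random(n_ied)

    lag = np.clip(
        rng.normal(p.couple_lag_mean_s, p.couple_lag_sd_s, n_ied), 0.03, None
    )
    down_start = np.where(coupled, ied_t + lag, np.nan)
    down_dur = p.down_pos_s + p.down_neg_s
    spindle_start = down_start + down_dur + p.spindle_delay_s
    spindle_dur = rng.uniform(*p.spindle_dur_s, n_ied)
    spindle_freq = rng.uniform(*p.spindle_freq_hz, n_ied)
    spindle_amp = np.clip(
        rng.normal(p.spindle_amp_uv, p.spindle_amp_jitter_uv, n_ied),
        p.spindle_amp_uv * 0.85,
        p.spindle_amp_uv * 1.2,
    )

    bg_down = _poisson_times_in_nrem(rng, nrem, p.down_background_rate_per_min, 0.5, 1.0)
    if bg_down.size and n_ied:
        # keep background DOWNs clear of IED-coupled windows so the
        # pathological/physiological split stays unambiguous
        d_ied = np.min(np.abs(bg_down[:, None] - ied_t[None, :]), axis=1)
        cd = down_start[coupled]
        d_cd = (
            np.min(np.abs(bg_down[:, None] - cd[None, :]), axis=1)
            if cd.size
            else np.full(bg_down.size, np.inf)
        )
        bg_down = bg_down[(d_ied > 0.45) & (d_cd > 0.6)]

    bg_spi = _poisson_times_in_nrem(
        rng, nrem, p.spindle_background_rate_per_min, 1.0, 2.0, refractory_s=2.0
    )
    bg_spi_dur = rng.uniform(*p.spindle_dur_s, bg_spi.size)
    bg_spi_freq = rng.uniform(*p.spindle_freq_hz, bg_spi.size)
    bg_spi_amp = np.clip(
        rng.normal(p.spindle_amp_uv, p.spindle_amp_jitter_uv, bg_spi.size),
        p.spindle_amp_uv * 0.85,
        p.spindle_amp_uv * 1.2,
    )
    if bg_spi.size:
        # avoid direct overlap with coupled spindles (the detector's merge
        # rule would fuse them); chance co-occurrence elsewhere is kept so
        # CCG baselines reflect the background rate
        cs = spindle_start[coupled]
        if cs.size:
            d = np.min(np.abs(bg_spi[:, None] - cs[None, :]), axis=1)
            keep = d > 1.8
            bg_spi, bg_spi_dur = bg_spi[keep], bg_spi_dur[keep]
            bg_spi_freq, bg_spi_amp = bg_spi_freq[keep], bg_spi_amp[keep]

    mpfc_ied = _poisson_times_in_nrem(rng, nrem, p.ind_mpfc_ied_rate_per_min, 0.5, 0.5)
    if mpfc_ied.size and n_ied:
        d = np.min(np.abs(mpfc_ied[:, None] - ied_t[None, :]), axis=1)
        mpfc_ied = mpfc_ied[d > 0.3]  # enforce independence (>100 ms rule)
    mpfc_amp = rng.uniform(*p.mpfc_ied_amp_uv, mpfc_ied.size)

    min_len = 2 * (p.couple_lag_mean_s + down_dur + p.spindle_delay_s + max(p.spindle_dur_s))
    if p.hc_ied_rate_per_min > 0 and states.duration("NREM") < min_len:
        raise ValueError("session too short to place the requested coupled events")

    return SessionPlan(
        params=params,
        day_index=day_index,
        seed=seed,
        states=states,
        ied_hc_t=ied_t,
        ied_hc_amp=ied_amp,
        coupled=coupled,
        couple_eff_u=couple_eff_u,
        cancelled=np.zeros(n_ied, dtype=bool),
        down_start=down_start,
        bg_down_t=bg_down,
        spindle_start=spindle_start,
        spindle_dur=spindle_dur,
        spindle_freq=spindle_freq,
        spindle_amp=spindle_amp,
        bg_spindle_t=bg_spi,
        bg_spindle_dur=bg_spi_dur,
        bg_spindle_freq=bg_spi_freq,
        bg_spindle_amp=bg_spi_amp,
        ied_mpfc_t=mpfc_ied,
        ied_mpfc_amp=mpfc_amp,
    )


def attach_stim_effect(
    plan: SessionPlan, stim_times: np.ndarray, p_eff: float, eff_window_s: float = 0.15
) -> SessionPlan:
    """Apply stimulation effects to a session plan before rendering.

    A stimulation landing within ``eff_window_s`` after a coupled HC IED
    cancels — with probability ``p_eff`` (pre-drawn uniforms, so the same
    seed gives the same injections regardless of stimulation) — that
    IED's DOWN + spindle injection and the associated spike modulation.
    Stimulation artifacts are rendered on the mPFC channel at stim times.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    dur = plan.params.duration_s
    in_range = stim_times < dur
    if not np.all(in_range):
        import warnings

        warnings.warn("stimulation times beyond session end ignored")
        stim_times = stim_times[in_range]
    cancelled = plan.cancelled.copy()
    if plan.ied_hc_t.size and stim_times.size:
        for i, t in enumerate(plan.ied_hc_t):
            if not plan.coupled[i]:
                continue
            # detector may fire a few ms before the nominal peak
            j = np.searchsorted(stim_times, t - 0.05)
            hit = j < stim_times.size and stim_times[j] - t <= eff_window_s
            if hit and plan.couple_eff_u[i] < p_eff:
                cancelled[i] = True
    plan.cancelled = cancelled
    plan.stim_times = np.sort(stim_times)
    return plan


# ---------------------------------------------------------------------------
# waveform templates


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, normalized to target SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, sd: float
) -> np.ndarray:
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else x


def ied_template(fs: float, sharp_ms: float = 40.0, slow_ms: float = 250.0) -> np.ndarray:
    """Biphasic IED: difference-of-Gaussians sharp transient + opposite
    polarity slow wave; peak normalized to 1."""
    s1 = sharp_ms / 1000.0 / 10.0
    s2 = sharp_ms / 1000.0 / 3.5
    s3 = slow_ms / 1000.0 / 5.0
    half = slow_ms / 1000.0 * 1.2
    t = np.arange(-half, half + 1.0 / fs, 1.0 / fs)
    sharp = np.exp(-(t**2) / (2 * s1**2)) - 0.55 * np.exp(-(t**2) / (2 * s2**2))
    slow = -0.35 * np.exp(-((t - 0.1) ** 2) / (2 * s3**2))
    w = sharp + slow
    return w / np.abs(w).max()


def down_template(fs: float, pos_s: float, neg_s: float) -> np.ndarray:
    """Positive deflection (DOWN) followed by a negative rebound (UP onset)."""
    tp = np.arange(0, pos_s, 1.0 / fs)
    tn = np.arange(0, neg_s, 1.0 / fs)
    pos = np.sin(np.pi * tp / pos_s)
    neg = -0.75 * np.sin(np.pi * tn / neg_s)
    return np.concatenate([pos, neg])


def spindle_template(fs: float, dur_s: float, freq_hz: float, phase: float = 0.0) -> np.ndarray:
    from scipy.signal.windows import tukey

    t = np.arange(0, dur_s, 1.0 / fs)
    return tukey(t.size, 0.6) * np.sin(2 * np.pi * freq_hz * t + phase)


def stim_artifact_template(fs: float, dur_s: float = 0.2) -> np.ndarray:
    """Gaussian wave opposite in polarity to the (positive) DOWN state."""
    t = np.arange(0, dur_s, 1.0 / fs)
    sd = dur_s / 6.0
    return -np.exp(-((t - dur_s / 2) ** 2) / (2 * sd**2))


def _add(signal: np.ndarray, fs: float, t0: float, w: np.ndarray, amp: float) -> None:
    i0 = int(round(t0 * fs))
    if i0 >= signal.size or i0 + w.size <= 0:
        return
    a = max(i0, 0)
    b = min(i0 + w.size, signal.size)
    signal[a:b] += amp * w[a - i0 : b - i0]


# ---------------------------------------------------------------------------
# rendering


def render_session(plan: SessionPlan) -> SessionBundle:
    p = plan.params
    fs = p.fs_hz
    n = int(round(p.duration_s * fs))
    ss = np.random.SeedSequence([plan.seed, 202])
    rng_noise, rng_spk, rng_unit = [
        np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3)
    ]

    nrem_mask = plan.states.mask("NREM", n, fs)
    rem_mask = plan.states.mask("REM", n, fs)
    wake_mask = plan.states.mask("WAKE", n, fs)

    hc = _pink_noise(rng_noise, n, p.noise_sd_uv)
    if p.hc_hf_noise_sd_uv > 0:
        hc += _band_noise(rng_noise, n, fs, 100.0, 550.0, p.hc_hf_noise_sd_uv)
    hc += _band_noise(rng_noise, n, fs, 5.0, 8.0, p.theta_amp_uv) * (
        rem_mask + 0.4 * wake_mask
    )
    mpfc = _pink_noise(rng_noise, n, p.noise_sd_uv)
    mpfc += _band_noise(rng_noise, n, fs, 0.5, 4.0, p.so_amp_uv) * nrem_mask
    if p.sharp_noise_sd_uv > 0:
        mpfc += (
            _band_noise(rng_noise, n, fs, 80.0, 300.0, p.sharp_noise_sd_uv)
            * p.sharpness_gain
            * nrem_mask
        )
    accel = rng_noise.normal(0.0, p.sleep_accel_sd, n)
    accel += rng_noise.normal(0.0, p.wake_accel_sd, n) * wake_mask

    w_ied = ied_template(fs, p.hc_ied_sharp_ms, p.hc_ied_slow_ms)
    ied_center = int(np.argmax(w_ied))
    for t, a in zip(plan.ied_hc_t, plan.ied_hc_amp):
        _add(hc, fs, t - ied_center / fs, w_ied, a)

    w_down = down_template(fs, p.down_pos_s, p.down_neg_s)
    active = plan.coupled & ~plan.cancelled
    for t in plan.down_start[active]:
        _add(mpfc, fs, t, w_down, p.down_amp_uv)
    for t in plan.bg_down_t:
        _add(mpfc, fs, t, w_down, p.down_amp_uv)

    for t, d, f, a in zip(
        plan.spindle_start[active],
        plan.spindle_dur[active],
        plan.spindle_freq[active],
        plan.spindle_amp[active],
    ):
        _add(mpfc, fs, t, spindle_template(fs, d, f), a)
    for t, d, f, a in zip(
        plan.bg_spindle_t, plan.bg_spindle_dur, plan.bg_spindle_freq, plan.bg_spindle_amp
    ):
        _add(mpfc, fs, t, spindle_template(fs, d, f), a)

    for t, a in zip(plan.ied_mpfc_t, plan.ied_mpfc_amp):
        _add(mpfc, fs, t - ied_center / fs, w_ied, a)

    w_stim = stim_artifact_template(fs)
    for t in plan.stim_times:
        _add(mpfc, fs, t, w_stim, 800.0)

    units, unit_gains = _simulate_units(plan, rng_spk, rng_unit)

    channels = [
        ChannelInfo("hc0", "HC", "LFP", uv_per_bit=0.2),
        ChannelInfo("mpfc0", "MPFC", "LFP", uv_per_bit=0.2),
        ChannelInfo("accel0", "OTHER", "ACCEL", uv_per_bit=0.2),
    ]
    meta = SessionMeta(
        session_id=f"synth-d{plan.day_index:02d}-s{plan.seed}",
        fs_hz=fs,
        n_samples=n,
        channels=channels,
        day_index=plan.day_index,
        seed=plan.seed,
    )
    lfp = np.column_stack([hc, mpfc, accel])

    gt = _ground_truth(plan, unit_gains)
    gt.snr = float(plan.ied_hc_amp.mean() / p.noise_sd_uv) if plan.ied_hc_t.size else float("nan")

    event_series = {}
    if plan.stim_times.size:
        event_series["stim"] = EventSeries.from_times(
            plan.stim_times, kind="STIM", region="MPFC", channel="mpfc0", width_s=0.2
        )

    return SessionBundle(
        meta=meta,
        lfp=lfp,
        states=plan.states,
        units=units,
        event_series=event_series,
        ground_truth=gt,
    )


def _simulate_units(
    plan: SessionPlan, rng_spk: np.random.Generator, rng_unit: np.random.Generator
) -> tuple[list[SpikeUnit], dict[str, float]]:
    p = plan.params
    n_units = p.n_pyr + p.n_int
    if n_units == 0:
        return [], {}
    dt = 1e-3
    nb = int(round(p.duration_s / dt))

    def win_mask(starts, durs):
        m = np.zeros(nb, dtype=bool)
        starts = np.atleast_1d(np.asarray(starts, dtype=float))
        durs = np.broadcast_to(np.atleast_1d(np.asarray(durs, dtype=float)), starts.shape)
        for t, d in zip(starts, durs):
            if np.isnan(t):
                continue
            a = max(int(t / dt), 0)
            b = min(int((t + d) / dt) + 1, nb)
            m[a:b] = True
        return m

    active = plan.coupled & ~plan.cancelled
    burst_ied = ~plan.cancelled  # stim aborts the cortical burst as well
    m_burst_hc = win_mask(plan.ied_hc_t[burst_ied] + 0.005, p.ied_gain_dur_s)
    m_burst_mpfc = win_mask(plan.ied_mpfc_t + 0.005, p.ied_gain_dur_s)
    down_dur = plan.down_dur_s
    m_down = win_mask(plan.down_start[active], down_dur) | win_mask(plan.bg_down_t, down_dur)
    m_up_path = win_mask(plan.down_start[active] + p.down_pos_s, 0.5)
    m_up_phys = win_mask(plan.bg_down_t + p.down_pos_s, 0.5)
    m_up_path &= ~m_down
    m_up_phys &= ~m_down & ~m_up_path

    units: list[SpikeUnit] = []
    unit_gains: dict[str, float] = {}
    for i in range(n_units):
        is_pyr = i < p.n_pyr
        base = (p.pyr_rate_hz if is_pyr else p.int_rate_hz) * rng_unit.lognormal(0, 0.3)
        g = float(rng_unit.lognormal(0, 0.4))  # shared IED-response gain
        unit_gains_i = 1.0 + (p.ied_gain - 1.0) * g
        rate = np.full(nb, base)
        rate[m_burst_hc] *= unit_gains_i
        rate[m_burst_mpfc] *= unit_gains_i
        rate[m_up_path] *= p.up_path_gain
        rate[m_up_phys] *= p.up_phys_gain
        rate[m_down] *= p.down_suppression
        prob = np.clip(rate * dt, 0.0, 1.0)
        hit = rng_spk.random(nb) < prob
        idx = np.nonzero(hit)[0]
        times = (idx + rng_spk.random(idx.size)) * dt
        uid = f"u{i:03d}"
        units.append(
            SpikeUnit(uid, times, region="MPFC", cell_class="PYR" if is_pyr else "INT")
        )
        unit_gains[uid] = g
    return units, unit_gains


def _ground_truth(plan: SessionPlan, unit_gains: dict[str, float]) -> GroundTruth:
    p = plan.params
    active = plan.coupled & ~plan.cancelled
    down_dur = plan.down_dur_s

    ev = {}
    ev["ied_hc"] = EventSeries.from_times(
        plan.ied_hc_t,
        kind="IED",
        region="HC",
        channel="hc0",
        width_s=0.08,
        amplitudes=plan.ied_hc_amp,
    )
    down_t = np.concatenate([plan.down_start[active], plan.bg_down_t])
    down_path = np.concatenate(
        [np.ones(int(active.sum()), dtype=bool), np.zeros(plan.bg_down_t.size, dtype=bool)]
    )
    order = np.argsort(down_t)
    down_t, down_path = down_t[order], down_path[order]
    from .types import Event

    ev["down_mpfc"] = EventSeries(
        events=[
            Event(t + p.down_pos_s / 2, t, t + down_dur, "mpfc0", p.down_amp_uv, "DOWN")
            for t in down_t
        ],
        kind="DOWN",
        region="MPFC",
        params={"pathological": down_path.tolist()},
    )
    spi_start = np.concatenate([plan.spindle_start[active], plan.bg_spindle_t])
    spi_dur = np.concatenate([plan.spindle_dur[active], plan.bg_spindle_dur])
    spi_amp = np.concatenate([plan.spindle_amp[active], plan.bg_spindle_amp])
    spi_coupled = np.concatenate(
        [np.ones(int(active.sum()), dtype=bool), np.zeros(plan.bg_spindle_t.size, dtype=bool)]
    )
    order = np.argsort(spi_start)
    spi_start, spi_dur, spi_amp, spi_coupled = (
        spi_start[order],
        spi_dur[order],
        spi_amp[order],
        spi_coupled[order],
    )
    ev["spindle_mpfc"] = EventSeries(
        events=[
            Event(t + d / 2, t, t + d, "mpfc0", a, "SPINDLE")
            for t, d, a in zip(spi_start, spi_dur, spi_amp)
        ],
        kind="SPINDLE",
        region="MPFC",
        params={"coupled": spi_coupled.tolist()},
    )
    ev["ied_mpfc"] = EventSeries.from_times(
        plan.ied_mpfc_t,
        kind="IED",
        region="MPFC",
        channel="mpfc0",
        width_s=0.08,
        amplitudes=plan.ied_mpfc_amp,
    )
    if plan.stim_times.size:
        ev["stim"] = EventSeries.from_times(
            plan.stim_times, kind="STIM", region="MPFC", channel="mpfc0", width_s=0.2
        )

    # links: HC IED i -> its coupled DOWN/spindle indices in the sorted series
    links = []
    if int(active.sum()):
        down_times_sorted = ev["down_mpfc"].peak_times
        spi_times_sorted = ev["spindle_mpfc"].peak_times
        for i in np.nonzero(active)[0]:
            dt_ = plan.down_start[i] + p.down_pos_s / 2
            st_ = plan.spindle_start[i] + plan.spindle_dur[i] / 2
            j = int(np.argmin(np.abs(down_times_sorted - dt_)))
            k = int(np.argmin(np.abs(spi_times_sorted - st_)))
            links.append({"ied": int(i), "down": j, "spindle": k})

    return GroundTruth(
        events=ev,
        coupled_mask=plan.coupled.copy(),
        cancelled_mask=plan.cancelled.copy(),
        links=links,
        unit_gains=unit_gains,
        params=p,
        seed=plan.seed,
    )


# ---------------------------------------------------------------------------
# public generation API


def generate_session(params: GenParams, day_index: int = 0, seed: int = 0) -> SessionBundle:
    """Generate one fully rendered session with ground truth."""
    return render_session(plan_session(params, day_index, seed))


def generate_events(params: GenParams, day_index: int = 0, seed: int = 0) -> GroundTruth:
    """Ground truth only (no LFP/spike rendering) — cheap for long sessions."""
    plan = plan_session(params, day_index, seed)
    return _ground_truth(plan, {})


def generate_cohort(schedule: KindlingSchedule, seed: int = 0) -> list[SessionBundle]:
    """One session per schedule day; per-day seeds derive from the master."""
    out = []
    for d, params in schedule.days:
        bundle = generate_session(params, day_index=d, seed=day_seed(seed, d))
        bundle.meta.condition = schedule.condition
        out.append(bundle)
    return out


__all__ = [
    "GenParams",
    "GroundTruth",
    "KindlingSchedule",
    "SessionPlan",
    "attach_stim_effect",
    "day_seed",
    "down_template",
    "generate_cohort",
    "generate_events",
    "generate_session",
    "ied_template",
    "make_kindling_schedule",
    "make_state_schedule",
    "plan_session",
    "render_session",
    "spindle_template",
    "stim_artifact_template",
]
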