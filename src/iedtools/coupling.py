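"""Event-coupling and spectral statistics.

Cross-correlograms use the convolution method: the per-bin expected
baseline is the raw CCG convolved with a hollow (center-zeroed,
renormalized) Gaussian kernel, and 95% bounds come from a Poisson
distribution with that per-bin mean.  Coupling modulation is
``M = (a - b) / b`` with ``a`` the CCG peak above the upper bound inside
the zero-centered test window and ``b`` the baseline at that bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.signal import butter, fftconvolve, sosfiltfilt
from scipy.signal.windows import dpss

from .types import EventSeries, SessionBundle, StateIntervals


# ---------------------------------------------------------------------------
# CCG


@dataclass
class CCGResult:
    bin_s: float
    lags_s: np.ndarray
    counts: np.ndarray
    baseline_b: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_ref: int
    n_tgt: int
    a: float = float("nan")
    b: float = float("nan")
    M: float = float("nan")
    peak_lag_s: float = float("nan")
    low_count_warning: bool = False


def hollow_gaussian_kernel(
    bin_s: float, kernel_sd_s: float, hollow_radius_s: Optional[float] = None
) -> np.ndarray:
    """Gaussian kernel with the center hollowed out, renormalized to sum 1.

    By default only the center bin is zeroed; a wider ``hollow_radius_s``
    excludes the whole coupling-peak neighbourhood from the baseline
    estimate, which matters when the coupling lag density is narrow
    relative to the kernel.
    """
    half = max(1, int(math.ceil(3 * kernel_sd_s / bin_s)))
    x = np.arange(-half, half + 1) * bin_s
    w = np.exp(-(x**2) / (2 * kernel_sd_s**2))
    if hollow_radius_s is None:
        w[half] = 0.0
    else:
        w[np.abs(x) <= hollow_radius_s + 1e-12] = 0.0
    if w.sum() <= 0:
        raise ValueError("hollow radius leaves an empty kernel")
    return w / w.sum()


def ccg_convolution(
    ref: np.ndarray,
    tgt: np.ndarray,
    bin_s: float = 0.01,
    window_s: float = 1.0,
    kernel_sd_s: float = 0.1,
    min_ref: int = 20,
    hollow_radius_s: Optional[float] = None,
) -> CCGResult:
    """Binned CCG of target events around reference events with a
    convolution baseline and per-bin Poisson 95% bounds."""
    ref = np.sort(np.asarray(ref, dtype=float))
    tgt = np.sort(np.asarray(tgt, dtype=float))
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("empty event series")
    low = ref.size < min_ref
    if low:
        warnings.warn(f"only {ref.size} reference events (< {min_ref})")

    k = int(round(window_s / bin_s))
    lags = np.arange(-k, k + 1) * bin_s
    edges = np.concatenate([lags - bin_s / 2, [lags[-1] + bin_s / 2]])
    idx = np.searchsorted(tgt, ref[:, None] + edges[None, :])
    counts = np.diff(idx, axis=1).sum(axis=0).astype(float)

    w = hollow_gaussian_kernel(bin_s, kernel_sd_s, hollow_radius_s)
    num = fftconvolve(counts, w, mode="same")
    den = fftconvolve(np.ones_like(counts), w, mode="same")
    baseline = np.clip(num / den, 0.0, None)
    baseline[baseline < 1e-9] = 0.0  # fftconvolve residue on empty bins

    ci_low = stats.poisson.ppf(0.025, baseline)
    ci_high = stats.poisson.ppf(0.975, baseline)
    ci_low = np.where(baseline <= 0, 0.0, ci_low)
    ci_high = np.where(baseline <= 0, 0.0, ci_high)

    return CCGResult(
        bin_s=bin_s,
        lags_s=lags,
        counts=counts,
        baseline_b=baseline,
        ci_low=ci_low,
        ci_high=ci_high,
        n_ref=int(ref.size),
        n_tgt=int(tgt.size),
        low_count_warning=low,
    )


def coupling_modulation(
    ccg: CCGResult, test_window_s: float = 0.05, zero_bin_only: bool = False
) -> float:
    """Coupling modulation M = (a - b)/b inside the zero-centered window.

    ``a`` is the largest count among window bins exceeding the Poisson
    upper bound; when no bin exceeds it, a := b so M = 0 (non-significant
    coupling is reported as zero, not negative).
    """
    if zero_bin_only:
        in_win = np.isclose(ccg.lags_s, 0.0)
    else:
        in_win = np.abs(ccg.lags_s) <= test_window_s + 1e-12
    counts = ccg.counts[in_win]
    base = ccg.baseline_b[in_win]
    hi = ccg.ci_high[in_win]
    lags = ccg.lags_s[in_win]
    sig = (counts > hi) & (base > 0)
    if not sig.any():
        center = int(np.argmin(np.abs(lags)))
        b = float(base[center])
        if b <= 0:
            raise ValueError("degenerate baseline (b = 0) at peak bin")
        ccg.a, ccg.b, ccg.M, ccg.peak_lag_s = b, b, 0.0, float(lags[center])
        return 0.0
    j = int(np.argmax(np.where(sig, counts, -np.inf)))
    a = float(counts[j])
    b = float(base[j])
    if b <= 0:
        raise ValueError("degenerate baseline (b = 0) at peak bin")
    m = (a - b) / b
    ccg.a, ccg.b, ccg.M, ccg.peak_lag_s = a, b, m, float(lags[j])
    return m


def ccg_brute_force(
    ref: np.ndarray, tgt: np.ndarray, bin_s: float = 0.01, window_s: float = 1.0
) -> np.ndarray:
    """O(n^2) nested-loop CCG counts — independent oracle for tests."""
    ref = np.sort(np.asarray(ref, dtype=float))
    tgt = np.sort(np.asarray(tgt, dtype=float))
    k = int(round(window_s / bin_s))
    counts = np.zeros(2 * k + 1)
    for r in ref:
        for t in tgt:
            lag = t - r
            j = int(np.floor((lag + bin_s / 2) / bin_s)) + k
            if 0 <= j <= 2 * k:
                counts[j] += 1
    return counts


# ---------------------------------------------------------------------------
# independence


def classify_independent(
    tgt: EventSeries | np.ndarray, ref: EventSeries | np.ndarray, radius_s: float = 0.1
) -> tuple[np.ndarray, float]:
    """Flag target events with no reference peak within ``radius_s``."""
    t = tgt.peak_times if isinstance(tgt, EventSeries) else np.asarray(tgt, float)
    r = ref.peak_times if isinstance(ref, EventSeries) else np.asarray(ref, float)
    if t.size == 0:
        return np.empty(0, dtype=bool), float("nan")
    if r.size == 0:
        return np.ones(t.size, dtype=bool), 1.0
    r = np.sort(r)
    i = np.searchsorted(r, t)
    left = np.where(i > 0, t - r[np.clip(i - 1, 0, r.size - 1)], np.inf)
    right = np.where(i < r.size, r[np.clip(i, 0, r.size - 1)] - t, np.inf)
    nearest = np.minimum(left, right)
    flags = nearest > radius_s
    return flags, float(flags.mean())


def independence_matrix(
    foci: dict[str, EventSeries | np.ndarray], soz_key: str, radius_s: float = 0.1
) -> dict[str, float]:
    """Per-focus ratio of IEDs independent (> radius) from SOZ IEDs."""
    if soz_key not in foci:
        raise KeyError(f"unknown seizure-onset key {soz_key!r}")
    if len(foci) < 2:
        raise ValueError("need at least two foci")
    out = {}
    for key, series in foci.items():
        if key == soz_key:
            out[key] = 0.0
        else:
            _, frac = classify_independent(series, foci[soz_key], radius_s)
            out[key] = frac
    return out


def occurrence_rate(
    series: EventSeries | np.ndarray, states: StateIntervals, state: str = "NREM"
) -> float:
    """Events per minute of the given behavioural state."""
    minutes = states.duration(state) / 60.0
    if minutes <= 0:
        raise ValueError(f"zero {state} time")
    t = series.peak_times if isinstance(series, EventSeries) else np.asarray(series, float)
    n = sum(
        1 for x in t if any(s <= x < e for s, e in states.for_state(state))
    )
    return n / minutes


# ---------------------------------------------------------------------------
# spectral


def gabor_spectrogram(
    signal: np.ndarray,
    fs: float,
    freqs: Sequence[float],
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Complex Morlet (Gabor) wavelet power, shape (n_freqs, n_samples).

    Normalized so that for a pure sinusoid of amplitude A the power at its
    frequency approaches A^2/2, i.e. the signal variance.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    x = np.asarray(signal, dtype=float)
    out = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        sigma = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sigma * fs))
        t = np.arange(-half, half + 1) / fs
        env = np.exp(-(t**2) / (2 * sigma**2))
        kernel = env * np.exp(2j * np.pi * f * t)
        kernel /= env.sum() / 2.0  # amplitude-recovering normalization
        w = fftconvolve(x, np.conj(kernel[::-1]), mode="same")
        out[i] = np.abs(w) ** 2 / 2.0
    return out


def spindle_band_power(
    bundle: SessionBundle,
    channel: str,
    windows: Sequence[tuple[float, float]],
    band_hz: tuple[float, float] = (10.0, 20.0),
    min_window_s: float = 0.25,
) -> np.ndarray:
    """Mean band power per window, z-scored against equal-length NREM
    windows tiled across the same session.  Stimulation artifacts on the
    channel are interpolated out before filtering."""
    from .detect import interpolate_blanks, stim_blank_intervals

    fs = bundle.meta.fs_hz
    x = interpolate_blanks(
        bundle.channel(channel), fs, stim_blank_intervals(bundle, channel)
    )
    sos = butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    p = sosfiltfilt(sos, x) ** 2

    def win_mean(s: float, e: float) -> float:
        a, b = int(s * fs), int(e * fs)
        if b <= a:
            return float("nan")
        return float(p[a:b].mean())

    vals = []
    for s, e in windows:
        if e - s < min_window_s:
            raise ValueError(f"window [{s}, {e}) shorter than {min_window_s} s")
        if s < 0 or e > bundle.duration_s:
            raise ValueError("window outside session")
        vals.append(win_mean(s, e))
    vals = np.asarray(vals)

    wlen = float(np.median([e - s for s, e in windows]))
    ref = []
    for s, e in bundle.states.for_state("NREM"):
        t = s
        while t + wlen <= e:
            ref.append(win_mean(t, t + wlen))
            t += wlen
    ref = np.asarray(ref)
    if ref.size < 10:
        raise ValueError("insufficient NREM reference windows")
    mu, sd = ref.mean(), ref.std()
    if sd == 0:
        raise ValueError("zero-variance NREM reference")
    return (vals - mu) / sd


@dataclass
class CoherenceResult:
    freqs_hz: np.ndarray
    coherence: np.ndarray
    n_segments: int
    normalization: str = "NONE"


def multitaper_coherence(
    bundle: SessionBundle,
    ch_a: str,
    ch_b: str,
    states: Optional[Sequence[str]] = None,
    seg_s: float = 10.0,
    n_segments: int = 100,
    seed: int = 0,
    nw: float = 3.0,
    n_tapers: int = 5,
    normalization: str = "NONE",
    fmin: float = 1.0,
    fmax: float = 100.0,
) -> CoherenceResult:
    """Multitaper coherence |C(f)| on randomly selected disjoint segments.

    C(f) = S12 / sqrt(S11 S22) with cross/auto spectra averaged over
    segments and tapers (time-bandwidth ``nw``, ``n_tapers`` tapers).
    ``normalization='MEAN_1_100'`` divides by the mean over the 1-100 Hz
    band.
    """
    fs = bundle.meta.fs_hz
    nseg = int(round(seg_s * fs))
    candidates = []
    ivs = (
        bundle.states.intervals
        if bundle.states.intervals
        else [(0.0, bundle.duration_s, "WAKE")]
    )
    for s, e, st in ivs:
        if states is not None and st not in states:
            continue
        t = s
        while t + seg_s <= e:
            candidates.append(t)
            t += seg_s
    if len(candidates) < 5:
        raise ValueError("fewer than 5 usable segments")
    rng = np.random.default_rng(seed)
    if len(candidates) < n_segments:
        warnings.warn(
            f"only {len(candidates)} segments available (< {n_segments})"
        )
        picked = np.asarray(candidates)
    else:
        picked = rng.choice(np.asarray(candidates), n_segments, replace=False)

    tapers = dpss(nseg, nw, n_tapers)
    xa = bundle.channel(ch_a)
    xb = bundle.channel(ch_b)
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)

    s11 = np.zeros(sel.sum())
    s22 = np.zeros(sel.sum())
    s12 = np.zeros(sel.sum(), dtype=complex)
    for t0 in picked:
        a = int(round(t0 * fs))
        sa = xa[a : a + nseg]
        sb = xb[a : a + nseg]
        fa = np.fft.rfft(tapers * (sa - sa.mean()), axis=1)[:, sel]
        fb = np.fft.rfft(tapers * (sb - sb.mean()), axis=1)[:, sel]
        s11 += (np.abs(fa) ** 2).mean(axis=0)
        s22 += (np.abs(fb) ** 2).mean(axis=0)
        s12 += (fa * np.conj(fb)).mean(axis=0)
    denom = np.sqrt(s11 * s22)
    coh = np.abs(np.where(denom > 0, s12 / np.where(denom > 0, denom, 1.0), 0.0))
    if normalization == "MEAN_1_100":
        coh = coh / coh.mean()
    elif normalization != "NONE":
        raise ValueError(f"unknown normalization {normalization!r}")
    return CoherenceResult(
        freqs_hz=freqs[sel],
        coherence=coh,
        n_segments=int(len(picked)),
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# cohort trends


def mann_kendall(values: Sequence[float]) -> tuple[float, float]:
    """Mann-Kendall trend test: (tau, two-sided p).

    Exact enumeration of the S null distribution for n <= 10 without
    ties; otherwise normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values")
    s = 0
    for i in range(n - 1):
        s += int(np.sign(x[i + 1 :] - x[i]).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    denom = n * (n - 1) / 2
    if has_ties:
        t1 = (tie_counts * (tie_counts - 1) / 2).sum()
        d = math.sqrt((denom - t1) * denom)
        tau = s / d if d > 0 else 0.0
    else:
        tau = s / denom

    if n <= 10 and not has_ties:
        dist = _exact_s_distribution(n)
        smax = int(denom)
        probs = dist / dist.sum()
        vals = np.arange(-smax, smax + 1, 2)
        p = float(probs[np.abs(vals) >= abs(s)].sum())
    else:
        var = (
            n * (n - 1) * (2 * n + 5)
            - (tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)).sum()
        ) / 18.0
        if var <= 0:
            return float(tau), 1.0
        z = (s - np.sign(s)) / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(tau), min(p, 1.0)


def _exact_s_distribution(n: int) -> np.ndarray:
    """Counts over S = -n(n-1)/2 .. +n(n-1)/2 step 2 (via inversions)."""
    poly = np.array([1.0])
    for k in range(1, n):
        poly = np.convolve(poly, np.ones(k + 1))
    return poly[::-1]  # inversions -> S is an order reversal; symmetric anyway


def fit_occurrence_trajectories(
    day_rates: dict[str, Sequence[float]],
    days: Optional[Sequence[float]] = None,
) -> dict:
    """Cubic least-squares fit per series plus pairwise extra-sum-of-squares
    F tests of shared versus separate curves (df = 4, n_total - 8)."""
    if len(day_rates) < 2:
        raise ValueError("need at least two series")
    fits = {}
    for name, y in day_rates.items():
        y = np.asarray(y, dtype=float)
        if y.size < 8:
            raise ValueError(f"series {name!r}: need >= 8 days")
        x = np.asarray(days, float) if days is not None else np.arange(y.size, dtype=float)
        coef = np.polyfit(x, y, 3)
        resid = y - np.polyval(coef, x)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        fits[name] = {
            "coef": coef,
            "ss_res": ss_res,
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            "x": x,
            "y": y,
        }
    names = list(day_rates)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = fits[names[i]], fits[names[j]]
            x = np.concatenate([a["x"], b["x"]])
            y = np.concatenate([a["y"], b["y"]])
            coef = np.polyfit(x, y, 3)
            ss_shared = float(((y - np.polyval(coef, x)) ** 2).sum())
            ss_sep = a["ss_res"] + b["ss_res"]
            n_tot = y.size
            df2 = n_tot - 8
            if df2 <= 0:
                raise ValueError("too few days for the F comparison")
            if ss_sep <= 0:
                f_stat = 0.0 if ss_shared <= ss_sep + 1e-12 else float("inf")
            else:
                f_stat = ((ss_shared - ss_sep) / 4.0) / (ss_sep / df2)
            f_stat = max(f_stat, 0.0)
            p = float(stats.f.sf(f_stat, 4, df2)) if np.isfinite(f_stat) else 0.0
            pairwise[(names[i], names[j])] = {"F": f_stat, "p": p, "df": (4, df2)}
    return {"fits": {k: {kk: v[kk] for kk in ("coef", "ss_res", "r2")} for k, v in fits.items()},
            "pairwise": pairwise}


def composite_responsiveness(
    m_spindle: Sequence[float],
    m_down: Sequence[float],
    mua_modulation: Sequence[float],
) -> np.ndarray:
    """Equal-weight mean of cohort z-scores of the three coupling measures."""
    cols = [np.asarray(v, dtype=float) for v in (m_spindle, m_down, mua_modulation)]
    n = cols[0].size
    if n < 3 or any(c.size != n for c in cols):
        raise ValueError("need >= 3 sessions with all three measures")
    zs = []
    for c in cols:
        sd = c.std()
        if sd == 0:
            warnings.warn("zero-variance measure dropped from composite")
            continue
        zs.append((c - c.mean()) / sd)
    if not zs:
        raise ValueError("all measures degenerate")
    return np.mean(zs, axis=0)


__all__ = [
    "CCGResult",
    "CoherenceResult",
    "ccg_brute_force",
    "ccg_convolution",
    "classify_independent",
    "composite_responsiveness",
    "coupling_modulation",
    "fit_occurrence_trajectories",
    "gabor_spectrogram",
    "hollow_gaussian_kernel",
    "independence_matrix",
    "mann_kendall",
    "multitaper_coherence",
    "occurrence_rate",
    "spindle_band_power",
]
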