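"""Population-rate construction and peri-event spiking modulation.

Significance uses a jittered-permutation maximum-deviation test on the
event-locked cumulative spike density (a binning-free temporal-deviation
statistic); the observed KS-type deviation is compared against a null
built by uniformly jittering event times.  Sessions with fewer than 20
events are excluded from modulation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .detect import DownState
from .types import SpikeUnit, StateIntervals

MIN_EVENTS = 20


@dataclass
class ModulationResult:
    unit_id: str
    event_kind: str
    n_events: int
    p_value: float = float("nan")
    ifr_peak_norm: float = float("nan")
    latency_s: float = float("nan")
    significant: Optional[bool] = None
    excluded: bool = False


def population_rate(
    units: Sequence[SpikeUnit],
    duration_s: float,
    states: Optional[StateIntervals] = None,
    normalize: bool = False,
    smooth_sd_s: float = 0.05,
) -> np.ndarray:
    """Summed single-unit activity at 1 ms resolution, smoothed with a
    Gaussian window (SD ``smooth_sd_s``); optionally normalized by the
    session NREM mean rate."""
    if not units:
        raise ValueError("need at least one unit")
    dt = 1e-3
    nb = int(round(duration_s / dt))
    counts = np.zeros(nb)
    total = 0
    for u in units:
        idx = np.floor(u.spike_times_s / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < nb)]
        np.add.at(counts, idx, 1.0)
        total += idx.size
    if total == 0:
        warnings.warn("no spikes: population rate is all zero")
        return counts
    rate = gaussian_filter1d(counts, smooth_sd_s / dt, mode="nearest") / dt
    if normalize:
        if states is not None:
            m = states.mask("NREM", nb, 1.0 / dt)
            base = rate[m].mean() if m.any() else rate.mean()
        else:
            base = rate.mean()
        if base <= 0:
            raise ValueError("zero baseline population rate")
        rate = rate / base
    return rate


def _rel_spikes(spikes: np.ndarray, events: np.ndarray, w: float) -> np.ndarray:
    i0 = np.searchsorted(spikes, events - w)
    i1 = np.searchsorted(spikes, events + w)
    parts = [spikes[a:b] - t for a, b, t in zip(i0, i1, events)]
    return np.concatenate(parts) if parts else np.empty(0)


def _deviation_stat(rel: np.ndarray, w: float) -> float:
    """sqrt(n)-scaled max deviation of the event-locked cumulative spike
    density from its linear (uniform) baseline."""
    n = rel.size
    if n == 0:
        return 0.0
    u = np.sort((rel + w) / (2 * w))
    grid = np.arange(1, n + 1) / n
    d = max(np.max(grid - u), np.max(u - (grid - 1.0 / n)))
    return float(np.sqrt(n) * d)


def peri_event_modulation(
    unit: SpikeUnit,
    events: np.ndarray,
    window_s: float = 1.0,
    n_perm: int = 500,
    jitter_s: float = 2.0,
    seed: int = 0,
    states: Optional[StateIntervals] = None,
    duration_s: Optional[float] = None,
    event_kind: str = "EVENT",
    alpha: float = 0.05,
    ifr_sd_s: float = 0.01,
) -> ModulationResult:
    """Jitter-permutation modulation test plus IFR peak/latency.

    The instantaneous firing rate is the Gaussian-kernel (SD 10 ms)
    event-averaged rate; ``ifr_peak_norm`` divides its in-window peak by
    the unit baseline rate (NREM spikes outside +-1 s of analyzed events;
    total-session rate when no state scoring is supplied).
    """
    events = np.sort(np.asarray(events, dtype=float))
    if duration_s is not None:
        ok = (events >= window_s) & (events <= duration_s - window_s)
        if not ok.all():
            warnings.warn("events near session edges dropped")
            events = events[ok]
    if events.size < MIN_EVENTS:
        return ModulationResult(unit.unit_id, event_kind, int(events.size), excluded=True)

    spikes = unit.spike_times_s
    rel = _rel_spikes(spikes, events, window_s)
    obs = _deviation_stat(rel, window_s)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        jit = events + rng.uniform(-jitter_s, jitter_s, events.size)
        null[k] = _deviation_stat(_rel_spikes(spikes, np.sort(jit), window_s), window_s)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)

    # event-averaged IFR
    dt = 1e-3
    nb = int(round(2 * window_s / dt))
    hist, _ = np.histogram(rel, bins=nb, range=(-window_s, window_s))
    ifr = gaussian_filter1d(hist.astype(float), ifr_sd_s / dt, mode="nearest") / (
        events.size * dt
    )
    base = _baseline_rate(unit, events, window_s, states, duration_s)
    peak_i = int(np.argmax(ifr))
    ifr_peak_norm = float(ifr[peak_i] / base) if base > 0 else float("nan")
    sig = bool(p < alpha)
    latency = float(-window_s + (peak_i + 0.5) * dt) if sig else float("nan")
    return ModulationResult(
        unit_id=unit.unit_id,
        event_kind=event_kind,
        n_events=int(events.size),
        p_value=float(p),
        ifr_peak_norm=ifr_peak_norm,
        latency_s=latency,
        significant=sig,
    )


def _baseline_rate(
    unit: SpikeUnit,
    events: np.ndarray,
    window_s: float,
    states: Optional[StateIntervals],
    duration_s: Optional[float],
) -> float:
    """Unit baseline: NREM spike rate excluding +-1 s around events."""
    spikes = unit.spike_times_s
    if states is None:
        dur = duration_s if duration_s else (spikes[-1] if spikes.size else 0.0)
        return spikes.size / dur if dur > 0 else 0.0
    excl = 1.0
    keep = np.ones(spikes.size, dtype=bool)
    total = 0.0
    in_nrem = np.zeros(spikes.size, dtype=bool)
    for s, e in states.for_state("NREM"):
        total += e - s
        in_nrem |= (spikes >= s) & (spikes < e)
    for t in events:
        keep &= ~((spikes >= t - excl) & (spikes <= t + excl))
    lost = min(events.size * 2 * excl, total)
    eff = total - lost
    if eff <= 0:
        return spikes.size / duration_s if duration_s else 0.0
    return float((keep & in_nrem).sum() / eff)


CATEGORIES = ("IED_ONLY", "IED_DOWN", "IED_DOWN_UP", "DOWN_UP_ONLY", "UNMODULATED")


def categorize_modulation(
    ied: dict[str, ModulationResult],
    down: dict[str, ModulationResult],
    up: dict[str, ModulationResult],
) -> tuple[dict[str, str], dict[str, float]]:
    """Assign each unit to exactly one pathological-event category.

    Returns (unit -> category, category -> proportion of modulated units).
    Units modulated by the cortical DOWN and/or UP state without any IED
    modulation fall in ``DOWN_UP_ONLY``.
    """
    if not (set(ied) == set(down) == set(up)):
        raise ValueError("the three result sets must cover the same units")
    cats: dict[str, str] = {}
    for uid in ied:
        si = bool(ied[uid].significant) and not ied[uid].excluded
        sd = bool(down[uid].significant) and not down[uid].excluded
        su = bool(up[uid].significant) and not up[uid].excluded
        if si and sd and su:
            cats[uid] = "IED_DOWN_UP"
        elif si and sd:
            cats[uid] = "IED_DOWN"
        elif si:
            cats[uid] = "IED_ONLY"
        elif sd or su:
            cats[uid] = "DOWN_UP_ONLY"
        else:
            cats[uid] = "UNMODULATED"
    n_mod = sum(1 for c in cats.values() if c != "UNMODULATED")
    props = {
        c: (sum(1 for v in cats.values() if v == c) / n_mod if n_mod else 0.0)
        for c in CATEGORIES
        if c != "UNMODULATED"
    }
    return cats, props


def transition_firing_windows(
    pop_rate: np.ndarray,
    downs: Sequence[DownState],
    dt: float = 1e-3,
) -> dict:
    """Per-transition normalized firing in the UP_pre / DOWN / UP_post
    windows, aggregated separately for pathological and physiological
    transitions.

    UP_pre = mean in [t_start - 0.1, t_start); DOWN = min in
    [t_start, t_start + 0.2); UP_post = mean in [t_peak, t_peak + 0.5).
    """
    n = pop_rate.size
    rows = []
    for d in downs:
        i_pre0 = int((d.t_start - 0.1) / dt)
        i_s = int(d.t_start / dt)
        i_p = int(d.t_peak / dt)
        if i_pre0 < 0 or i_p + int(0.5 / dt) >= n:
            continue  # transition too close to session edge
        up_pre = float(pop_rate[i_pre0:i_s].mean())
        down_min = float(pop_rate[i_s : i_s + int(0.2 / dt)].min())
        up_post = float(pop_rate[i_p : i_p + int(0.5 / dt)].mean())
        rows.append((up_pre, down_min, up_post, d.pathological))
    out = {"per_transition": rows}
    for name, flag in (("pathological", True), ("physiological", False)):
        sub = [(a, b, c) for a, b, c, f in rows if f == flag]
        arr = np.asarray(sub) if sub else np.empty((0, 3))
        out[name] = {
            "n": arr.shape[0],
            "up_pre": arr[:, 0] if arr.size else np.empty(0),
            "down_min": arr[:, 1] if arr.size else np.empty(0),
            "up_post": arr[:, 2] if arr.size else np.empty(0),
        }
    return out


def modulation_correlation(
    results_a: dict[str, ModulationResult], results_b: dict[str, ModulationResult]
) -> tuple[float, float]:
    """Spearman rank correlation of IFR modulation across shared units."""
    shared = [
        u
        for u in results_a
        if u in results_b and not results_a[u].excluded and not results_b[u].excluded
    ]
    if len(shared) < 5:
        raise ValueError("fewer than 5 shared non-excluded units")
    a = [results_a[u].ifr_peak_norm for u in shared]
    b = [results_b[u].ifr_peak_norm for u in shared]
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


__all__ = [
    "CATEGORIES",
    "MIN_EVENTS",
    "ModulationResult",
    "categorize_modulation",
    "modulation_correlation",
    "peri_event_modulation",
    "population_rate",
    "transition_firing_windows",
]
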