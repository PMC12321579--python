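"""Detection-free LFP gradient-sharpness ("epileptogenicity") index.

Per session, random 5 s NREM segments are Savitzky-Golay filtered, the
absolute discrete gradient is taken, artifact samples above 20x the
median gradient are removed and the segment statistic is the
median-based threshold ``median(|g|) + k * 1.4826 * MAD(|g|)`` of the
surviving samples.  Session values are z-scored against pooled baseline
segments and trended over days (OLS slope + Mann-Kendall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .coupling import mann_kendall
from .types import SessionBundle

MAD_SCALE = 1.4826


@dataclass
class EpiIndexResult:
    session_id: str
    day_index: int
    segment_values: np.ndarray
    session_mean: float
    session_z: float = float("nan")
    params: dict = field(default_factory=dict)


@dataclass
class EpiTrendResult:
    sessions: list[EpiIndexResult]
    slope: float
    slope_p: float
    mk_tau: float
    mk_p: float


def sample_nrem_segments(
    bundle: SessionBundle, n: int = 10, seg_s: float = 5.0, seed: int = 0
) -> list[tuple[float, float]]:
    """Seeded non-overlapping segment draws from NREM intervals."""
    slots: list[tuple[float, float]] = []
    for s, e in bundle.states.for_state("NREM"):
        t = s
        while t + seg_s <= e:
            slots.append((t, t + seg_s))
            t += seg_s
    if len(slots) < n:
        raise ValueError(
            f"insufficient NREM: {len(slots)} candidate segments, need {n}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(slots), n, replace=False)
    return [slots[i] for i in sorted(picked)]


def segment_sharpness(
    segment: np.ndarray,
    savgol_window: int = 11,
    savgol_order: int = 3,
    k_mad: float = 5.0,
    artifact_mult: float = 20.0,
) -> float:
    """Gradient-sharpness statistic of one LFP segment (uV/sample).

    Translation-invariant and 1-homogeneous in amplitude by construction.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < savgol_window:
        raise ValueError("segment shorter than the Savitzky-Golay window")
    g = np.abs(np.gradient(savgol_filter(x, savgol_window, savgol_order)))
    med = np.median(g)
    keep = g <= artifact_mult * med if med > 0 else np.ones_like(g, dtype=bool)
    g = g[keep]
    if g.size == 0:
        raise ValueError("all samples removed by artifact bound")
    med = float(np.median(g))
    mad = float(np.median(np.abs(g - med)))
    return med + k_mad * MAD_SCALE * mad


def session_sharpness(
    bundle: SessionBundle,
    channel: Optional[str] = None,
    n_segments: int = 10,
    seg_s: float = 5.0,
    seed: int = 0,
    savgol_window: int = 11,
    savgol_order: int = 3,
    k_mad: float = 5.0,
) -> EpiIndexResult:
    if channel is None:
        mpfc = bundle.channels_of("MPFC")
        if not mpfc:
            raise ValueError("no mPFC channel")
        channel = mpfc[0]
    fs = bundle.meta.fs_hz
    x = bundle.channel(channel)
    segments = sample_nrem_segments(bundle, n_segments, seg_s, seed)
    vals = np.array(
        [
            segment_sharpness(
                x[int(s * fs) : int(e * fs)], savgol_window, savgol_order, k_mad
            )
            for s, e in segments
        ]
    )
    return EpiIndexResult(
        session_id=bundle.meta.session_id,
        day_index=bundle.meta.day_index,
        segment_values=vals,
        session_mean=float(vals.mean()),
        params={
            "n_segments": n_segments,
            "segment_s": seg_s,
            "seed": seed,
            "savgol_window": savgol_window,
            "savgol_order": savgol_order,
            "k_mad": k_mad,
            "channel": channel,
        },
    )


def epi_trend(
    cohort: Sequence[SessionBundle],
    baseline_days: Sequence[int],
    seed: int = 0,
    **kwargs,
) -> EpiTrendResult:
    """Per-session sharpness z-scored against pooled baseline segments,
    with OLS slope over day index and a Mann-Kendall trend test."""
    baseline_days = set(baseline_days)
    results = [
        session_sharpness(b, seed=seed + i, **kwargs) for i, b in enumerate(cohort)
    ]
    base_vals = np.concatenate(
        [r.segment_values for r in results if r.day_index in baseline_days]
    ) if any(r.day_index in baseline_days for r in results) else np.empty(0)
    if base_vals.size < 4:
        raise ValueError("need pooled segments from >= 2 baseline sessions")
    mu, sd = base_vals.mean(), base_vals.std()
    if sd == 0:
        raise ValueError("zero variance in baseline segments")
    for r in results:
        r.session_z = float((r.session_mean - mu) / sd)

    days = np.array([r.day_index for r in results], dtype=float)
    zs = np.array([r.session_z for r in results])
    lr = stats.linregress(days, zs)
    tau, mk_p = mann_kendall(zs[np.argsort(days)])
    return EpiTrendResult(
        sessions=results,
        slope=float(lr.slope),
        slope_p=float(lr.pvalue),
        mk_tau=tau,
        mk_p=mk_p,
    )


__all__ = [
    "EpiIndexResult",
    "EpiTrendResult",
    "epi_trend",
    "sample_nrem_segments",
    "segment_sharpness",
    "session_sharpness",
]
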