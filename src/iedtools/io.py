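"""Session directory reader/writer.

Layout (all plain text except the int16 payload):

    <session>/
      session.dat     interleaved little-endian int16, channel-major per frame
      session.yaml    fs_hz, day_index, condition, seed, channels[]
      states.tsv      start_s  end_s  state
      events.tsv      kind  channel  start_s  peak_s  end_s  amplitude_uv
      units.tsv       unit_id  region  cell_class
      spikes/<unit_id>.tsv   spike_time_s
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import resample_poly

from .types import (
    ANALYSIS_FS_HZ,
    STATES,
    ChannelInfo,
    Event,
    EventSeries,
    SessionBundle,
    SessionMeta,
    SpikeUnit,
    StateIntervals,
)

DAT_NAME = "session.dat"
YAML_NAME = "session.yaml"

INT16_MAX = 32767


def write_session(bundle: SessionBundle, path: str | os.PathLike) -> None:
    """Write a bundle to a session directory (deterministic byte output)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = bundle.meta

    scales = np.array([ch.uv_per_bit for ch in meta.channels])
    raw = bundle.lfp / scales  # broadcast over channels
    peak = np.abs(raw).max(initial=0.0)
    if peak > INT16_MAX:
        raise ValueError(
            f"scaled amplitude {peak:.0f} exceeds int16 range; "
            "increase uv_per_bit on the offending channel"
        )
    raw16 = np.round(raw).astype("<i2")
    raw16.tofile(path / DAT_NAME)

    sidecar = {
        "session_id": meta.session_id,
        "fs_hz": float(meta.fs_hz),
        "n_samples": int(meta.n_samples),
        "day_index": int(meta.day_index),
        "condition": meta.condition,
        "seed": meta.seed,
        "channels": [
            {
                "label": ch.label,
                "region": ch.region,
                "kind": ch.kind,
                "uv_per_bit": float(ch.uv_per_bit),
            }
            for ch in meta.channels
        ],
    }
    (path / YAML_NAME).write_text(yaml.safe_dump(sidecar, sort_keys=True))

    if bundle.states.intervals:
        pd.DataFrame(
            bundle.states.intervals, columns=["start_s", "end_s", "state"]
        ).to_csv(path / "states.tsv", sep="\t", index=False)

    rows = []
    for key, series in sorted(bundle.event_series.items()):
        for ev in series:
            rows.append(
                (key, ev.kind, ev.channel, ev.start_s, ev.peak_s, ev.end_s, ev.amplitude_uv)
            )
    if rows:
        pd.DataFrame(
            rows,
            columns=["series", "kind", "channel", "start_s", "peak_s", "end_s", "amplitude_uv"],
        ).to_csv(path / "events.tsv", sep="\t", index=False)

    if bundle.units:
        pd.DataFrame(
            [(u.unit_id, u.region, u.cell_class) for u in bundle.units],
            columns=["unit_id", "region", "cell_class"],
        ).to_csv(path / "units.tsv", sep="\t", index=False)
        spikes_dir = path / "spikes"
        spikes_dir.mkdir(exist_ok=True)
        for u in bundle.units:
            pd.DataFrame({"spike_time_s": u.spike_times_s}).to_csv(
                spikes_dir / f"{u.unit_id}.tsv", sep="\t", index=False
            )


def read_session(path: str | os.PathLike) -> SessionBundle:
    """Read a session directory; LFP is scaled to microvolts.

    If the sidecar declares a sampling rate other than the canonical
    1250 Hz, the signal is polyphase-resampled on read and all metadata
    adjusted accordingly.
    """
    path = Path(path)
    sidecar = yaml.safe_load((path / YAML_NAME).read_text())
    channels = [
        ChannelInfo(
            label=c["label"],
            region=c["region"],
            kind=c["kind"],
            uv_per_bit=float(c["uv_per_bit"]),
        )
        for c in sidecar["channels"]
    ]
    meta = SessionMeta(
        session_id=sidecar["session_id"],
        fs_hz=float(sidecar["fs_hz"]),
        n_samples=int(sidecar["n_samples"]),
        channels=channels,
        day_index=int(sidecar.get("day_index", 0)),
        condition=sidecar.get("condition", "BASELINE"),
        seed=sidecar.get("seed"),
    )

    n_ch = meta.n_channels
    payload = (path / DAT_NAME).stat().st_size
    expected = meta.n_samples * n_ch * 2
    if payload != expected:
        raise ValueError(
            f"payload size mismatch: expected {expected} bytes "
            f"({meta.n_samples} samples x {n_ch} channels x 2), got {payload}"
        )
    raw = np.fromfile(path / DAT_NAME, dtype="<i2").reshape(meta.n_samples, n_ch)
    scales = np.array([ch.uv_per_bit for ch in channels])
    lfp = raw.astype(float) * scales

    if abs(meta.fs_hz - ANALYSIS_FS_HZ) > 1e-9:
        up = int(round(ANALYSIS_FS_HZ))
        down = int(round(meta.fs_hz))
        g = np.gcd(up, down)
        lfp = resample_poly(lfp, up // g, down // g, axis=0)
        meta.fs_hz = ANALYSIS_FS_HZ
        meta.n_samples = lfp.shape[0]

    states = StateIntervals()
    if (path / "states.tsv").exists():
        df = pd.read_csv(path / "states.tsv", sep="\t")
        for _, r in df.iterrows():
            if r["state"] not in STATES:
                raise ValueError(f"unknown state label {r['state']!r} in states.tsv")
            states.intervals.append((float(r["start_s"]), float(r["end_s"]), r["state"]))

    event_series: dict[str, EventSeries] = {}
    if (path / "events.tsv").exists():
        df = pd.read_csv(path / "events.tsv", sep="\t")
        df["channel"] = df["channel"].fillna("")
        for key, grp in df.groupby("series", sort=True):
            kind = grp["kind"].iloc[0]
            evs = [
                Event(
                    peak_s=float(r.peak_s),
                    start_s=float(r.start_s),
                    end_s=float(r.end_s),
                    channel=str(r.channel),
                    amplitude_uv=float(r.amplitude_uv),
                    kind=str(r.kind),
                )
                for r in grp.itertuples()
            ]
            series = EventSeries(events=evs, kind=kind).sort()
            event_series[str(key)] = series

    units: list[SpikeUnit] = []
    if (path / "units.tsv").exists():
        udf = pd.read_csv(path / "units.tsv", sep="\t")
        for _, r in udf.iterrows():
            spikes_path = path / "spikes" / f"{r['unit_id']}.tsv"
            times = (
                pd.read_csv(spikes_path, sep="\t")["spike_time_s"].to_numpy()
                if spikes_path.exists()
                else np.empty(0)
            )
            units.append(
                SpikeUnit(
                    unit_id=str(r["unit_id"]),
                    spike_times_s=times,
                    region=str(r["region"]),
                    cell_class=str(r["cell_class"]),
                )
            )

    return SessionBundle(
        meta=meta, lfp=lfp, states=states, units=units, event_series=event_series
    )


__all__ = ["read_session", "write_session", "DAT_NAME", "YAML_NAME"]
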