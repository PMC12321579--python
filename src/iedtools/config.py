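"""Serializable pipeline configuration.

Flat dataclass of every detector/statistic parameter with its default;
round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0

    # sleep scoring
    sleep_window_s: float = 1.0
    sleep_r_rem: float = 2.0
    sleep_d_nrem: float = -0.5
    sleep_motion_z: float = 3.0

    # IED detection
    ied_k_detect: float = 5.0
    ied_k_reject_low: float = 10.0
    ied_k_reject_high: float = 100.0
    ied_merge_s: float = 0.1
    ied_robust: bool = False

    # spindle detection
    spindle_k_floor: float = 2.0
    spindle_k_peak_lo: float = 4.0
    spindle_k_peak_hi: float = 14.0
    spindle_merge_gap_s: float = 0.25
    spindle_dur_min_s: float = 0.35
    spindle_dur_max_s: float = 3.0
    spindle_ied_excl_s: float = 0.2

    # DOWN states
    down_dur_min_s: float = 0.15
    down_dur_max_s: float = 0.5
    down_path_window_s: float = 0.2
    down_mua_frac: float = 0.5

    # MUA
    mua_band_lo_hz: float = 80.0
    mua_band_hi_hz: float = 300.0
    mua_thr_mult: float = 5.0

    # CCG / coupling
    ccg_bin_s: float = 0.01
    ccg_window_s: float = 1.0
    ccg_kernel_sd_s: float = 0.1
    m_test_window_s: float = 0.05
    independence_radius_s: float = 0.1

    # coherence
    coh_seg_s: float = 10.0
    coh_n_segments: int = 100
    coh_nw: float = 3.0
    coh_n_tapers: int = 5

    # spiking modulation
    mod_window_s: float = 1.0
    mod_n_perm: int = 500
    mod_jitter_s: float = 2.0
    mod_min_events: int = 20
    mod_ifr_sd_s: float = 0.01

    # epileptogenicity
    epi_n_segments: int = 10
    epi_segment_s: float = 5.0
    epi_savgol_window: int = 11
    epi_savgol_order: int = 3
    epi_k_mad: float = 5.0

    # closed loop
    cl_k_sd: float = 7.0
    cl_baseline_s: float = 10.0
    cl_refractory_s: float = 3.0
    cl_ma_window_s: float = 0.02
    cl_p_eff: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


__all__ = ["PipelineConfig"]
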