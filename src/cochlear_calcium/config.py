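"""Analysis configuration.

Every tunable of the pipeline lives here with an explicit default, so that a
run is fully described by one :class:`AnalysisConfig` plus a seed.  The config
serializes losslessly to/from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class QCConfig:
    """Frame quality control (breathing / defocus artifacts)."""

    smooth_sigma: float = 1.0          # px; spatial Gaussian, FWHM ≈ 2 px
    smooth_sigma_t: float = 0.0        # frames; temporal smoothing corrupts the
                                       # 200 ms duration criterion, so off by default
    qc_roi_fraction: float = 0.8       # central fraction of the field used for the qc trace
    prominence_k: float = 4.0          # multiples of robust SD
    detect_positive: bool = False      # positive qc excursions are rare and usually biology
    template_threshold: float = 0.8    # normalized cross-correlation
    max_shift: float = 10.0            # px, drift-correction clamp
    drift_upsample: int = 20           # subpixel refinement factor for phase correlation


@dataclass
class TraceConfig:
    erosion_radius: int = 2            # px in [1, 3]
    f0_rule: str = "percentile"        # or "median"
    f0_percentile: float = 10.0
    detrend_window_s: float = 30.0     # rolling-median window


@dataclass
class EventConfig:
    min_fdhm_s: float = 0.2
    amp_k: float = 2.0                 # amplitude > amp_k * SD(detrended trace)
    prominence_k: float = 2.0          # prominence > prominence_k * robust SD
    window_s: float = 2.0              # same-event linkage window
    gap_limit: int = 4                 # max run of non-participating cells inside an event
    linkage: str = "single"            # or "complete"
    skipped_amplitude_fraction: float = 0.25
    min_duration_s: float = 300.0      # 5 min eligibility for frequencies / correlations
    min_overlap_s: float = 300.0       # pairwise-correlation overlap requirement
    distance_bin_um: float = 10.0      # r-vs-distance binning


@dataclass
class WaveConfig:
    bin_factor: int = 2
    threshold: float | None = None     # manual scalar override of Otsu, in dF units
    spot_sigma: float = 3.0            # binned px, seed detection smoothing
    outline_sigma: float = 1.0         # binned px, outline smoothing
    min_volume: int = 10               # binned voxels
    min_footprint_area_um2: float = 100.0  # single-cell confinement cutoff (> one SC body)
    speed_estimator: str = "equivalent_radius"  # or "boundary"
    kymo_half_width_px: int = 3
    kymo_step_um: float = 1.0
    origin_window_um: float = 35.0     # wave-to-IHC matching window
    match_lag_s: float = 2.0


@dataclass
class TerminalConfig:
    tophat_radius: int = 15            # px in [10, 20]
    spot_sigma: float = 1.5
    outline_sigma: float = 1.0
    min_area_px: int = 4
    ambiguity_margin_um: float = 3.0
    middle_half_width_um: float = 2.0
    merge_window_s: float = 1.0


@dataclass
class SyntheticConfig:
    """Defaults emulate the in vivo study conditions of the immature apical coil."""

    n_ihc: int = 20
    ihc_spacing_um: float = 9.0
    arc_curvature: float = 0.002       # 1/µm, gentle apical-coil bend
    ihc_radius_um: float = 4.0
    sc_radius_um: float = 5.0
    ger_offset_um: float = 8.0         # gap between IHC row and GER field
    ger_depth_um: float = 36.0         # radial depth of the GER field
    terminal_mean: float = 4.0         # terminals per IHC, clipped normal
    terminal_sd: float = 2.0
    terminal_min: int = 1
    terminal_max: int = 10
    terminal_radius_um: float = 6.0    # puncta placed within this radius of the IHC
    # activity schedule
    lambda_ind_per_min: float = 0.35   # independent IHC transient rate
    wave_rate_per_min: float = 0.8
    v_exp_um_s: float = 22.0
    v_con_um_s: float = 15.0
    v_ihc_um_s: float = 61.0           # lateral spread of coordinated IHC activity
    wave_a_long_um: float = 17.0       # semi-extent at maximal expansion (mean)
    wave_a_long_sd_um: float = 6.5
    wave_aspect: float = 2.4           # longitudinal/radial extent ratio
    p_reach: float = 0.31              # fraction of waves eliciting a coordinated event
    p_skip: float = 0.15               # per-cell skip probability inside a cohort
    cohort_mean: float = 7.0
    cohort_sd: float = 4.0
    cohort_min: int = 3
    cohort_max: int = 20
    amp_single: float = 0.25           # dF/F0, independent transient
    amp_coordinated_scale: float = 1.9
    # terminal activity
    p_terminal_single: float = 0.3     # terminal recruitment during single-IHC events
    p_terminal_multiple: float = 0.8   # ... during multiple-IHC events
    lambda_term_pillar_per_min: float = 0.6
    lambda_term_modiolar_per_min: float = 0.3
    terminal_amp: float = 0.4
    # rendering
    frame_rate: float = 30.0
    pixel_size_um: float = 1.0
    tau_rise_s: float = 0.05
    fdhm_s: float = 1.5                # target single-transient FDHM; sets tau_decay
    wave_tau_decay_s: float = 0.4      # supporting-cell indicator decay
    wave_amp: float = 1.0
    wave_edge_um: float = 1.5          # Gaussian softness of the wave rim
    baseline_bg: float = 15.0
    baseline_ihc: float = 100.0
    baseline_sc: float = 60.0
    baseline_terminal: float = 80.0
    photon_gain: float = 1.0           # counts/photon; 0 disables shot noise
    artifact_rate_per_min: float = 2.0
    artifact_depth_range: tuple = (0.3, 0.6)
    artifact_len_frames: tuple = (2, 8)
    drift_amplitude_px: float = 0.0
    drift_period_s: float = 60.0


@dataclass
class AnalysisConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    traces: TraceConfig = field(default_factory=TraceConfig)
    events: EventConfig = field(default_factory=EventConfig)
    waves: WaveConfig = field(default_factory=WaveConfig)
    terminals: TerminalConfig = field(default_factory=TerminalConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    def validate(self) -> None:
        for name, val in (
            ("qc.smooth_sigma", self.qc.smooth_sigma),
            ("qc.prominence_k", self.qc.prominence_k),
            ("traces.erosion_radius", self.traces.erosion_radius),
            ("traces.detrend_window_s", self.traces.detrend_window_s),
            ("events.min_fdhm_s", self.events.min_fdhm_s),
            ("events.window_s", self.events.window_s),
            ("waves.bin_factor", self.waves.bin_factor),
            ("terminals.tophat_radius", self.terminals.tophat_radius),
            ("synthetic.frame_rate", self.synthetic.frame_rate),
            ("synthetic.pixel_size_um", self.synthetic.pixel_size_um),
        ):
            if not val > 0:
                raise ValueError(f"config field {name} must be strictly positive, got {val}")
        for name, p in (
            ("synthetic.p_reach", self.synthetic.p_reach),
            ("synthetic.p_skip", self.synthetic.p_skip),
            ("synthetic.p_terminal_single", self.synthetic.p_terminal_single),
            ("synthetic.p_terminal_multiple", self.synthetic.p_terminal_multiple),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"config field {name} must lie in [0, 1], got {p}")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # YAML has no tuple type; store as lists and restore on load
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "qc", "traces", "events", "waves", "terminals", "synthetic",
            ):
                sub_cls = {
                    "qc": QCConfig, "traces": TraceConfig, "events": EventConfig,
                    "waves": WaveConfig, "terminals": TerminalConfig,
                    "synthetic": SyntheticConfig,
                }[f.name]
                sub_kwargs = {}
                for sf in dataclasses.fields(sub_cls):
                    if sf.name in v:
                        sv = v[sf.name]
                        if isinstance(sv, list):
                            sv = tuple(sv)
                        sub_kwargs[sf.name] = sv
                kwargs[f.name] = sub_cls(**sub_kwargs)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls.from_dict(d or {})
        cfg.validate()
        return cfg
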