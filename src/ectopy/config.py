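"""Tunable parameters for every pipeline stage.

The device architecture is public but its constants are not, so every
threshold lives here with a documented default and can be overridden from a
YAML mapping (section -> field -> value).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = [
    "PreprocessConfig", "QcConfig", "DetectorConfig", "NoiseConfig",
    "TemplateConfig", "TriggerConfig", "BurdenConfig", "EvalConfig",
    "PipelineConfig",
]


@dataclass
class PreprocessConfig:
    band_lo: float = 0.5        # Hz; high-pass corner, removes baseline drift
    band_hi: float = 40.0       # Hz; matches the 40 Hz band-limit of stored episodes
    target_fs: float = 256.0    # Hz; working rate of all downstream stages


@dataclass
class QcConfig:
    min_mean_r_uv: float = 100.0  # records below this mean R amplitude are rejected


@dataclass
class DetectorConfig:
    refractory_s: float = 0.20
    integration_s: float = 0.150   # moving-window integrator length
    searchback_factor: float = 1.66  # missed-beat search-back at this multiple of mean RR
    threshold_frac: float = 0.35     # detection threshold as fraction of running peak level
    refine_s: float = 0.060          # fiducial refinement half-window


@dataclass
class NoiseConfig:
    window_s: float = 1.0
    step_s: float = 0.25
    hf_lo: float = 45.0           # Hz; lower edge of the myopotential band
    power_frac: float = 0.5       # window is noise if HF power fraction exceeds this
    min_hf_rms_uv: float = 50.0   # HF floor so quiescent sensor noise is not flagged
    rail_uv: float = 8000.0       # amplitude-saturation rail
    rail_dur_s: float = 0.050
    merge_gap_s: float = 0.5


@dataclass
class TemplateConfig:
    window_s: float = 0.200       # fiducial-centered window; covers a wide QRS
    k_beats: int = 16             # beats averaged per template
    n_min: int = 8                # minimum qualifying beats for a valid template
    rr_tol: float = 0.125         # RR within +/-12.5% of local median qualifies
    min_corr: float = 0.95        # beat-to-running-mean correlation gate
    period_s: float = 7200.0      # re-formation attempted every 2 h
    retry_s: float = 120.0        # retry interval after a failed attempt
    max_shift: int = 10           # DCWA shift range in samples (~39 ms at 256 Hz)


@dataclass
class TriggerConfig:
    premature_factor: float = 0.88   # candidate if rr_prev/rr_local_mean <= this
    amp_lo: float = 0.4              # amplitude-ratio candidacy band
    amp_hi: float = 2.2
    rr_history: int = 8              # trailing non-candidate RRs for the local mean
    max_run: int = 3                 # runs longer than this leave PVC candidacy
    seq_rr_factor: float = 0.75      # mutual RR below this x local mean joins a sequence


@dataclass
class BurdenConfig:
    window_s: float = 86400.0
    threshold_pct: float = 5.0       # configurable alert threshold, minimum 5%


@dataclass
class EvalConfig:
    tolerance_s: float = 0.150
    excluded_symbols: tuple[str, ...] = ("F",)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    template: TemplateConfig = field(default_factory=TemplateConfig)
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    burden: BurdenConfig = field(default_factory=BurdenConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section, values in d.items():
            if not hasattr(cfg, section):
                raise ConfigurationError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            names = {f.name for f in dataclasses.fields(sub)}
            for key, val in values.items():
                if key not in names:
                    raise ConfigurationError(
                        f"unknown option {key!r} in section {section!r}")
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
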