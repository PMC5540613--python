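"""Pipeline configuration: defaults reproduce the published constants.

6 Hz / order-86 low-pass, 2.1 mV/s and 0.8 knee thresholds, 0.2 mV/s
detrending slope limit, 0.02 end-flattening fraction, k = 10 neighbours,
20 x 10-fold cross-validation.  Unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class FilterConfig:
    order: int = 86
    passband_hz: float = 6.0
    stopband_hz: float = 50.0


@dataclass
class SegmentConfig:
    pre_s: float = 5.0
    post_s: float = 15.0


@dataclass
class DecimationConfig:
    factor: int = 16


@dataclass
class KneeConfig:
    abs_threshold_mv_s: float = 2.1
    rel_fraction: float = 0.8
    search_window_s: float = 6.0
    kernel: str = "central5"  # central5 | printed


@dataclass
class TrendConfig:
    post_window_frac: float = 0.2
    slope_limit_mv_s: float = 0.2


@dataclass
class FitConfig:
    multistarts: int = 8
    seed: int = 0


@dataclass
class EndConfig:
    theta: float = 0.02
    variant: str = "flattening"  # flattening | printed


@dataclass
class ClassificationConfig:
    k_folds: int = 10
    repeats: int = 20
    knn_k: int = 10
    svm_c: float = 1.0
    svm_gamma: float = 1.0
    svm_variant: str = "c"  # c | nu
    svm_nu: float = 0.5
    standardize: bool = True


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    decimation: DecimationConfig = field(default_factory=DecimationConfig)
    knee: KneeConfig = field(default_factory=KneeConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    end: EndConfig = field(default_factory=EndConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    seed: int = 0
    log_level: str = "INFO"


def _update_section(obj, data: dict, path: str) -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigurationError(f"unknown config key {path}{key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config section {path}{key!r} must be a mapping")
            _update_section(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, type(current)(value) if current is not None else value)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config file on top of the defaults (None -> defaults)."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    _update_section(cfg, data, "")
    return cfg
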