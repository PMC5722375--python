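"""Pipeline configuration: a single YAML/JSON file validated eagerly.

The default configuration embodies the study settings: 0.2-45 Hz ECG band,
0.5-7.5 Hz ACC band, order-4 zero-phase Butterworth filters, 3-s segments,
10 m/s² pause threshold and a CCp decision threshold of 0.22.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .synthetic import GeneratorParams


@dataclass
class PipelineConfig:
    """All tunable settings of the processing pipeline."""

    # filtering
    ecg_band: tuple[float, float] = (0.2, 45.0)
    acc_band: tuple[float, float] = (0.5, 7.5)
    filter_order: int = 4
    zero_phase: bool = True
    # segmentation
    envelope_window_s: float = 0.5
    pause_threshold_ms2: float = 10.0
    min_pause_s: float = 3.0
    segment_duration_s: float = 3.0
    guard_offset_s: float = 0.0
    # detection
    ccp_threshold: float = 0.22
    normalization: str = "energy_sqrt"
    use_abs: bool = False
    # evaluation
    welch: bool = False
    chi_square_correction: bool = False
    auc_comparison: str = "delong"
    # generator + reproducibility
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    seed: int = 0

    def validate(self, sample_rate_hz: float | None = None) -> None:
        """Raise one consolidated ConfigurationError listing all violations."""
        problems: list[str] = []
        fs = sample_rate_hz or self.generator.sample_rate_hz
        nyq = fs / 2.0
        for name, band in (("ecg_band", self.ecg_band), ("acc_band", self.acc_band)):
            lo, hi = band
            if not 0 < lo < hi:
                problems.append(f"{name}: require 0 < low < high, got {band}")
            elif hi >= nyq:
                problems.append(
                    f"{name}: high cutoff {hi} Hz is at or above the Nyquist "
                    f"frequency {nyq} Hz"
                )
        if self.filter_order < 1:
            problems.append(f"filter_order must be >= 1, got {self.filter_order}")
        for name in ("envelope_window_s", "pause_threshold_ms2", "min_pause_s",
                     "segment_duration_s"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.guard_offset_s < 0:
            problems.append("guard_offset_s must be >= 0")
        if self.normalization not in ("energy_sqrt", "energy_product"):
            problems.append(f"unknown normalization {self.normalization!r}")
        if self.auc_comparison not in ("delong", "hanley"):
            problems.append(f"unknown auc_comparison {self.auc_comparison!r}")
        if problems:
            raise ConfigurationError(
                "invalid configuration:\n  - " + "\n  - ".join(problems)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a config from YAML/JSON, apply overrides, validate eagerly."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    gen = data.pop("generator", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("ecg_band", "acc_band"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = PipelineConfig(**data)
    if gen:
        gen_known = {f.name for f in dataclasses.fields(GeneratorParams)}
        bad = set(gen) - gen_known
        if bad:
            raise ConfigurationError(f"unknown generator keys: {sorted(bad)}")
        for k, v in gen.items():
            if isinstance(v, list):
                gen[k] = tuple(v)
        cfg = dataclasses.replace(cfg, generator=GeneratorParams(**gen))
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path
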