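"""Structured configuration for the extraction pipeline.

All tunables of delineation, HRV estimation and amplitude features live in
one dataclass that can be loaded from YAML, so a pipeline run is fully
described by (input files, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .delineation import DelineationConfig
from .exceptions import ConfigurationError
from .morphology_features import PLACEHOLDER_EK_WEIGHTS


@dataclass(frozen=True)
class ExtractionConfig:
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    hr_mean_mode: str = "instantaneous"      # or "overall"
    triangular_bin_width: float | None = None  # None -> 1/fs (study convention)
    spectral_min_span_s: float = 60.0
    bazett_literal: bool = False
    relative_amplitude_mode: str = "r_relative"
    ek_weights: dict[str, float] | None = field(
        default_factory=lambda: dict(PLACEHOLDER_EK_WEIGHTS))


def load_config(path: str | Path) -> ExtractionConfig:
    """Build an ExtractionConfig from a YAML file of overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    delin_over = raw.pop("delineation", {})
    known = {f.name for f in fields(ExtractionConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    delin_known = {f.name for f in fields(DelineationConfig)}
    bad = set(delin_over) - delin_known
    if bad:
        raise ConfigurationError(f"{path}: unknown delineation keys {sorted(bad)}")
    for key in ("bandpass_hz", "qrs_band_hz", "p_window_ms", "q_window_ms",
                "s_window_ms", "t_window_ms"):
        if key in delin_over:
            delin_over[key] = tuple(delin_over[key])
    return ExtractionConfig(delineation=DelineationConfig(**delin_over), **raw)
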