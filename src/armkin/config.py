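"""Run configuration: fail-closed loading and validation.

A run config is a flat JSON or YAML mapping.  Unknown keys are rejected
rather than ignored, so a typo in a tolerance name cannot silently fall
back to a default.  Every unset field takes the documented default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

from .arm_model import ArmGeometry
from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]

_MOTION_ALIASES = {
    "abd": "abduction_adduction",
    "abduction_adduction": "abduction_adduction",
    "rot": "external_internal",
    "external_internal": "external_internal",
}


@dataclass
class RunConfig:
    """Validated run parameters with their defaults.

    Lengths in mm, times in seconds.  ``strict`` selects the violation
    policy: ``True`` aborts on the first anatomically invalid frame,
    ``False`` (streaming, the default) flags it and emits NaN for that
    sample.
    """

    l2_mm: float = 180.0
    d5_mm: float = 300.0
    l6_mm: float = 260.0
    motion: str = "abduction_adduction"
    rom_mode: str = "per_cycle"
    seed: int = 0
    strict: bool = False
    residual_tol: float = 1e-6
    calibration_seconds: float = 1.0
    #: zero-phase Butterworth cutoff for marker pre-filtering (Hz); ~six
    #: harmonics of a 0.5 Hz exercise repetition.  None disables filtering.
    lowpass_cutoff_hz: float | None = 3.0
    max_flagged_fraction: float = 0.5
    derive_geometry_from_markers: bool = False

    def __post_init__(self):
        for key in ("l2_mm", "d5_mm", "l6_mm"):
            v = getattr(self, key)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"{key} must be a positive length, got {v!r}")
        if self.motion not in _MOTION_ALIASES:
            raise ConfigError(
                f"motion must be one of {sorted(set(_MOTION_ALIASES))}, got {self.motion!r}"
            )
        self.motion = _MOTION_ALIASES[self.motion]
        if self.rom_mode not in ("per_cycle", "global"):
            raise ConfigError(f"rom_mode must be 'per_cycle' or 'global', got {self.rom_mode!r}")
        for key in ("residual_tol", "calibration_seconds"):
            v = getattr(self, key)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"{key} must be > 0, got {v!r}")
        if self.lowpass_cutoff_hz is not None and not (
            isinstance(self.lowpass_cutoff_hz, (int, float)) and self.lowpass_cutoff_hz > 0
        ):
            raise ConfigError(
                f"lowpass_cutoff_hz must be > 0 or null, got {self.lowpass_cutoff_hz!r}"
            )
        if not 0 < self.max_flagged_fraction <= 1:
            raise ConfigError(
                f"max_flagged_fraction must be in (0, 1], got {self.max_flagged_fraction!r}"
            )
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    @property
    def geometry(self) -> ArmGeometry:
        return ArmGeometry(l2=float(self.l2_mm), d5=float(self.d5_mm), l6=float(self.l6_mm))


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a run config; ``None`` or an empty file -> defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if not text.strip():
        return RunConfig()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: cannot parse as JSON or YAML: {exc}") from None
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)
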