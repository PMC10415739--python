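"""JSON configuration for the simulation pipeline.

A single config document describes a full synthetic experiment::

    {
      "emulsion":   {"n_droplets": 2000, "radius_mean": 15.0, ...},
      "program":    {"period": 1.0, "amplitude": 1.0, ...},
      "acquisition":{"frame_interval": 2.0, "n_frames": 300, ...},
      "noise":      {"additive_sd": 1.0, "multiplicative_sd": 0.02},
      "artifacts":  {"frac_negative_slope": 0.0, ...},
      "rate":       {"k": 3.2e4, "label": "clean"},
      "calibration": null
    }

Every section is optional; omitted fields take the dataclass defaults,
unknown keys raise a ConfigError.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

from .compartments import EmulsionConfig, PressureProgram
from .errors import ConfigError
from .kinetics import K_CLEAN, RateParameters
from .synthetic_traces import AcquisitionConfig, ArtifactSpec, NoiseModel

__all__ = ["SimulationConfig", "load_simulation_config"]


@dataclass(frozen=True)
class SimulationConfig:
    emulsion: EmulsionConfig
    program: PressureProgram
    acquisition: AcquisitionConfig
    noise: NoiseModel
    artifacts: ArtifactSpec
    rate: RateParameters
    calibration: float | None = None


def _build(cls, section: dict[str, Any], name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name!r} section: {exc}") from exc


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a simulation config JSON file."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")
    known = {
        "emulsion", "program", "acquisition", "noise", "artifacts",
        "rate", "calibration",
    }
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{path}: unknown sections: {sorted(unknown)}")

    emulsion = _build(
        EmulsionConfig, doc.get("emulsion", {"n_droplets": 1000}), "emulsion"
    )
    return SimulationConfig(
        emulsion=emulsion,
        program=_build(PressureProgram, doc.get("program", {}), "program"),
        acquisition=_build(
            AcquisitionConfig, doc.get("acquisition", {}), "acquisition"
        ),
        noise=_build(NoiseModel, doc.get("noise", {}), "noise"),
        artifacts=_build(ArtifactSpec, doc.get("artifacts", {}), "artifacts"),
        rate=_build(RateParameters, doc.get("rate", {"k": K_CLEAN}), "rate"),
        calibration=doc.get("calibration"),
    )
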