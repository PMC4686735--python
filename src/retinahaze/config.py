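"""Pipeline configuration: defaults, YAML loading, flat-key overrides.

The configuration schema is a flat dotted-key namespace mirroring the stage
parameters::

    bipolar.sigma_cen   0.5     bipolar.sigma_sur  1.0     bipolar.k  0.3
    amacrine.epsilon    0.5
    ganglion.r_cen      1       ganglion.r_sur     3       ganglion.r_sub  1
    ganglion.A_cen      2.0     ganglion.A_s       2.0
    ganglion.A_u_on     0.7     ganglion.A_u_off   0.5
    output.mode         clip

YAML files may use either the flat keys or the equivalent nested mapping.
Unknown keys are rejected with the list of valid ones; constraint violations
raise the parameter errors of the owning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .amacrine import AmacrineParams
from .bipolar import BipolarParams
from .exceptions import ConfigError, ParameterError
from .ganglion import GanglionParams

__all__ = [
    "PipelineConfig",
    "config_from_dict",
    "config_to_dict",
    "default_config",
    "load_config",
    "parse_config",
]

OUTPUT_MODES = ("clip", "rescale")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the dehazing pipeline."""

    bipolar: BipolarParams
    amacrine: AmacrineParams
    ganglion_on: GanglionParams
    ganglion_off: GanglionParams
    output_mode: str = "clip"

    def __post_init__(self):
        if self.output_mode not in OUTPUT_MODES:
            raise ParameterError(
                f"output mode must be one of {OUTPUT_MODES}, got '{self.output_mode}'"
            )


def default_config() -> PipelineConfig:
    """The standard parameter set of the model."""
    return PipelineConfig(
        bipolar=BipolarParams(),
        amacrine=AmacrineParams(),
        ganglion_on=GanglionParams(A_u=0.7),
        ganglion_off=GanglionParams(A_u=0.5),
        output_mode="clip",
    )


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Serialize a configuration to the flat dotted-key mapping."""
    return {
        "bipolar.sigma_cen": cfg.bipolar.sigma_cen,
        "bipolar.sigma_sur": cfg.bipolar.sigma_sur,
        "bipolar.k": cfg.bipolar.k,
        "amacrine.epsilon": cfg.amacrine.epsilon,
        "ganglion.r_cen": cfg.ganglion_on.r_cen,
        "ganglion.r_sur": cfg.ganglion_on.r_sur,
        "ganglion.r_sub": cfg.ganglion_on.r_sub,
        "ganglion.A_cen": cfg.ganglion_on.A_cen,
        "ganglion.A_s": cfg.ganglion_on.A_s,
        "ganglion.A_u_on": cfg.ganglion_on.A_u,
        "ganglion.A_u_off": cfg.ganglion_off.A_u,
        "output.mode": cfg.output_mode,
    }


_VALID_KEYS = tuple(config_to_dict(default_config()))


def _flatten(mapping: dict, prefix: str = "") -> dict:
    flat = {}
    for key, value in mapping.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = value
    return flat


def config_from_dict(mapping: dict | None) -> PipelineConfig:
    """Build a configuration from a (possibly nested, possibly partial) mapping.

    Unspecified keys take the model defaults.
    """
    flat = _flatten(mapping or {})
    unknown = sorted(set(flat) - set(_VALID_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown configuration keys {unknown}; valid keys: {list(_VALID_KEYS)}"
        )
    values = dict(config_to_dict(default_config()))
    values.update(flat)
    ganglion_common = dict(
        r_cen=int(values["ganglion.r_cen"]),
        r_sur=int(values["ganglion.r_sur"]),
        r_sub=int(values["ganglion.r_sub"]),
        A_cen=float(values["ganglion.A_cen"]),
        A_s=float(values["ganglion.A_s"]),
    )
    return PipelineConfig(
        bipolar=BipolarParams(
            sigma_cen=float(values["bipolar.sigma_cen"]),
            sigma_sur=float(values["bipolar.sigma_sur"]),
            k=float(values["bipolar.k"]),
        ),
        amacrine=AmacrineParams(epsilon=float(values["amacrine.epsilon"])),
        ganglion_on=GanglionParams(A_u=float(values["ganglion.A_u_on"]), **ganglion_common),
        ganglion_off=GanglionParams(A_u=float(values["ganglion.A_u_off"]), **ganglion_common),
        output_mode=str(values["output.mode"]),
    )


def load_config(path) -> dict:
    """Read a YAML configuration file into a mapping (empty file -> {})."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file '{path}' must contain a mapping")
    return data


def parse_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Resolve a configuration from an optional file plus overriding flags.

    ``overrides`` uses the flat dotted keys and wins over file values, which
    in turn win over defaults.
    """
    values = load_config(path) if path is not None else {}
    flat = _flatten(values)
    flat.update(_flatten(overrides or {}))
    return config_from_dict(flat)


def with_output_mode(cfg: PipelineConfig, mode: str) -> PipelineConfig:
    return replace(cfg, output_mode=mode)
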