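"""Pipeline configuration: nested YAML blocks, strict validation.

Unknown keys are rejected on load so typos fail fast; the fully resolved
configuration (defaults included) is echoed into the run log and hashed
into the provenance record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import AcquisitionParams
from .simulate import PhantomSpec

__all__ = ["PipelineConfig", "PhasorConfig", "SegmentationConfig",
           "StatsConfig", "SimulateConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a configuration."""


@dataclass(frozen=True)
class PhasorConfig:
    reference: str = "analytic"        # "analytic" | path to a measured reference stack
    reference_tau_ns: float = 4.04     # fluorescein at pH 9
    tau_free_ns: float = 0.4           # free NAD(P)H in solution
    photon_threshold: float = 5.0      # strict ">" background exclusion


@dataclass(frozen=True)
class SegmentationConfig:
    channel: str = "auto"              # auto | marker | nadh
    blur_sigma: float = 2.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area: int = 50
    exclude_border: bool = False
    viability_cutoff: float | None = None


@dataclass(frozen=True)
class StatsConfig:
    bottom_z: int = 0
    top_z: int | None = None
    holm: bool = False


@dataclass(frozen=True)
class SimulateConfig:
    enabled: bool = True
    conditions: tuple[str, ...] = ("control", "activated")
    timepoints: tuple[float, ...] = (10.0,)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass(frozen=True)
class PipelineConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    phasor: PhasorConfig = field(default_factory=PhasorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    input_stacks: tuple[str, ...] = ()   # when given, simulation is skipped
    seed: int = 0
    write_plots: bool = False

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            return obj
        return convert(self)

    def digest(self) -> str:
        """Stable hash of the resolved configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{context}: {e}") from e


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top
    if unknown:
        raise ConfigError(f"top level: unknown keys {sorted(unknown)}")
    kwargs = {}
    if "acquisition" in data:
        acq = dict(data.pop("acquisition"))
        if "frame_shape" in acq:
            acq["frame_shape"] = tuple(acq["frame_shape"])
        kwargs["acquisition"] = _build(AcquisitionParams, acq, "acquisition")
    if "simulate" in data:
        sim = dict(data.pop("simulate"))
        if "phantom" in sim:
            ph = dict(sim["phantom"])
            for key in ("compartment_alphas", "photons_range", "mito_z_weights"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            sim["phantom"] = _build(PhantomSpec, ph, "simulate.phantom")
        kwargs["simulate"] = _build(SimulateConfig, sim, "simulate")
    for name, cls in (("phasor", PhasorConfig),
                      ("segmentation", SegmentationConfig),
                      ("stats", StatsConfig)):
        if name in data:
            kwargs[name] = _build(cls, dict(data.pop(name)), name)
    for name in ("input_stacks", "seed", "write_plots"):
        if name in data:
            v = data.pop(name)
            kwargs[name] = tuple(v) if isinstance(v, list) else v
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as f:
        try:
            data = yaml.safe_load(f)
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: invalid YAML ({e})") from e
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)
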