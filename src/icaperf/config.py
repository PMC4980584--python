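"""Run configuration: strict YAML round-trip of every stage's parameters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .concentration import ConversionParams
from .deconvolution import DeconvSpec
from .phantom import BolusParams, KiselevParams, PhantomSpec

__all__ = ["IcaSettings", "InputSettings", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class IcaSettings:
    n_components: Optional[int] = 10
    variance_fraction: Optional[float] = None
    k_voxels: int = 50
    artery_component: Optional[int] = None
    surround_component: Optional[int] = None
    aif_on: str = "signal"


@dataclass(frozen=True)
class InputSettings:
    path: Optional[str] = None
    te: Optional[float] = None
    dt: Optional[float] = None
    injection_tp: Optional[int] = None
    discard_first: int = 0
    manual_mask: Optional[str] = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    simulate: Optional[PhantomSpec] = None
    input: Optional[InputSettings] = None
    conversion: ConversionParams = field(default_factory=ConversionParams)
    ica: IcaSettings = field(default_factory=IcaSettings)
    deconv: DeconvSpec = field(default_factory=DeconvSpec)
    out_dir: str = "icaperf_out"

    def validate(self) -> "RunConfig":
        if self.simulate is None and (self.input is None or self.input.path is None):
            raise ValueError("config needs either a 'simulate' or an 'input' block")
        return self

    def hash(self) -> str:
        """Digest of the analysis parameters (output path and verbosity
        excluded, so reruns into different directories hash alike)."""
        plain = _to_plain(self)
        plain.pop("out_dir", None)
        plain.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(plain, sort_keys=True).encode()
        ).hexdigest()[:16]


def _from_dict(cls, d: dict):
    if d is None:
        return None
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    nested = {"bolus": BolusParams, "physics": KiselevParams,
              "simulate": PhantomSpec, "input": InputSettings,
              "conversion": ConversionParams, "ica": IcaSettings,
              "deconv": DeconvSpec}
    for key, val in d.items():
        if key in nested and isinstance(val, dict):
            kwargs[key] = _from_dict(nested[key], val)
        elif key in ("baseline_window",) and val is not None:
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, float) and obj != obj:  # NaN guard for YAML
        return None
    return obj


def load_config(path) -> RunConfig:
    """Parse a YAML config file; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(RunConfig, data).validate()


def dump_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
    return path
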