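"""Run configuration: a single human-readable YAML file with explicit units.

Unknown keys are rejected (fail-fast) so misspelled parameters cannot be
silently ignored.  The default configuration reproduces the study set-up:
one baseline run plus right-side shortenings of 2, 4, 6, 8, 10, 12, 14 and
16 mm with otherwise identical settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .contact import ContactParams
from .dynamics import ActivationProtocol, DynamicsParams
from .geometry import GeometryParams
from .materials import MooneyRivlinMaterial, PronySeries

__all__ = ["RunConfig", "load_config", "save_config", "config_digest"]

DEFAULT_SHORTENINGS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run or sweep."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    cartilage: MooneyRivlinMaterial = field(default_factory=MooneyRivlinMaterial)
    disc: PronySeries = field(default_factory=PronySeries)
    contact: ContactParams = field(default_factory=ContactParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    protocol: ActivationProtocol = field(default_factory=ActivationProtocol)
    dt: float = 5e-5                       # s
    shortening_side: str = "right"
    shortenings_mm: tuple[float, ...] = DEFAULT_SHORTENINGS
    output_dir: str = "tmjload_out"
    write_traces: bool = True
    write_stress_vtk: bool = True
    write_plots: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.shortening_side not in ("left", "right"):
            raise ValueError(f"shortening_side must be left or right, got {self.shortening_side!r}")
        if any(s < 0 for s in self.shortenings_mm):
            raise ValueError("shortenings must be >= 0")

    @classmethod
    def fast_preset(cls, **overrides) -> "RunConfig":
        """Reduced dt / surface resolution preset for quick sweeps."""
        geometry = overrides.pop("geometry", GeometryParams(surface_resolution=7))
        return cls(geometry=geometry, dt=1e-4, **overrides)


_SECTIONS = {
    "geometry": GeometryParams,
    "cartilage": MooneyRivlinMaterial,
    "disc": PronySeries,
    "contact": ContactParams,
    "dynamics": DynamicsParams,
    "protocol": ActivationProtocol,
}
_SCALARS = ("dt", "shortening_side", "shortenings_mm", "output_dir",
            "write_traces", "write_stress_vtk", "write_plots")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dc_fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(x) for x in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("# tmjload run configuration (lengths mm, forces N, times s, "
                 "stresses Pa / Prony moduli MPa)\n")
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dc_fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {}, name)
    for name in _SCALARS:
        if name in data:
            v = data[name]
            kwargs[name] = tuple(v) if isinstance(v, list) else v
    return RunConfig(**kwargs)


def config_digest(cfg: RunConfig) -> str:
    """SHA-256 of the canonical (key-sorted) JSON form; stable under key order."""
    return hashlib.sha256(
        json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    ).hexdigest()
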