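"""YAML configuration: probe geometry, layer stacks and preset registry.

A config file looks like::

    probe:
      size_um: 60          # tip diameter
    stack:
      layers:
        - {thickness_um: 10, modulus_MPa: 3.16, poisson: 0.45}
        - {thickness_um: 1000, modulus_MPa: 2.6, poisson: 0.45}
    indentation:
      depth_um: 20
    presets:               # optional overrides of the packaged registry
      wt_60um: {plateau: 1.0, f50_mN: 3.0, f90_mN: 4.0}

Missing sections fall back to the packaged defaults (60 μm probe, the
cuticle-on-PDMS stack, 20 μm depth).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .contact import ProbeSpec
from .fields import Layer, LayerStack
from .synthetic import PRESETS, ResponsePreset

__all__ = ["load_config", "probe_from_config", "stack_from_config", "presets_from_config"]


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML config file; ``None`` gives an empty (all-defaults) config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def probe_from_config(cfg: dict[str, Any], default_size: float = 60.0) -> ProbeSpec:
    size = cfg.get("probe", {}).get("size_um", default_size)
    return ProbeSpec(diameter=float(size))


def stack_from_config(cfg: dict[str, Any]) -> LayerStack:
    layers_cfg = cfg.get("stack", {}).get("layers")
    if not layers_cfg:
        return LayerStack.default()
    return LayerStack(
        tuple(
            Layer(
                thickness=float(l["thickness_um"]),
                modulus=float(l["modulus_MPa"]),
                poisson=float(l.get("poisson", 0.45)),
            )
            for l in layers_cfg
        )
    )


def presets_from_config(cfg: dict[str, Any]) -> dict[str, ResponsePreset]:
    """Packaged preset registry with any config-file overrides applied."""
    registry = dict(PRESETS)
    for name, spec in (cfg.get("presets") or {}).items():
        base = registry.get(name)
        registry[name] = ResponsePreset(
            label=name,
            plateau=float(spec.get("plateau", base.plateau if base else 1.0)),
            f50=float(spec.get("f50_mN", base.f50 if base else 1.0)),
            f90=float(spec.get("f90_mN", base.f90 if base else 2.0)),
            noise_sd=float(spec.get("noise_sd", base.noise_sd if base else 0.1)),
            n_cells=int(spec.get("n_cells", base.n_cells if base else 12)),
            force_grid=tuple(spec.get("force_grid", base.force_grid if base else (0.0, 1.0, 2.0, 3.0))),
        )
    return registry
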