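"""Run configuration: YAML/JSON loading, grid parsing, and config echoes.

A run config is a plain nested dict; ``load_config`` accepts YAML or JSON
(YAML is a superset, so one loader serves both) and ``config_hash`` gives a
short stable digest for logging so a run can be tied to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .species import SEBUM_PRESETS, ChainKind, LipidClass, MoietyRange, SpeciesGrid

__all__ = ["load_config", "dump_config", "config_hash", "grid_from_config"]


def load_config(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config must be a mapping, got {type(data).__name__}")
    return data


def dump_config(config: dict, path=None) -> str:
    text = json.dumps(config, indent=2, sort_keys=True, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, ensure_ascii=False).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def grid_from_config(spec: dict | str) -> SpeciesGrid:
    """Build a species grid from a preset name or an explicit mapping.

    Mapping form::

        class: 2α-WdiE
        axes:
          - {kind: FA, carbons: [16, 16], double_bonds: [0, 1]}
          - {kind: diol_FA, carbons: [32, 60], double_bonds: [0, 1, 2, 3]}
    """
    if isinstance(spec, str):
        try:
            return SEBUM_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown grid preset {spec!r}; presets: {sorted(SEBUM_PRESETS)}"
            ) from None
    cls = LipidClass(spec["class"])
    axes = []
    for ax in spec["axes"]:
        axes.append(MoietyRange(
            kind=ChainKind(ax["kind"]),
            carbons=tuple(ax["carbons"]),
            double_bonds=tuple(ax["double_bonds"]),
            carbon_step=int(ax.get("carbon_step", 1)),
        ))
    return SpeciesGrid(cls, tuple(axes), extrapolated=bool(spec.get("extrapolated", False)))
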