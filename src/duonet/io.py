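"""Serialisation helpers: parameters, conditions and results to JSON/YAML."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .conditions import ExperimentalCondition
from .parameters import ModelParameters
from .topology import RegulatoryTopology

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "condition_to_dict",
    "condition_from_dict",
    "dump_json",
    "load_yaml",
]


def params_to_dict(params: ModelParameters) -> dict[str, Any]:
    return {
        "b_e": params.b_e,
        "b_g": params.b_g,
        "k_e": params.k_e,
        "k_g": params.k_g,
        "f": params.f.tolist(),
        "K": params.K.tolist(),
        "n": params.n.tolist(),
    }


def params_from_dict(d: Mapping[str, Any]) -> ModelParameters:
    return ModelParameters(
        b_e=float(d["b_e"]),
        b_g=float(d["b_g"]),
        k_e=float(d["k_e"]),
        k_g=float(d["k_g"]),
        f=np.asarray(d["f"], dtype=float),
        K=np.asarray(d["K"], dtype=float),
        n=np.asarray(d["n"], dtype=float),
    )


def condition_to_dict(condition: ExperimentalCondition) -> dict[str, Any]:
    return {
        "sirna_target": condition.sirna_target,
        "sirna_efficiency": condition.sirna_efficiency,
        "chx_window": list(condition.chx_window) if condition.chx_window else None,
        "ici_dose": condition.ici_dose,
        "ici_k50": condition.ici_k50,
        "ici_loss_rate": condition.ici_loss_rate,
        "label": condition.label,
    }


def condition_from_dict(d: Mapping[str, Any]) -> ExperimentalCondition:
    chx = d.get("chx_window")
    return ExperimentalCondition(
        sirna_target=d.get("sirna_target", "none"),
        sirna_efficiency=float(d.get("sirna_efficiency", 0.9)),
        chx_window=tuple(chx) if chx else None,
        ici_dose=float(d.get("ici_dose", 0.0)),
        ici_k50=float(d.get("ici_k50", 1.0)),
        ici_loss_rate=float(d.get("ici_loss_rate", 0.1)),
        label=d.get("label"),
    )


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, RegulatoryTopology):
            return o.to_string()
        if isinstance(o, ModelParameters):
            return params_to_dict(o)
        if isinstance(o, ExperimentalCondition):
            return condition_to_dict(o)
        return super().default(o)


def dump_json(obj: Any, path: str | Path | None = None, **kwargs) -> str:
    """JSON with numpy/domain-object support; writes to ``path`` if given."""
    text = json.dumps(obj, cls=_Encoder, indent=2, sort_keys=True, **kwargs)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def load_yaml(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
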