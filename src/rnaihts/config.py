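"""YAML configuration loading for the scoring and hit-selection constants."""

from __future__ import annotations

from pathlib import Path

import yaml

from .hits import SelectionConfig
from .scoring import ScoringConfig
from .simulate import ErrorModel, SimulationConfig, TruthModel


def load_config(path: str | Path) -> dict:
    """Read a YAML config file.  Recognised top-level sections: ``scoring``,
    ``selection``, ``simulation``, ``truth``, ``errors``; a flat file is
    treated as shared scoring+selection keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping")
    return raw


def scoring_config(raw: dict) -> ScoringConfig:
    return ScoringConfig.from_mapping(raw.get("scoring", raw))


def selection_config(raw: dict) -> SelectionConfig:
    return SelectionConfig.from_mapping(raw.get("selection", raw))


def _pick(cls, mapping: dict):
    known = set(cls.__dataclass_fields__)
    kwargs = {k: v for k, v in mapping.items() if k in known}
    for key in ("edge_rows", "edge_channels", "failed_plates"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in kwargs[key]
            )
    return cls(**kwargs)


def simulation_config(raw: dict) -> SimulationConfig:
    return _pick(SimulationConfig, raw.get("simulation", {}))


def truth_model(raw: dict) -> TruthModel:
    return _pick(TruthModel, raw.get("truth", {}))


def error_model(raw: dict) -> ErrorModel:
    return _pick(ErrorModel, raw.get("errors", {}))
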