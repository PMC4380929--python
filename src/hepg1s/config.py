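"""YAML/JSON configuration for protocols, noise, fits and track generation.

Configuration files are plain mappings; each loader accepts a dict or a
path to a ``.yaml``/``.yml``/``.json`` file.  Example protocol entry::

    condition: hgf40
    hgf_dose: 40.0
    t_stim: 24.0
    t_end: 72.0
    inhibitor: none
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .simulate import ExperimentProtocol
from .synth import HillSpec, NoiseSpec, TrackGeneratorSpec

__all__ = [
    "load_mapping",
    "protocol_from_config",
    "protocols_from_config",
    "noise_from_config",
    "track_spec_from_config",
    "FitConfig",
    "fit_config_from_config",
]


def load_mapping(source) -> dict:
    """Load a mapping from a dict (pass-through) or a YAML/JSON file."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


_PROTOCOL_KEYS = {"hgf_dose", "t_stim", "t_end", "washout_time", "inhibitor"}


def protocol_from_config(source) -> ExperimentProtocol:
    cfg = {k: v for k, v in load_mapping(source).items() if k in _PROTOCOL_KEYS}
    return ExperimentProtocol(**cfg)


def protocols_from_config(source) -> dict[str, ExperimentProtocol]:
    """Load ``{condition: protocol}`` from a list of protocol mappings with
    ``condition`` labels."""
    entries = load_mapping(source) if isinstance(source, dict) else load_mapping(source)
    if isinstance(entries, dict):
        entries = entries.get("protocols", entries)
    out = {}
    for entry in entries:
        label = entry.get("condition")
        if label is None:
            raise ValueError("each protocol entry needs a 'condition' label")
        out[label] = protocol_from_config(entry)
    return out


def noise_from_config(source) -> NoiseSpec:
    return NoiseSpec(**load_mapping(source))


def track_spec_from_config(source) -> TrackGeneratorSpec:
    cfg = dict(load_mapping(source))
    if isinstance(cfg.get("responder_hill"), dict):
        cfg["responder_hill"] = HillSpec(**cfg["responder_hill"])
    for key in ("g1_dwell", "g1s_dwell", "sgm_dwell", "abortive_dwell"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return TrackGeneratorSpec(**cfg)


@dataclass(frozen=True)
class FitConfig:
    """Multi-start estimation settings (production default: 1000 starts)."""

    n_starts: int = 1000
    s: float = 1.5
    max_iter: int = 300
    chi2_tol: float = 1e-5
    step_tol: float = 1e-5
    seed: int = 0
    select_k: int = 10


def fit_config_from_config(source) -> FitConfig:
    return FitConfig(**load_mapping(source))
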