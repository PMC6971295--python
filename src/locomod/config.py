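"""Declarative pipeline configuration.

A single YAML/JSON document holds every tunable of the pipeline; CLI flags
override file values and every run writes a resolved snapshot next to its
outputs, so config + seed fully determine all artifacts.
"""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "synthetic": {
        "scenario": "emg",          # 'emg' | 'joint_angle'
        "n_subjects": 8,
        "speed_range": [0.5, 2.5],
        "noise_energy_fraction": 0.48,
    },
    "preprocess": {
        "n_frames": 200,
        "lowpass_cutoff_hz": 15.0,
        "filter_order": 4,
        "emg_bandpass_hz": [20.0, 450.0],
        "emg_envelope_cutoff_hz": 4.0,
        "grf_threshold_n": 20.0,
        "min_phase_ms": 50.0,
        "cycle_anchor": "toe_off",
        "speed_bin_width": 0.1,
    },
    "decompose": {
        "rank": None,               # None -> automatic selection
        "threshold": 0.7,
        "R_max": 10,
        "nonneg": True,
        "max_iter": 500,
        "tol": 1.0e-8,
        "n_restarts": 10,
    },
    "analyze": {
        "walk_ref_speed": 1.8,
        "run_ref_speed": 2.3,
        "alpha": 0.05,
        "subject_weight_noise_sd": 0.05,  # per-subject spatial-weight scatter
    },
}


class PipelineConfig:
    """Nested dict of pipeline settings with dotted-path overrides."""

    def __init__(self, values: Optional[Dict[str, Any]] = None) -> None:
        self.values = deepcopy(DEFAULTS)
        if values:
            _deep_update(self.values, values)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(data)

    def override(self, dotted: str, value: Any) -> None:
        node = self.values
        *parts, last = dotted.split(".")
        for p in parts:
            node = node.setdefault(p, {})
        node[last] = value

    def get(self, dotted: str) -> Any:
        node = self.values
        for p in dotted.split("."):
            node = node[p]
        return node

    def to_json(self) -> str:
        return json.dumps(self.values, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))


def _deep_update(base: Dict[str, Any], new: Dict[str, Any]) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
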