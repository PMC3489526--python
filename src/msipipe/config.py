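"""Pipeline configuration: defaults, YAML loading, strict validation.

The config is a nested mapping of per-stage parameter sections.  Unknown
keys are rejected up front so a typo cannot silently fall back to a
default mid-run.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "input": None,                     # imzML or .h5 container path (ingest)
    "synth": {
        "width": 40,
        "height": 40,
        "noise_cv": 0.3,
        "baseline": 1.0,
        "hotspot_fraction": 0.01,
    },
    "normalization": {"method": "tic", "target_scale": None},
    "baseline": {"enabled": True, "window": 101},
    "smoothing": {"enabled": True, "window": 5},
    "peaks": {
        "snr": 3.0,
        "min_fraction": 0.01,
        "tol": 0.5,
        "max_per_spectrum": 60,
        "target_max": 200,
    },
    "segment": {
        "method": "spatial",           # kmeans | hierarchical | denoise | spatial
        "k": 3,
        "radius": 2.0,
        "adaptive": True,
        "denoise_strength": 1.0,
        "pca_variance": 0.70,
        "linkage": "ward",
    },
    "interpret": {"alpha": 0.05, "use_q": False, "top_n": 6},
    "classify": {
        "enabled": False,
        "roi": None,                   # CSV of x,y,label
        "group_a": 1,
        "group_b": 2,
        "folds": 5,
        "top_n": 5,
    },
    "viz": {
        "quantile": 0.95,
        "bins": 256,
        "spatial_sigma": 1.5,
        "range_sigma": 0.1,
        "colormap": "jet",
    },
}


class PipelineConfig:
    """Validated pipeline configuration with attribute-style section access."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        data = copy.deepcopy(DEFAULTS)
        if overrides:
            _merge(data, dict(overrides), path="")
        self._data = data

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(loaded)

    def section(self, name: str) -> dict[str, Any]:
        return copy.deepcopy(self._data[name])

    def __getitem__(self, name: str) -> Any:
        return copy.deepcopy(self._data[name])

    @property
    def seed(self) -> int:
        return int(self._data["seed"])

    def with_overrides(self, **kwargs: Any) -> "PipelineConfig":
        data = copy.deepcopy(self._data)
        _merge(data, kwargs, path="")
        cfg = PipelineConfig()
        cfg._data = data
        return cfg

    def as_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self._data)

    def digest(self, *sections: str) -> str:
        """Stable hash of the named sections (plus the seed)."""
        payload = {name: self._data[name] for name in sections}
        payload["seed"] = self._data["seed"]
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _merge(base: dict[str, Any], overrides: dict[str, Any], path: str) -> None:
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {where} must be a mapping")
            _merge(base[key], value, where)
        else:
            base[key] = value
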