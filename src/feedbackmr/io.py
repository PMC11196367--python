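"""Delimited-text input/output with '#'-prefixed metadata headers.

Every file written by the package embeds enough metadata (generating
parameters, seed, software version) to regenerate it exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .model import StructuralParams
from .simulate import COLUMNS

__all__ = ["write_dataset", "read_dataset", "read_metadata", "load_config", "params_from_mapping"]

_PARAM_FIELDS = [f.name for f in dataclasses.fields(StructuralParams)]


def write_dataset(data: pd.DataFrame, path, params: StructuralParams | None = None,
                  seed=None, extra: dict | None = None) -> None:
    """Write an (x1, x2, y1, y2) dataset as CSV with comment metadata lines."""
    meta = {"software": f"feedbackmr {__version__}", "n": int(len(data))}
    if params is not None:
        meta.update({k: getattr(params, k) for k in _PARAM_FIELDS})
    if seed is not None:
        meta["seed"] = seed
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        data.to_csv(fh, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset written by :func:`write_dataset` (or any 4-column CSV)."""
    data = pd.read_csv(path, comment="#")
    missing = set(COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
    return data[COLUMNS]


def read_metadata(path) -> dict:
    """Parse '# key = value' comment lines from a file header."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = yaml.safe_load(value.strip())
    return meta


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain mapping."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    return config


def params_from_mapping(mapping: dict) -> StructuralParams:
    """Build :class:`StructuralParams` from a config mapping, ignoring extras."""
    kwargs = {k: float(mapping[k]) for k in _PARAM_FIELDS if k in mapping}
    return StructuralParams(**kwargs)


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
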