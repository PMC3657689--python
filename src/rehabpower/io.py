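"""Long-format CSV and YAML-config I/O.

The single interchange format is a tidy CSV with header
``subject,group,session,y`` (UTF-8), rows in subject-major,
session-minor order.
"""

from __future__ import annotations

import dataclasses
import pathlib

import pandas as pd
import yaml

from .datagen import GeneratingModel, StudyDesign, validate_long
from .simulation import GridSpec

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "load_config",
    "dump_config",
]

_REQUIRED = ["subject", "group", "session", "y"]


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a long-format dataset.

    Malformed numeric fields are reported with their line numbers;
    duplicate (subject, session) pairs are an error.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_lines = []
    for col in ("session", "y"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        # line numbers are 1-based and include the header
        bad_lines += [(int(i) + 2, col, raw.loc[i, col]) for i in raw.index[bad]]
        raw[col] = coerced
    if bad_lines:
        detail = "; ".join(f"line {ln}: bad {col} value {v!r}" for ln, col, v in bad_lines[:5])
        raise ValueError(f"{path}: malformed rows — {detail}")
    if raw["y"].isna().any():
        rows = (raw.index[raw["y"].isna()] + 2).tolist()
        raise ValueError(f"{path}: missing outcome values at lines {rows[:5]}")
    return validate_long(raw)


def write_long_csv(data: pd.DataFrame, path) -> None:
    """Write a validated dataset in canonical (subject-major) row order."""
    validate_long(data).to_csv(path, index=False)


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("session_values", "group_labels", "sample_sizes", "waves",
                "effects", "methods"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path) -> dict:
    """Parse a YAML run config into typed blocks.

    Recognized top-level keys: ``design`` (StudyDesign fields), ``model``
    (GeneratingModel fields), ``grid`` (GridSpec fields); each optional.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    out: dict = {}
    if "design" in cfg:
        out["design"] = _from_mapping(StudyDesign, cfg["design"])
    if "model" in cfg:
        out["model"] = _from_mapping(GeneratingModel, cfg["model"])
    if "grid" in cfg:
        grid = dict(cfg["grid"])
        if "model" in grid:
            grid["base_model"] = _from_mapping(GeneratingModel, grid.pop("model"))
        out["grid"] = _from_mapping(GridSpec, grid)
    extra = set(cfg) - {"design", "model", "grid"}
    if extra:
        raise ValueError(f"unknown config sections: {sorted(extra)}")
    return out


def dump_config(blocks: dict, path) -> None:
    """Write config blocks back to YAML (read -> write -> read is lossless)."""
    payload = {}
    for key, value in blocks.items():
        d = dataclasses.asdict(value)
        if key == "grid":
            d["model"] = d.pop("base_model")
        payload[key] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
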