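"""Reflection-table and configuration I/O.

The native reflection container is a TSV dialect standing in for stream
chunks: one row per observation with columns image_id, a, b, c, alpha,
beta, gamma, h, k, l, I, sigma.  Every file written carries a stamped
header (tool version, master seed, config hash) in ``#``-prefixed lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import UnitCell
from .synth import ImageRecord

REFLECTION_COLUMNS = [
    "image_id", "a", "b", "c", "alpha", "beta", "gamma",
    "h", "k", "l", "I", "sigma",
]


class SchemaError(ValueError):
    """Reflection file does not match the documented schema."""


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stamp_header(seed=None, config: dict | None = None) -> list[str]:
    lines = [f"# ssxdamage {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


def write_reflection_tsv(
    images: list[ImageRecord], path, seed=None, config: dict | None = None
) -> None:
    frames = []
    for im in images:
        c = im.cell
        frames.append(pd.DataFrame({
            "image_id": im.image_id,
            "a": c.a, "b": c.b, "c": c.c,
            "alpha": c.alpha, "beta": c.beta, "gamma": c.gamma,
            "h": im.hkl[:, 0], "k": im.hkl[:, 1], "l": im.hkl[:, 2],
            "I": im.intensity, "sigma": im.sigma,
        }))
    table = pd.concat(frames, ignore_index=True)[REFLECTION_COLUMNS]
    with open(path, "w") as fh:
        fh.write("\n".join(stamp_header(seed, config)) + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_reflection_tsv(path) -> list[ImageRecord]:
    """Read the reflection TSV dialect back into image records.

    Raises :class:`SchemaError` on missing columns and a line-numbered
    parse error on malformed rows.
    """
    path = Path(path)
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REFLECTION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    numeric = table.columns.drop("image_id")
    converted = table[numeric].apply(pd.to_numeric, errors="coerce")
    bad = converted.isna().any(axis=1)
    if bad.any():
        # +2: 1-based line numbers plus the column-header line
        lineno = int(bad.idxmax()) + n_header + 2
        raise SchemaError(f"{path}:{lineno}: malformed row")
    table[numeric] = converted

    images = []
    for image_id, grp in table.groupby("image_id", sort=False):
        first = grp.iloc[0]
        cell = UnitCell(first["a"], first["b"], first["c"],
                        first["alpha"], first["beta"], first["gamma"])
        images.append(ImageRecord(
            image_id=str(image_id),
            cell=cell,
            hkl=grp[["h", "k", "l"]].to_numpy(dtype=int),
            intensity=grp["I"].to_numpy(dtype=float),
            sigma=grp["sigma"].to_numpy(dtype=float),
        ))
    return images


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config


def write_json(obj: dict, path, seed=None, config: dict | None = None) -> None:
    payload = {
        "tool": f"ssxdamage {__version__}",
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    } | obj
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
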