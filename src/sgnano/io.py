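"""Readers and writers for the pipeline's interchange formats.

Localization tables use a ThunderSTORM-compatible CSV dialect
(``frame, x [nm], y [nm], sigma [nm], intensity [photon], uncertainty [nm]``);
both comma and semicolon delimiters are accepted on read. Image stacks are
multi-page 16-bit TIFF, masks single-page 0/255 TIFF. Every table written by
the pipeline carries the parameter hash of the config that produced it as a
leading comment line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .locfit import LOC_COLUMNS

_TS_HEADER = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "sigma": "sigma [nm]",
    "photons": "intensity [photon]",
    "uncertainty": "uncertainty [nm]",
}
_TS_REVERSE = {v: k for k, v in _TS_HEADER.items()}


def config_hash(config: dict) -> str:
    """Stable short hash of a (JSON-serializable) parameter dictionary."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_locs_csv(df: pd.DataFrame, path: str | Path, params_hash: str | None = None) -> None:
    """Write a localization table in the ThunderSTORM CSV dialect."""
    out = df.rename(columns=_TS_HEADER)
    with open(path, "w") as fh:
        if params_hash:
            fh.write(f"# config_hash: {params_hash}\n")
        out.to_csv(fh, index=False)


def read_locs_csv(path: str | Path) -> pd.DataFrame:
    """Read a localization table; accepts ',' or ';' delimiters."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().strip('"') for c in df.columns]
    df = df.rename(columns=_TS_REVERSE)
    missing = {"frame", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table lacks columns: {sorted(missing)}")
    for col in LOC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[LOC_COLUMNS]


def write_table(df: pd.DataFrame, path: str | Path, params_hash: str | None = None,
                index: bool = False) -> None:
    """Write any result table as CSV with the config-hash comment line."""
    with open(path, "w") as fh:
        if params_hash:
            fh.write(f"# config_hash: {params_hash}\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0
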