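"""File I/O: 8-bit grayscale images, {0,255} masks, and provenance-stamped CSVs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_csv",
    "read_csv",
    "config_hash",
]


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    arr = np.asarray(pixels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary masks are stored as {0, 255} 8-bit images."""
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1, 255))):
        raise ValueError("mask must be binary")
    iio.imwrite(Path(path), np.where(arr > 0, 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a stored mask back to {0, 1}."""
    return (np.asarray(iio.imread(Path(path))) > 0).astype(np.uint8)


def config_hash(config: object) -> str:
    """Stable short hash of any JSON-serialisable config mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_csv(
    path: str | Path,
    frame: pd.DataFrame,
    *,
    seed: int | None = None,
    config: object = None,
    index: bool = False,
) -> None:
    """Write a CSV with a commented provenance header (seed + config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_hash={config_hash(config)}\n")
        frame.to_csv(fh, index=index)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
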