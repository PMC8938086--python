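"""Speckle/impulse denoising and data augmentation for B-mode ultrasound frames.

The centrepiece is a two-level adaptive median filter. For each pixel a
square window grows from ``initial_size`` to at most ``s_max``:

* **Level A** asks whether the window median is itself an extreme value
  (``A1 = Z_med - Z_min``, ``A2 = Z_max - Z_med``; both must be strictly
  positive). If not, the window is enlarged and Level A repeated; if the
  window reaches ``s_max`` without passing, the original centre value
  ``Z_xy`` is emitted.
* **Level B** keeps the centre pixel unless it is an extreme
  (``B1 = Z_xy - Z_min``, ``B2 = Z_max - Z_xy``; both strictly positive
  keeps ``Z_xy``, otherwise the median ``Z_med`` is emitted).

Strict inequalities mean ties (e.g. a constant window) trigger enlargement.
Borders are handled by edge replication so every pixel sees a full window,
and the filter reads only the original image, making the output independent
of scan order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "UltrasoundImage",
    "AugmentSpec",
    "window_stats",
    "level_a",
    "level_b",
    "adaptive_median_filter",
    "augment",
]

GO_TO_LEVEL_B = "go_to_level_b"
ENLARGE_WINDOW = "enlarge_window"


@dataclass(frozen=True)
class UltrasoundImage:
    """A 2-D grayscale frame with optional physical pixel spacing (mm)."""

    pixels: np.ndarray
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"image must be 2-D, got ndim={px.ndim}")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class AugmentSpec:
    """One augmentation step.

    ``magnitude`` is operation specific: rotation angle in degrees, zoom
    factor (> 0), additive brightness shift, multiplicative contrast factor
    about the image mean, or a ``(top, left, height, width)`` crop box.
    """

    operation: Literal["crop", "zoom", "rotate", "brightness", "contrast"]
    magnitude: float | tuple[int, int, int, int]
    seed: int | None = None


def _as_array(image: UltrasoundImage | np.ndarray) -> np.ndarray:
    if isinstance(image, UltrasoundImage):
        return image.pixels
    return np.asarray(image)


def _check_odd(value: int, name: str) -> None:
    if value < 1 or value % 2 == 0:
        raise ValueError(f"{name} must be a positive odd integer, got {value}")


def window_stats(
    image: UltrasoundImage | np.ndarray,
    center: tuple[int, int],
    m: int,
    n: int,
) -> tuple[float, float, float, float]:
    """Return ``(Z_min, Z_max, Z_med, Z_xy)`` over an ``m`` x ``n`` window.

    The window is centred at ``center`` (row, col); pixels outside the image
    are filled by edge replication. ``Z_med`` is always an element of the
    window because the window has odd cardinality.
    """
    _check_odd(m, "m")
    _check_odd(n, "n")
    px = _as_array(image)
    r, c = center
    if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
        raise ValueError(f"center {center} outside image of shape {px.shape}")
    pad_r, pad_c = m // 2, n // 2
    padded = np.pad(px, ((pad_r, pad_r), (pad_c, pad_c)), mode="edge")
    win = padded[r : r + m, c : c + n]
    vals = np.sort(win, axis=None)
    z_med = vals[vals.size // 2]
    return float(vals[0]), float(vals[-1]), float(z_med), float(px[r, c])


def level_a(z_min: float, z_max: float, z_med: float) -> str:
    """First decision layer: is the window median a usable (non-extreme) value?"""
    if (z_med - z_min) > 0 and (z_max - z_med) > 0:
        return GO_TO_LEVEL_B
    return ENLARGE_WINDOW


def level_b(z_min: float, z_max: float, z_med: float, z_xy: float) -> float:
    """Second decision layer: keep the centre pixel unless it is an extreme."""
    if (z_xy - z_min) > 0 and (z_max - z_xy) > 0:
        return z_xy
    return z_med


def adaptive_median_filter(
    image: UltrasoundImage | np.ndarray,
    initial_size: int = 3,
    s_max: int = 7,
) -> np.ndarray:
    """Apply the two-level adaptive median filter with a growing square window.

    Parameters
    ----------
    image
        2-D grayscale image (any numeric dtype; returned dtype matches).
    initial_size, s_max
        Odd starting and maximum window sizes; the window grows by 2 per
        side per Level-A failure.
    """
    _check_odd(initial_size, "initial_size")
    _check_odd(s_max, "s_max")
    if s_max < initial_size:
        raise ValueError(f"s_max={s_max} smaller than initial_size={initial_size}")
    px = _as_array(image)
    if px.ndim != 2:
        raise ValueError("image must be 2-D")

    out = px.copy()
    decided = np.zeros(px.shape, dtype=bool)
    # All window-size passes read the ORIGINAL image, never intermediate output.
    work = px.astype(np.float64)
    for size in range(initial_size, s_max + 1, 2):
        z_min = ndimage.minimum_filter(work, size=size, mode="nearest")
        z_max = ndimage.maximum_filter(work, size=size, mode="nearest")
        z_med = ndimage.median_filter(work, size=size, mode="nearest")
        passes_a = (z_med > z_min) & (z_max > z_med)
        keep_center = (work > z_min) & (z_max > work)
        level_b_out = np.where(keep_center, work, z_med)
        newly = passes_a & ~decided
        out[newly] = level_b_out[newly].astype(out.dtype)
        decided |= passes_a
    # Window budget exhausted without Level A passing: emit Z_xy (already in out).
    return out


def _rotate(px: np.ndarray, degrees: float) -> np.ndarray:
    deg = degrees % 360.0
    if deg == 0.0:
        return px.copy()
    if deg in (90.0, 180.0, 270.0):
        return np.rot90(px, k=int(deg // 90))
    rotated = sktransform.rotate(
        px.astype(np.float64), angle=degrees, mode="edge", preserve_range=True
    )
    return np.clip(rotated, 0, 255).astype(px.dtype)


def augment(image: UltrasoundImage | np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """Apply one deterministic geometric or photometric augmentation.

    Crop and zoom change the output shape; rotation keeps it (multiples of
    90 degrees are exact array rotations). Output is clipped to [0, 255].
    """
    px = _as_array(image)
    op = spec.operation
    if op == "rotate":
        return _rotate(px, float(spec.magnitude))
    if op == "brightness":
        shifted = px.astype(np.float64) + float(spec.magnitude)
        return np.clip(shifted, 0, 255).astype(px.dtype)
    if op == "contrast":
        factor = float(spec.magnitude)
        if factor <= 0:
            raise ValueError("contrast factor must be > 0")
        mean = px.astype(np.float64).mean()
        stretched = mean + factor * (px.astype(np.float64) - mean)
        return np.clip(stretched, 0, 255).astype(px.dtype)
    if op == "zoom":
        factor = float(spec.magnitude)
        if factor <= 0:
            raise ValueError("zoom factor must be > 0")
        zoomed = sktransform.rescale(
            px.astype(np.float64),
            factor,
            order=1,
            mode="edge",
            preserve_range=True,
            anti_aliasing=False,
        )
        return np.clip(zoomed, 0, 255).astype(px.dtype)
    if op == "crop":
        top, left, height, width = (int(v) for v in spec.magnitude)  # type: ignore[misc]
        if height <= 0 or width <= 0:
            raise ValueError("crop box must have positive size")
        if top < 0 or left < 0 or top + height > px.shape[0] or left + width > px.shape[1]:
            raise ValueError(f"crop box {(top, left, height, width)} outside image {px.shape}")
        return px[top : top + height, left : left + width].copy()
    raise ValueError(f"unknown augmentation operation: {op!r}")
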