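"""Frame and label-mask I/O with fixed geometric conventions.

Images are ``uint8`` RGB arrays of shape ``(height, width, 3)``; label masks
are ``uint8`` arrays of shape ``(height, width)`` with per-pixel class ids

* 0 — background (tissue),
* 1 — surgical tool,
* 2 — catheter.

Coordinates are 0-based with the origin at the top-left corner, ``x``
rightward and ``y`` downward, so "upper" always means smaller ``y``.  The
reference working resolution is 416 rows by 608 columns (the resolution the
endoscopic frames are resized to); smaller frames are used for desk-scale
training and tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_IDS",
    "N_CLASSES",
    "REFERENCE_HEIGHT",
    "REFERENCE_WIDTH",
    "read_frame",
    "write_frame",
    "read_mask",
    "write_mask",
    "resize_frame",
    "resize_mask",
    "validate_mask",
]

CLASS_IDS = (0, 1, 2)
N_CLASSES = 3

#: Reference frame size: 416 x 608 read as (height, width), configurable downstream.
REFERENCE_HEIGHT = 416
REFERENCE_WIDTH = 608

# Indexed-PNG palette for masks: background black, tool grey, catheter white.
_MASK_PALETTE = [0, 0, 0, 128, 128, 128, 255, 255, 255] + [0, 0, 0] * 253


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check a label raster and return it as a contiguous ``uint8`` array.

    Raises
    ------
    ValueError
        If the raster is not 2-D or contains a value outside ``{0, 1, 2}``.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be single-channel 2-D, got shape {arr.shape}")
    bad = np.setdiff1d(np.unique(arr), np.asarray(CLASS_IDS))
    if bad.size:
        raise ValueError(f"unknown class id {bad.tolist()} in mask (allowed: 0,1,2)")
    return np.ascontiguousarray(arr, dtype=np.uint8)


def read_frame(path: str | Path) -> np.ndarray:
    """Read an RGB frame (PNG/JPEG) as an ``(H, W, 3) uint8`` array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_frame(path: str | Path, frame: np.ndarray) -> None:
    arr = np.asarray(frame, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"frame must have shape (H, W, 3), got {arr.shape}")
    Image.fromarray(arr, mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask from a single-channel (indexed or greyscale) raster.

    Pixel values must lie in ``{0, 1, 2}``; anything else is rejected so that
    palette images saved by other tools cannot silently corrupt class ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode not in ("P", "L", "I", "I;16", "1"):
            raise ValueError(
                f"mask file {path} is mode {im.mode!r}; expected a single-channel indexed raster"
            )
        arr = np.asarray(im)
    return validate_mask(arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a label mask as an indexed PNG (palette: black/grey/white).

    Round-trips bit-exactly through :func:`read_mask`.
    """
    arr = validate_mask(mask)
    im = Image.fromarray(arr, mode="P")
    im.putpalette(_MASK_PALETTE)
    im.save(path, format="PNG")


def resize_frame(frame: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    """Resize an RGB frame with bilinear interpolation."""
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    arr = np.asarray(frame, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"frame must have shape (H, W, 3), got {arr.shape}")
    if (arr.shape[1], arr.shape[0]) == (target_w, target_h):
        return arr.copy()
    im = Image.fromarray(arr, mode="RGB").resize((target_w, target_h), Image.BILINEAR)
    return np.asarray(im, dtype=np.uint8)


def resize_mask(mask: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    """Resize a label mask with nearest-neighbour so class ids stay in {0,1,2}."""
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    arr = validate_mask(mask)
    if (arr.shape[1], arr.shape[0]) == (target_w, target_h):
        return arr.copy()
    im = Image.fromarray(arr, mode="L").resize((target_w, target_h), Image.NEAREST)
    return validate_mask(np.asarray(im))
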