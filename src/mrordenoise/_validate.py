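"""Shared input validation for image arrays.

Images are plain 2-D numpy arrays of floats in [0, 255]. Full precision is
kept internally; quantization to 8-bit happens only when a file is written.
"""

from __future__ import annotations

import numpy as np

#: smallest image side accepted anywhere in the package.  5x5 statistic
#: windows plus the reflect border policy need this much room.
MIN_SIDE = 16


def as_image(values, *, min_side: int = MIN_SIDE) -> np.ndarray:
    """Validate and return a grayscale image as a float64 2-D array.

    Raises ``ValueError`` if the array is not 2-D, smaller than
    ``min_side`` on either side, or has intensities outside [0, 255].
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got ndim={arr.ndim}")
    if arr.shape[0] < min_side or arr.shape[1] < min_side:
        raise ValueError(
            f"image {arr.shape} smaller than the minimum {min_side}x{min_side}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite intensities")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(
            f"intensities must lie in [0, 255], got [{arr.min()}, {arr.max()}]"
        )
    return arr


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")


def as_mask(mask, image: np.ndarray | None = None) -> np.ndarray:
    """Validate a boolean corruption/detection mask."""
    m = np.asarray(mask)
    if m.dtype != bool:
        raise ValueError(f"mask must be boolean, got dtype {m.dtype}")
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got ndim={m.ndim}")
    if image is not None:
        check_same_shape(m, image, "mask and image")
    return m
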