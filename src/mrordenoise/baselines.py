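"""Comparison filters: standard median and the two-level adaptive median.

The standard median filter replaces *every* pixel by its window median,
corrupted or not — effective against impulses but destructive to fine
detail (a one-pixel-wide bright line is simply voted away).  The adaptive
median filter (Hwang–Haddad scheme) grows the window until its median is
not an extreme of the window, then replaces the pixel only if the pixel
itself is an extreme — so non-extreme pixels pass through unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ._validate import as_image

__all__ = ["standard_median", "adaptive_median"]


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")


def standard_median(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Plain windowed median of every pixel (reflect borders)."""
    img = as_image(image)
    _check_window(window)
    return ndi.median_filter(img, size=window, mode="reflect")


def adaptive_median(image: np.ndarray, max_window: int = 11) -> np.ndarray:
    """Two-level adaptive median filter.

    Level A: starting at 3x3, grow the window by 2 while its median equals
    its min or max, up to ``max_window``.  Level B: in the first window
    whose median is interior, keep the pixel if it is itself interior,
    otherwise replace it with that window's median.  Pixels for which no
    window qualifies get the ``max_window`` median.
    """
    img = as_image(image)
    _check_window(max_window)
    out = img.copy()
    decided = np.zeros(img.shape, dtype=bool)
    med = img
    for window in range(3, max_window + 1, 2):
        med = ndi.median_filter(img, size=window, mode="reflect")
        mn = ndi.minimum_filter(img, size=window, mode="reflect")
        mx = ndi.maximum_filter(img, size=window, mode="reflect")
        interior_median = (med > mn) & (med < mx) & ~decided
        pixel_is_extreme = (img <= mn) | (img >= mx)
        replace = interior_median & pixel_is_extreme
        out[replace] = med[replace]
        decided |= interior_median
    out[~decided] = med[~decided]
    return out
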