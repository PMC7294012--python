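"""Adaptive fuzzy median (AFM) restoration of flagged pixels.

Each flagged pixel is rebuilt from the non-corrupted pixels inside a square
window centered on it.  The window starts small and grows (by 2 per step, up
to ``max_window``) while the clean sample is unusable: fewer than
``min_clean`` clean values, or the clean median is itself suspect — it sits
at an extreme of the clean sample and that extreme occurs only once (a lone
surviving outlier), the mask-aware analogue of the classic adaptive-median
"median is an impulse" trigger.  The surviving clean
values are combined with triangular fuzzy weights centered on their median
(half-width ``fuzzy_spread``, floored at a small positive weight), which
down-weights clean values that are themselves far from the local consensus.
If even the largest window holds no clean pixel, the plain median of all
window values is returned as a last resort.

Restoration never touches unflagged pixels, and within one pass every
replacement is computed from the *input* image — restored values never feed
other restorations in the same pass.  Cascading across passes is the
caller's (the detector's) job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validate import as_image, as_mask

__all__ = ["AFMConfig", "afm_restore_pixel", "afm_restore"]

#: floor weight so the fuzzy aggregate is always defined
_WEIGHT_FLOOR = 1e-3


@dataclass(frozen=True)
class AFMConfig:
    initial_window: int = 3
    max_window: int = 11
    fuzzy_spread: float = 20.0
    min_clean: int = 3

    def validate(self) -> None:
        if self.initial_window < 3 or self.initial_window % 2 == 0:
            raise ValueError("initial_window must be odd and >= 3")
        if self.max_window < self.initial_window or self.max_window % 2 == 0:
            raise ValueError("max_window must be odd and >= initial_window")
        if self.fuzzy_spread <= 0:
            raise ValueError("fuzzy_spread must be positive")
        if self.min_clean < 1:
            raise ValueError("min_clean must be >= 1")


def _fuzzy_aggregate(values: np.ndarray, spread: float) -> float:
    """Weighted mean with a triangular membership centered on the median."""
    med = np.median(values)
    w = np.maximum(1.0 - np.abs(values - med) / spread, _WEIGHT_FLOOR)
    return float(np.sum(w * values) / np.sum(w))


def _window_slices(row, col, half, shape):
    return (
        slice(max(row - half, 0), min(row + half + 1, shape[0])),
        slice(max(col - half, 0), min(col + half + 1, shape[1])),
    )


def afm_restore_pixel(
    image: np.ndarray,
    mask: np.ndarray,
    row: int,
    col: int,
    cfg: AFMConfig = AFMConfig(),
) -> float:
    """Restored intensity for the flagged pixel at (row, col)."""
    img = as_image(image)
    m = as_mask(mask, img)
    cfg.validate()
    if not m[row, col]:
        raise ValueError(f"pixel ({row}, {col}) is not flagged; refusing to restore it")

    window = cfg.initial_window
    while True:
        sl = _window_slices(row, col, window // 2, img.shape)
        win_vals = img[sl]
        clean_vals = win_vals[~m[sl]]
        usable = clean_vals.size >= cfg.min_clean
        if usable:
            # "median is an impulse" trigger: the clean median sits at an
            # extreme of the clean sample and that extreme is a singleton —
            # i.e. the sample is so thin its median is a lone outlier.
            med = np.median(clean_vals)
            cmin, cmax = clean_vals.min(), clean_vals.max()
            if cmin < cmax and (med == cmin or med == cmax):
                usable = int(np.count_nonzero(clean_vals == med)) > 1
        if usable or window >= cfg.max_window:
            break
        window += 2

    if clean_vals.size == 0:
        return float(np.median(win_vals))
    return _fuzzy_aggregate(clean_vals, cfg.fuzzy_spread)


def afm_restore(
    image: np.ndarray, mask: np.ndarray, cfg: AFMConfig = AFMConfig()
) -> np.ndarray:
    """Replace every flagged pixel by its AFM estimate; clean pixels pass through."""
    img = as_image(image)
    m = as_mask(mask, img)
    cfg.validate()
    out = img.copy()
    for row, col in zip(*np.nonzero(m)):
        out[row, col] = afm_restore_pixel(img, m, int(row), int(col), cfg)
    return out
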