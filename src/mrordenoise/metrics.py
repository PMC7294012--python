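"""Restoration quality metrics: MSE and PSNR (8-bit peak).

PSNR = 10 log10(255^2 / MSE) in decibels, with the peak fixed at 255 by
the 8-bit convention (never the per-image maximum).  A perfect restoration
has MSE 0 and PSNR +inf; tabular output renders that as the string "inf".
"""

from __future__ import annotations

import math

import numpy as np

from ._validate import as_image, check_same_shape

__all__ = ["mse", "psnr", "detection_scores"]

PEAK = 255.0


def mse(original: np.ndarray, restored: np.ndarray) -> float:
    """Mean squared pixel difference; 0 iff the images are identical."""
    a = as_image(original)
    b = as_image(restored)
    check_same_shape(a, b, "original and restored")
    return float(np.mean((a - b) ** 2))


def psnr(original: np.ndarray, restored: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; ``math.inf`` when MSE is 0."""
    err = mse(original, restored)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(PEAK**2 / err)


def detection_scores(truth: np.ndarray, detected: np.ndarray) -> tuple[float, float]:
    """(recall, false-positive rate) of a detected mask vs ground truth.

    Recall = flagged true impulses / true impulses; FPR = flagged clean
    pixels / clean pixels.  Degenerate denominators yield NaN.
    """
    t = np.asarray(truth, dtype=bool)
    d = np.asarray(detected, dtype=bool)
    check_same_shape(t, d, "truth and detected masks")
    pos = t.sum()
    neg = t.size - pos
    recall = float((t & d).sum() / pos) if pos else float("nan")
    fpr = float((~t & d).sum() / neg) if neg else float("nan")
    return recall, fpr
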