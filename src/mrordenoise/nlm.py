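"""Mask-restricted, reference-based non-local means restoration.

Standard NL-means rebuilds a pixel as a weighted average of other pixels,
the weights decaying exponentially with the squared distance between the
patches around them.  This variant extends that scheme three ways, matching
the switching philosophy of the detector it follows:

1. only pixels flagged in the mask are restored — clean pixels pass through
   bit-identical;
2. patch distances ignore flagged positions: the mean squared difference is
   taken over patch positions where *both* patches are clean, and a pair
   whose clean overlap falls below ``min_clean_fraction`` is declared
   incomparable (infinite distance, zero weight);
3. similarities and averaged intensities are read from a *reference* image —
   in the full pipeline the coarse/fine restored working image produced by
   the detector, the cleanest estimate the pipeline itself constructs.

Candidates are the clean pixels in a square search window; patch weighting
is uniform (no Gaussian kernel inside the distance).  If every candidate
weight vanishes the pixel falls back to the adaptive fuzzy median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from ._validate import as_image, as_mask, check_same_shape
from .afm import AFMConfig, afm_restore_pixel
from .detector import DetectionConfig, detect_full

__all__ = ["NLMConfig", "patch_distance", "nlm_restore", "denoise"]


@dataclass(frozen=True)
class NLMConfig:
    """NL-means tunables.

    ``patch_radius`` 3 means 7x7 patches; ``search_radius`` 10 means a
    21x21 candidate window; ``bandwidth_h`` is the intensity scale of the
    weight decay exp(-d / h^2).
    """

    patch_radius: int = 3
    search_radius: int = 10
    bandwidth_h: float = 10.0
    min_clean_fraction: float = 0.5
    afm_config: AFMConfig = field(default_factory=AFMConfig)

    def validate(self) -> None:
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.search_radius < max(self.patch_radius, 1):
            raise ValueError("search_radius must be >= patch_radius (and >= 1)")
        if self.bandwidth_h <= 0:
            raise ValueError("bandwidth_h must be positive")
        if not (0.0 < self.min_clean_fraction <= 1.0):
            raise ValueError("min_clean_fraction must lie in (0, 1]")
        self.afm_config.validate()


def patch_distance(
    reference: np.ndarray,
    mask: np.ndarray,
    p: tuple[int, int],
    q: tuple[int, int],
    cfg: NLMConfig = NLMConfig(),
) -> float:
    """Masked mean squared difference between the patches at ``p`` and ``q``.

    Averaged over patch positions where both patches are clean (patches are
    reflect-padded at the border).  Returns ``math.inf`` — the
    "incomparable" sentinel — when the clean overlap fraction is below
    ``cfg.min_clean_fraction``.
    """
    ref = as_image(reference)
    m = as_mask(mask, ref)
    cfg.validate()
    r = cfg.patch_radius
    refp = np.pad(ref, r, mode="symmetric")
    cleanp = np.pad(~m, r, mode="symmetric")

    def patch(arr, center):
        i, j = center
        return arr[i : i + 2 * r + 1, j : j + 2 * r + 1]

    both = patch(cleanp, p) & patch(cleanp, q)
    area = (2 * r + 1) ** 2
    if both.sum() < cfg.min_clean_fraction * area:
        return math.inf
    diff = patch(refp, p) - patch(refp, q)
    return float(np.mean(diff[both] ** 2))


def _nlm_weights_sweep(reference, clean, cfg):
    """Accumulate NL-means numerator/denominator for every pixel at once.

    One pass per search offset: patch sums of masked squared differences are
    box filters, so each offset costs two uniform_filter calls.
    """
    h, w = reference.shape
    pr, sr = cfg.patch_radius, cfg.search_radius
    k = 2 * pr + 1
    area = k * k
    pad = sr + pr
    refp = np.pad(reference, pad, mode="symmetric")
    cleanp = np.pad(clean.astype(float), pad, mode="symmetric")

    # views of shape (h + 2*pr, w + 2*pr): image plus a patch-radius apron
    def view(arr, dy, dx):
        return arr[sr + dy : sr + dy + h + 2 * pr, sr + dx : sr + dx + w + 2 * pr]

    c_img = view(refp, 0, 0)
    c_cln = view(cleanp, 0, 0)
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    inner = (slice(pr, pr + h), slice(pr, pr + w))
    h2 = cfg.bandwidth_h**2
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            s_img = view(refp, dy, dx)
            s_cln = view(cleanp, dy, dx)
            both = c_cln * s_cln
            d2 = (c_img - s_img) ** 2 * both
            cnt = uniform_filter(both, size=k)[inner] * area
            ssum = uniform_filter(d2, size=k)[inner] * area
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(cnt > 0, ssum / np.maximum(cnt, 1e-12), np.inf)
            valid = cnt >= cfg.min_clean_fraction * area - 1e-9
            wgt = np.where(valid, np.exp(-dist / h2), 0.0)
            # candidate q itself must be clean to contribute
            wgt *= s_cln[inner]
            num += wgt * s_img[inner]
            den += wgt
    return num, den


def nlm_restore(
    image: np.ndarray,
    mask: np.ndarray,
    reference: np.ndarray,
    cfg: NLMConfig = NLMConfig(),
) -> np.ndarray:
    """Restore flagged pixels of ``image`` from clean patches of ``reference``.

    Restored values are convex combinations of contributing reference
    intensities; pixels with no comparable clean candidate fall back to the
    adaptive fuzzy median of the reference.
    """
    img = as_image(image)
    ref = as_image(reference)
    m = as_mask(mask, img)
    check_same_shape(img, ref, "image and reference")
    cfg.validate()

    out = img.copy()
    if not m.any():
        return out

    num, den = _nlm_weights_sweep(ref, ~m, cfg)
    ok = m & (den > 0)
    out[ok] = num[ok] / den[ok]
    for row, col in zip(*np.nonzero(m & ~ok)):
        out[row, col] = afm_restore_pixel(ref, m, int(row), int(col), cfg.afm_config)
    return np.clip(out, 0, 255)


def denoise(
    image: np.ndarray,
    det_cfg: DetectionConfig = DetectionConfig(),
    nlm_cfg: NLMConfig = NLMConfig(),
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Full pipeline: detect impulses, then NL-means-restore them.

    The NL-means reference defaults to the coarse/fine restored working
    image the detector produces; pass ``reference`` to override it with an
    external clean image.  Never-flagged pixels of the output equal the
    input exactly.
    """
    img = as_image(image)
    result = detect_full(img, det_cfg)
    ref = result.restored if reference is None else as_image(reference)
    return nlm_restore(img, result.mask, ref, nlm_cfg)
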