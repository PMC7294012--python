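"""Iterative coarse/fine impulse detection.

Detection runs per-cluster threshold rules on the deviation |pixel - AMED|:
a pixel is flagged when its deviation exceeds the threshold assigned to its
mROR cluster.  The cascade has two stages:

* **coarse** (default 4 iterations, larger thresholds): each iteration
  recomputes the robust statistics on the current working image, flags
  pixels, restores the newly flagged ones with the adaptive fuzzy median,
  and feeds the restored image to the next iteration — so the working image
  drifts toward the clean image and previously hidden impulses surface.
* **fine** (default 2 iterations, strictly smaller thresholds): the same
  rule on the coarse-restored image, catching low-amplitude residuals.

The detected mask is the union over all iterations and stages; a pixel once
flagged is never unflagged (its value has been replaced, so later rules
cannot meaningfully re-judge it).  An iteration that flags nothing new ends
its stage early — a pure optimization with a bit-identical result.

The per-cluster threshold values are this package's own calibration on
phantom fixtures (they decrease from the most impulse-like cluster to the
least); the iteration caps follow the published finding that a few
iterations suffice and more degrade the restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validate import as_image, as_mask, check_same_shape
from .afm import AFMConfig, afm_restore
from .robust_stats import RobustStatConfig, amed_map, cluster_pixels, mror_map

__all__ = [
    "DetectionConfig",
    "DetectionResult",
    "decide_cluster",
    "detect_coarse",
    "detect_fine",
    "detect",
    "detect_full",
]


@dataclass(frozen=True)
class DetectionConfig:
    """All knobs of the detection cascade.

    ``coarse_thresholds`` / ``fine_thresholds`` are intensity thresholds on
    |pixel - AMED| indexed by cluster (1..4 = most to least impulse-like);
    every fine threshold must sit strictly below its coarse counterpart.
    """

    coarse_iterations: int = 4
    fine_iterations: int = 2
    coarse_thresholds: tuple[float, float, float, float] = (45.0, 30.0, 20.0, 15.0)
    fine_thresholds: tuple[float, float, float, float] = (34.0, 25.0, 16.0, 11.0)
    stat_config: RobustStatConfig = field(default_factory=RobustStatConfig)
    afm_config: AFMConfig = field(default_factory=AFMConfig)

    def validate(self) -> None:
        if self.coarse_iterations < 1 or self.fine_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if len(self.coarse_thresholds) != 4 or len(self.fine_thresholds) != 4:
            raise ValueError("need exactly four thresholds per stage")
        for c, f in zip(self.coarse_thresholds, self.fine_thresholds):
            if c <= 0 or f <= 0:
                raise ValueError("thresholds must be positive")
            if f >= c:
                raise ValueError(
                    f"fine threshold {f} must be strictly below coarse threshold {c}"
                )
        self.stat_config.validate()
        self.afm_config.validate()


@dataclass(frozen=True)
class DetectionResult:
    """Mask plus the restored working image and per-iteration diagnostics."""

    mask: np.ndarray
    restored: np.ndarray
    coarse_new_flags: tuple[int, ...]
    fine_new_flags: tuple[int, ...]


def decide_cluster(
    image: np.ndarray,
    amed: np.ndarray,
    cmap: np.ndarray,
    thresholds,
) -> np.ndarray:
    """Flag pixels whose |pixel - AMED| exceeds their cluster's threshold."""
    img = as_image(image)
    check_same_shape(img, np.asarray(amed), "image and AMED map")
    check_same_shape(img, np.asarray(cmap), "image and cluster map")
    thr = np.asarray(thresholds, dtype=float)
    if thr.shape != (4,) or (thr <= 0).any():
        raise ValueError("thresholds must be four positive values")
    thr_map = thr[np.asarray(cmap) - 1]
    return np.abs(img - np.asarray(amed, dtype=float)) > thr_map


def _stage(work, cum_mask, thresholds, iterations, cfg):
    """Run one detection stage; returns (mask, restored image, new-flag counts)."""
    counts = []
    for _ in range(iterations):
        mror = mror_map(work, cfg.stat_config)
        amed = amed_map(work, cfg.stat_config)
        labels = cluster_pixels(mror)
        new = decide_cluster(work, amed, labels, thresholds) & ~cum_mask
        counts.append(int(new.sum()))
        if not new.any():
            break
        cum_mask = cum_mask | new
        work = afm_restore(work, new, cfg.afm_config)
    return cum_mask, work, tuple(counts)


def detect_coarse(
    image: np.ndarray, cfg: DetectionConfig = DetectionConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse stage: returns (union mask, coarse-restored image)."""
    img = as_image(image)
    cfg.validate()
    mask = np.zeros(img.shape, dtype=bool)
    mask, restored, _ = _stage(
        img, mask, cfg.coarse_thresholds, cfg.coarse_iterations, cfg
    )
    return mask, restored


def detect_fine(
    coarse_restored: np.ndarray,
    prior_mask: np.ndarray,
    cfg: DetectionConfig = DetectionConfig(),
) -> np.ndarray:
    """Fine stage on the coarse-restored image; returns prior ∪ new flags."""
    img = as_image(coarse_restored)
    prior = as_mask(prior_mask, img)
    cfg.validate()
    mask, _, _ = _stage(img, prior, cfg.fine_thresholds, cfg.fine_iterations, cfg)
    return mask


def detect_full(
    image: np.ndarray, cfg: DetectionConfig = DetectionConfig()
) -> DetectionResult:
    """Full cascade with diagnostics; the restored image doubles as the
    NL-means reference downstream."""
    img = as_image(image)
    cfg.validate()
    mask = np.zeros(img.shape, dtype=bool)
    mask, work, coarse_counts = _stage(
        img, mask, cfg.coarse_thresholds, cfg.coarse_iterations, cfg
    )
    mask, work, fine_counts = _stage(
        work, mask, cfg.fine_thresholds, cfg.fine_iterations, cfg
    )
    return DetectionResult(mask, work, coarse_counts, fine_counts)


def detect(image: np.ndarray, cfg: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Coarse-then-fine detection; returns the final impulse mask."""
    return detect_full(image, cfg).mask
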