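"""Impulse-noise simulation.

Two corruption models, both replacing a random subset of pixels and leaving
the rest untouched:

* ``fixed_valued`` (salt-and-pepper): each corrupted pixel becomes either
  eta_min or eta_max (50/50 by default).
* ``random_valued``: each corrupted pixel is redrawn uniformly on
  [eta_min, eta_max] and rounded to an integer.

Each pixel is corrupted independently with probability ``p``, so corrupted
counts are Binomial(n_pixels, p); an exact-count mode replaces exactly
round(p * n_pixels) pixels for fixed-ratio experiments.  The returned mask
records the process, not the outcome: a random-valued replacement that
happens to equal the original still counts as corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validate import as_image, as_mask

__all__ = ["NoiseSpec", "corrupt", "corruption_rate"]

KINDS = ("fixed_valued", "random_valued")


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the impulse corruption process."""

    kind: str = "fixed_valued"
    p: float = 0.1
    eta_min: float = 0.0
    eta_max: float = 255.0
    seed: int = 0
    #: probability a fixed-valued impulse is "salt" (eta_max) rather than
    #: "pepper" (eta_min); the 50/50 default is an assumption, not a given
    salt_fraction: float = 0.5
    #: corrupt exactly round(p * n) pixels instead of Bernoulli(p) per pixel
    exact_count: bool = False

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not (0 <= self.eta_min < self.eta_max <= 255):
            raise ValueError(
                f"need 0 <= eta_min < eta_max <= 255, got [{self.eta_min}, {self.eta_max}]"
            )
        if not (0.0 <= self.salt_fraction <= 1.0):
            raise ValueError("salt_fraction must lie in [0, 1]")


def corrupt(image: np.ndarray, spec: NoiseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt ``image`` per ``spec``; return (noisy image, ground-truth mask).

    Deterministic given (image, spec).  Uncorrupted pixels are bit-identical
    to the input.
    """
    img = as_image(image)
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.exact_count:
        n = img.size
        k = int(round(spec.p * n))
        flat = np.zeros(n, dtype=bool)
        flat[rng.choice(n, size=k, replace=False)] = True
        mask = flat.reshape(img.shape)
    else:
        mask = rng.random(img.shape) < spec.p

    if spec.kind == "fixed_valued":
        salt = rng.random(img.shape) < spec.salt_fraction
        replacement = np.where(salt, spec.eta_max, spec.eta_min)
    else:
        replacement = np.rint(rng.uniform(spec.eta_min, spec.eta_max, img.shape))

    noisy = np.where(mask, replacement, img)
    return noisy, mask


def corruption_rate(mask: np.ndarray) -> float:
    """Fraction of flagged pixels in a mask."""
    m = as_mask(mask)
    return float(m.sum()) / m.size
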