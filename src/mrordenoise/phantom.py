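"""Seeded mammogram-like phantom images.

The phantom is a deliberately simple stand-in for a real mammogram: a smooth
background with an optional illumination ramp, a fine-grained correlated
texture field emulating parenchymal tissue, a few soft-edged bright blobs
playing the role of masses, and isolated bright specks playing the role of
microcalcifications.  It gives every detector and filter in the package a
clean ground-truth image without any external data.  The texture matters:
on a perfectly flat image a whole-image median filter is nearly lossless
and any comparison between switching and non-switching denoisers is
meaningless — fine-scale clean structure is precisely what is at stake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from ._validate import as_image

__all__ = ["PhantomSpec", "make_phantom", "load_phantom_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom.

    All intensities are on the 8-bit [0, 255] scale.  ``gradient_amplitude``
    is the total intensity swing of a linear illumination ramp across the
    image; ``mass_contrast`` and ``speck_contrast`` are peak heights above
    the local background (clipped at 255 after composition).
    """

    height: int = 256
    width: int = 256
    background_level: float = 90.0
    gradient_amplitude: float = 30.0
    n_masses: int = 3
    mass_radius_range: tuple[int, int] = (8, 24)
    mass_contrast: float = 60.0
    n_specks: int = 12
    speck_contrast: float = 80.0
    #: std-dev (intensity) and correlation length (pixels) of the smooth
    #: random field standing in for parenchymal texture
    texture_amplitude: float = 6.0
    texture_scale: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom must be at least 16x16")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level outside [0, 255]")
        lo, hi = self.mass_radius_range
        if not (0 < lo <= hi):
            raise ValueError("mass_radius_range must satisfy 0 < lo <= hi")
        if self.n_masses > 0 and 2 * hi >= min(self.height, self.width):
            raise ValueError(
                f"mass radius {hi} does not fit a {self.height}x{self.width} image"
            )
        if self.n_masses < 0 or self.n_specks < 0:
            raise ValueError("counts must be non-negative")
        if self.texture_amplitude < 0 or self.texture_scale <= 0:
            raise ValueError("texture_amplitude must be >= 0 and texture_scale > 0")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom described by ``spec``.

    Pure function of the spec (including its seed): identical specs yield
    bit-identical images.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    img = np.full((h, w), spec.background_level, dtype=float)

    if spec.gradient_amplitude != 0:
        theta = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(theta) * xx / max(w - 1, 1)
                + np.sin(theta) * yy / max(h - 1, 1))
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12)
        img += spec.gradient_amplitude * (ramp - 0.5)

    lo, hi = spec.mass_radius_range
    for _ in range(spec.n_masses):
        r = rng.uniform(lo, hi)
        cy = rng.uniform(r, h - 1 - r)
        cx = rng.uniform(r, w - 1 - r)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # soft Gaussian profile: contrast at center, ~1% at 1.5 radii
        img += spec.mass_contrast * np.exp(-d2 / (2 * (r / 2.0) ** 2))

    for _ in range(spec.n_specks):
        cy = rng.integers(1, h - 1)
        cx = rng.integers(1, w - 1)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # near-point speck: full contrast at the center pixel, sharp falloff
        img += spec.speck_contrast * np.exp(-d2 / (2 * 0.6**2))

    if spec.texture_amplitude > 0:
        field = gaussian_filter(rng.standard_normal((h, w)), spec.texture_scale)
        img += field / max(field.std(), 1e-12) * spec.texture_amplitude

    return as_image(np.clip(img, 0, 255))


def load_phantom_spec(path) -> PhantomSpec:
    """Load a :class:`PhantomSpec` from a YAML key-value file.

    Keys mirror the dataclass fields; omitted keys keep their defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"phantom spec file {path!r} must hold a mapping")
    if "mass_radius_range" in data:
        data["mass_radius_range"] = tuple(data["mass_radius_range"])
    spec = PhantomSpec(**data)
    spec.validate()
    return spec
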