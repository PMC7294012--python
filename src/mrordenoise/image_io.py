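"""Reading and writing 8-bit grayscale images (PGM, PNG, TIFF).

Intensities are held as floats in [0, 255] in memory and quantized to 8-bit
only on write (round-half-up).  Color inputs are collapsed to luminance with
the ITU-R BT.601 weights; higher bit depths are rescaled into [0, 255] by
dividing by the dtype maximum.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from ._validate import as_image

__all__ = ["read_image", "write_image"]

# ITU-R BT.601 luma weights for RGB -> gray conversion
_BT601 = np.array([0.299, 0.587, 0.114])

_WRITE_FORMATS = {".png", ".pgm"}


class UnsupportedDepthError(ValueError):
    """Raised for pixel formats the reader does not handle."""


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale image, returning a float64 array in [0, 255].

    PGM (P2/P5), PNG and TIFF are supported.  RGB(A) inputs are converted
    to luminance (BT.601; any alpha channel is dropped).  8-bit values pass
    through unchanged; 16-bit (and wider integer) values are rescaled by
    dividing by the dtype maximum and multiplying by 255.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps format errors inconsistently
        raise OSError(f"could not read image {path!r}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(float) @ _BT601
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise UnsupportedDepthError(
                f"cannot convert image with {arr.shape[2]} channels to grayscale"
            )
    elif arr.ndim != 2:
        raise UnsupportedDepthError(f"unsupported image dimensionality {arr.ndim}")

    if arr.dtype == np.uint8 or arr.dtype == float or arr.dtype == np.float64:
        out = arr.astype(float)
    elif np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.max <= 255:
            out = arr.astype(float)
        else:
            # e.g. 16-bit TIFF: value / 65535 * 255
            out = arr.astype(float) / info.max * 255.0
    elif np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(float)
    else:
        raise UnsupportedDepthError(f"unsupported pixel dtype {arr.dtype}")

    if out.min() < 0 or out.max() > 255:
        raise UnsupportedDepthError(
            f"decoded intensities outside [0, 255] for dtype {arr.dtype}"
        )
    return as_image(out)


def quantize(image: np.ndarray) -> np.ndarray:
    """Quantize a float image in [0, 255] to uint8, rounding half up."""
    return np.floor(np.asarray(image, dtype=float) + 0.5).clip(0, 255).astype(np.uint8)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an image as an 8-bit single-channel PNG or PGM file.

    The float pixels are rounded half-up to integers; a read-back therefore
    differs from the in-memory image by at most 0.5 per pixel.
    """
    img = as_image(image)
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext not in _WRITE_FORMATS:
        raise ValueError(
            f"unsupported write format {ext!r}; use one of {sorted(_WRITE_FORMATS)}"
        )
    iio.imwrite(path, quantize(img))
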