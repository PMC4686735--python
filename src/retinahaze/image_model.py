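"""Image I/O, value normalization, Gaussian kernels and the convolution contract.

Every retinal stage in this package operates on float64 arrays: a *plane* is a
2-D ``H x W`` array of unitless intensities, an *RGB image* is an ``H x W x 3``
stack with the planes ordered (R, G, B) and all values in [0, 1].

Convolution is the single spatial primitive shared by all layers.  Boundaries
are handled by mirror (edge-inclusive reflect) padding, so a spatially uniform
field passes through any normalized kernel unchanged and no artificial dark
frame is injected into centre-surround differences near image borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .exceptions import (
    DegenerateInputError,
    FormatError,
    GeometryError,
    ParameterError,
    RangeError,
    StructuralError,
)

logger = logging.getLogger("retinahaze")

__all__ = [
    "Kernel",
    "as_plane",
    "as_rgb_image",
    "convolve",
    "gaussian_kernel",
    "load_image",
    "normalize_joint_max",
    "save_image",
]


def as_plane(values) -> np.ndarray:
    """Validate and coerce ``values`` to a finite 2-D float64 plane."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise StructuralError(f"expected a non-empty 2-D plane, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise RangeError("plane contains non-finite values")
    return arr


def as_rgb_image(values) -> np.ndarray:
    """Validate and coerce ``values`` to a finite H x W x 3 float64 image."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise StructuralError(
            f"expected an H x W x 3 RGB image, got shape {arr.shape}"
        )
    if not np.isfinite(arr).all():
        raise RangeError("image contains non-finite values")
    return arr


def load_image(path) -> np.ndarray:
    """Read a raster image and map it to floats in [0, 1].

    8- and 16-bit integer images are divided by their full-scale value (255 or
    65535); float images are taken as already being on a [0, 1] scale and are
    clipped to it.  Grayscale inputs are replicated to three identical planes;
    an alpha channel is dropped with a logged warning.

    Raises
    ------
    OSError
        If the file cannot be read.
    FormatError
        If the pixel dtype or channel layout is unsupported.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except OSError:
        raise
    except Exception as exc:  # imageio wraps backend failures in various types
        raise OSError(f"cannot read image file '{path}': {exc}") from exc

    if raw.dtype == np.uint8:
        arr = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        arr = raw.astype(np.float64) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        arr = np.clip(raw.astype(np.float64), 0.0, 1.0)
    else:
        raise FormatError(
            f"unsupported pixel dtype {raw.dtype} in '{path}'; "
            "expected 8-/16-bit integer or float"
        )

    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of '%s'", path)
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"unsupported channel layout {arr.shape} in '{path}'"
        )
    return as_rgb_image(arr)


def save_image(path, image, bit_depth: int = 8) -> None:
    """Write a float image (plane or RGB) after clipping to [0, 1].

    ``bit_depth`` may be 8 (default) or 16.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise StructuralError(f"expected a plane or RGB image, got shape {arr.shape}")
    arr = np.clip(arr, 0.0, 1.0)
    if bit_depth == 8:
        out = np.round(arr * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(arr * 65535.0).astype(np.uint16)
    else:
        raise FormatError(f"unsupported bit depth {bit_depth}; use 8 or 16")
    iio.imwrite(Path(path), out)


def normalize_joint_max(image) -> np.ndarray:
    """Divide all three planes by the single maximum taken across R, G and B.

    This joint normalization preserves the relative scale between channels;
    the resulting global maximum is exactly 1.

    Raises
    ------
    DegenerateInputError
        If the image is all-zero (the division is undefined).
    """
    arr = as_rgb_image(image)
    m = float(arr.max())
    if m <= 0.0:
        raise DegenerateInputError("cannot normalize an all-zero image")
    return arr / m


@dataclass(frozen=True)
class Kernel:
    """Truncated, renormalized 2-D Gaussian on the integer grid [-r, r]^2."""

    weights: np.ndarray = field(repr=False)
    sigma: float
    radius: int

    @property
    def size(self) -> int:
        return 2 * self.radius + 1


def gaussian_kernel(sigma: float, radius: int) -> Kernel:
    """Isotropic Gaussian weights exp(-(x^2+y^2)/(2 sigma^2)), renormalized.

    The support is exactly (2 radius + 1)^2; after truncation the weights are
    rescaled to sum to 1 so that constant inputs are preserved.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ParameterError(f"sigma must be a positive real, got {sigma}")
    r = int(radius)
    if r != radius or r < 1:
        raise ParameterError(f"radius must be a positive integer, got {radius}")
    coords = np.arange(-r, r + 1, dtype=np.float64)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    w = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    w /= w.sum()
    return Kernel(weights=w, sigma=float(sigma), radius=r)


def convolve(plane, kernel) -> np.ndarray:
    """Convolve a plane with a kernel under mirror boundary padding.

    The output has the same shape as the input and the operation is linear in
    the input.  Kernels here are rotationally symmetric, so convolution and
    correlation coincide.

    Raises
    ------
    GeometryError
        If the kernel support exceeds ``2 * min(H, W) + 1``.
    """
    arr = as_plane(plane)
    weights = kernel.weights if isinstance(kernel, Kernel) else np.asarray(kernel, dtype=np.float64)
    if weights.ndim != 2 or weights.shape[0] % 2 == 0 or weights.shape[0] != weights.shape[1]:
        raise GeometryError(f"kernel must be square with odd side, got {weights.shape}")
    if weights.shape[0] > 2 * min(arr.shape) + 1:
        raise GeometryError(
            f"kernel side {weights.shape[0]} exceeds 2*min(H,W)+1 = {2 * min(arr.shape) + 1}"
        )
    return ndimage.convolve(arr, weights, mode="reflect")
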