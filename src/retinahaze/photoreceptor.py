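"""Photoreceptor sampling: cone channels, rod luminance, and OFF-pathway inputs.

The three camera planes R, G, B stand in for the L-, M- and S-cone samples of
the scene.  Rods sample the luminance f_L = (f_R + f_G + f_B)/3.  The diffuse
(yellow-sensitive) bipolar pathway pools M and L cones, f_Y = (f_R + f_G)/2;
the S/B contribution to it is omitted because diffuse bipolar input is
overwhelmingly M/L-dominated.  The OFF pathway is driven by the photometric
complement f' = 1 - f; the rod pathway has no OFF branch (rod bipolars are
ON-type only), so the complement is taken of R, G, B and Y but never of L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import RangeError
from .image_model import as_plane, as_rgb_image

__all__ = [
    "PhotoreceptorOutput",
    "off_input",
    "photoreceptor_layer",
    "rod_luminance",
    "yellow_channel",
]

#: Channel labels carried by the ON bipolar pathway (rod plane included).
ON_CHANNELS = ("R", "G", "B", "Y", "L")
#: Channel labels carried by the OFF bipolar pathway (no rod plane).
OFF_CHANNELS = ("R", "G", "B", "Y")


@dataclass(frozen=True)
class PhotoreceptorOutput:
    """Named single-channel planes produced by the photoreceptor layer."""

    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    Y: np.ndarray
    L: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


def rod_luminance(image) -> np.ndarray:
    """Rod sample of the scene: pointwise (f_R + f_G + f_B) / 3."""
    arr = as_rgb_image(image)
    return (arr[:, :, 0] + arr[:, :, 1] + arr[:, :, 2]) / 3.0


def yellow_channel(image) -> np.ndarray:
    """Diffuse-bipolar (yellow) input: pointwise (f_R + f_G) / 2, B ignored."""
    arr = as_rgb_image(image)
    return (arr[:, :, 0] + arr[:, :, 1]) / 2.0


def off_input(plane) -> np.ndarray:
    """Photometric complement 1 - f feeding the OFF bipolar cells.

    The operation is an involution on [0, 1]: applying it twice returns the
    input exactly.
    """
    arr = as_plane(plane)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise RangeError("OFF input requires values in [0, 1]")
    return 1.0 - arr


def photoreceptor_layer(image) -> PhotoreceptorOutput:
    """Split a normalized RGB image into the five retinal input channels."""
    arr = as_rgb_image(image)
    return PhotoreceptorOutput(
        R=arr[:, :, 0].copy(),
        G=arr[:, :, 1].copy(),
        B=arr[:, :, 2].copy(),
        Y=yellow_channel(arr),
        L=rod_luminance(arr),
    )
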