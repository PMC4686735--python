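"""ON/OFF cone-bipolar DOG filtering and the rod-bipolar luminance response.

Each bipolar cell has a centre-surround receptive field modelled as a
difference of Gaussians:

    BP_c  = f_c  (*) g(sigma_cen)  -  k * f_c  (*) g(sigma_sur)
    BP'_c = f'_c (*) g(sigma_cen)  -  k * f'_c (*) g(sigma_sur)

with f'_c = 1 - f_c the OFF input.  The surround sensitivity k is the
haze-suppression dial of the model: a spatially constant (zero-frequency)
field c is attenuated to c*(1-k) exactly, so dispersed low-frequency airlight
is removed in proportion to k while edges pass through.  Responses are
rectified at zero and jointly renormalized per polarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .exceptions import DegenerateInputError
from .image_model import Kernel, as_plane, convolve, gaussian_kernel
from .photoreceptor import OFF_CHANNELS, ON_CHANNELS, PhotoreceptorOutput, off_input

__all__ = ["BipolarOutput", "BipolarParams", "dog_filter", "bipolar_layer"]


@dataclass(frozen=True)
class BipolarParams:
    """DOG geometry and surround sensitivity of the bipolar receptive field.

    Parameters
    ----------
    sigma_cen, sigma_sur : float
        Standard deviations (pixels) of the excitatory centre and inhibitory
        annular surround Gaussians; the centre must be the narrower of the two.
        Defaults 0.5 and 1.0.
    k : float
        Sensitivity of the inhibitory surround, in [0, 1].  Default 0.3 for
        the dehazing pipeline; larger values remove more haze at the cost of
        fine detail.
    """

    sigma_cen: float = 0.5
    sigma_sur: float = 1.0
    k: float = 0.3

    def __post_init__(self):
        from .exceptions import ParameterError

        if not (0.0 < self.sigma_cen < self.sigma_sur):
            raise ParameterError(
                f"require 0 < sigma_cen < sigma_sur, got {self.sigma_cen}, {self.sigma_sur}"
            )
        if not (0.0 <= self.k <= 1.0):
            raise ParameterError(f"k must lie in [0, 1], got {self.k}")

    def center_kernel(self) -> Kernel:
        return gaussian_kernel(self.sigma_cen, ceil(3 * self.sigma_cen))

    def surround_kernel(self) -> Kernel:
        return gaussian_kernel(self.sigma_sur, ceil(3 * self.sigma_sur))


@dataclass
class BipolarOutput:
    """Rectified, jointly normalized bipolar responses per polarity.

    ``on`` holds planes for channels R, G, B, Y and the rod plane L; ``off``
    holds R, G, B, Y (rods have no OFF branch).
    """

    on: dict
    off: dict


def dog_filter(plane, params: BipolarParams | None = None) -> np.ndarray:
    """Difference-of-Gaussians response, before rectification.

    Computed as ``conv(f, g_cen) - k * conv(f, g_sur)``; may contain negative
    values (rectification is a separate step of the layer).
    """
    params = params if params is not None else BipolarParams()
    arr = as_plane(plane)
    center = convolve(arr, params.center_kernel())
    if params.k == 0.0:
        return center
    return center - params.k * convolve(arr, params.surround_kernel())


def _joint_normalize(planes: dict, polarity: str) -> dict:
    """Divide every plane by the joint maximum of the cone planes R, G, B.

    Y (and L for the ON polarity) are divided by that same joint cone maximum
    so the relative scale between all channels of one polarity is preserved.
    """
    joint_max = max(float(planes[c].max()) for c in ("R", "G", "B"))
    if joint_max <= 0.0:
        raise DegenerateInputError(
            f"joint maximum of the {polarity} cone responses is zero; "
            "normalization undefined"
        )
    return {c: p / joint_max for c, p in planes.items()}


def bipolar_layer(pr: PhotoreceptorOutput, params: BipolarParams | None = None) -> BipolarOutput:
    """Run the full bipolar stage on a photoreceptor output.

    ON planes are the rectified DOG responses of f_c for c in {R, G, B, Y, L};
    OFF planes are the rectified DOG responses of 1 - f_c for c in
    {R, G, B, Y}.  Each polarity is then renormalized by the joint maximum of
    its cone (R, G, B) planes.
    """
    params = params if params is not None else BipolarParams()
    on = {
        c: np.maximum(dog_filter(pr.channel(c), params), 0.0) for c in ON_CHANNELS
    }
    off = {
        c: np.maximum(dog_filter(off_input(pr.channel(c)), params), 0.0)
        for c in OFF_CHANNELS
    }
    return BipolarOutput(
        on=_joint_normalize(on, "ON"),
        off=_joint_normalize(off, "OFF"),
    )
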