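"""Single-opponent ganglion cells with a disinhibitory subunit surround.

A ganglion cell is excited through its classical centre by one channel and
inhibited through its extensive (non-classical) surround by the opponent
channel.  The surround is built from many subunits that first inhibit each
other — disinhibition — before their pooled activity inhibits the centre:

    U_c  = max(0, MBP_c - A_u * MBP_c (*) g(sigma_u))     subunit mutual inhibition
    S_c  = U_c (*) g(sigma_s)                              surround pooling
    GC_c = A_cen * max(0, MBP_c (*) g(sigma_cen) - A_s * S_o)

with o the opponent of c under the single-opponent wiring R->G, G->R, B->Y.
Larger A_u means stronger mutual inhibition among subunits, hence weaker
surround inhibition and a higher response to large stimuli — the classical
"secondary rise" of area-response curves.

Gaussian widths are tied to the receptive-field radii by sigma = r/3, with the
kernel support exactly (2r+1)^2.  The rectification in U is applied pointwise
before pooling, as the cascade order dictates.  The OFF ganglion cells apply
the identical wiring to the modulated OFF bipolar planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .amacrine import ModulatedBipolar
from .exceptions import ParameterError, StructuralError
from .image_model import Kernel, as_plane, convolve, gaussian_kernel

__all__ = [
    "GanglionOutput",
    "GanglionParams",
    "OPPONENT_MAP",
    "ganglion_layer",
    "ganglion_opponent",
    "opponent_channels",
    "subunit_response",
    "surround_pool",
]

#: Single-opponent wiring: output channel -> channel feeding its surround.
#: Y serves only as the surround of B and produces no output of its own.
OPPONENT_MAP = {"R": "G", "G": "R", "B": "Y"}


@dataclass(frozen=True)
class GanglionParams:
    """Receptive-field geometry and sensitivities of one ganglion population.

    Parameters
    ----------
    r_cen, r_sur, r_sub : int
        Radii (pixels) of the excitatory centre, the inhibitory surround and
        one surround subunit.  Gaussian widths follow sigma = r/3.  Pipeline
        defaults (1, 3, 1); the in-silico experiments use larger presets.
    A_cen, A_s, A_u : float
        Sensitivities of the centre, the surround, and the subunit mutual
        inhibition.  Pipeline defaults A_cen = A_s = 2 with A_u = 0.7 for the
        ON population and 0.5 for the OFF population.
    """

    r_cen: int = 1
    r_sur: int = 3
    r_sub: int = 1
    A_cen: float = 2.0
    A_s: float = 2.0
    A_u: float = 0.7

    def __post_init__(self):
        for name in ("r_cen", "r_sur", "r_sub"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v}")
        if not self.r_sur > self.r_cen:
            raise ParameterError(
                f"require r_sur > r_cen, got r_sur={self.r_sur}, r_cen={self.r_cen}"
            )
        if not self.A_cen > 0:
            raise ParameterError(f"A_cen must be positive, got {self.A_cen}")
        if self.A_s < 0 or self.A_u < 0:
            raise ParameterError("A_s and A_u must be non-negative")

    @property
    def sigma_cen(self) -> float:
        return self.r_cen / 3.0

    @property
    def sigma_sur(self) -> float:
        return self.r_sur / 3.0

    @property
    def sigma_sub(self) -> float:
        return self.r_sub / 3.0

    def center_kernel(self) -> Kernel:
        return gaussian_kernel(self.sigma_cen, self.r_cen)

    def surround_kernel(self) -> Kernel:
        return gaussian_kernel(self.sigma_sur, self.r_sur)

    def subunit_kernel(self) -> Kernel:
        return gaussian_kernel(self.sigma_sub, self.r_sub)


#: Pipeline defaults for the two polarities.
DEFAULT_ON = GanglionParams(A_u=0.7)
DEFAULT_OFF = GanglionParams(A_u=0.5)


@dataclass
class GanglionOutput:
    """Non-negative opponent responses, channels R, G, B per polarity."""

    on: dict
    off: dict


def subunit_response(mbp, params: GanglionParams) -> np.ndarray:
    """Subunit activity after mutual inhibition among neighbouring subunits.

    ``max(0, MBP - A_u * MBP (*) g(sigma_u))``, rectified pointwise before any
    pooling.  With A_u = 0 the input passes through unchanged.
    """
    arr = as_plane(mbp)
    if params.A_u == 0.0:
        return arr.copy()
    return np.maximum(arr - params.A_u * convolve(arr, params.subunit_kernel()), 0.0)


def surround_pool(u, params: GanglionParams) -> np.ndarray:
    """Total inhibited-subunit activity pooled over the surround Gaussian."""
    return convolve(as_plane(u), params.surround_kernel())


def ganglion_opponent(center, opponent_surround, params: GanglionParams) -> np.ndarray:
    """Opponent centre-surround subtraction with output rectification.

    ``A_cen * max(0, center (*) g(sigma_cen) - A_s * opponent_surround)``.
    """
    c = as_plane(center)
    s = as_plane(opponent_surround)
    if c.shape != s.shape:
        raise StructuralError(
            f"center shape {c.shape} and surround shape {s.shape} disagree"
        )
    drive = convolve(c, params.center_kernel()) - params.A_s * s
    return params.A_cen * np.maximum(drive, 0.0)


def opponent_channels(
    channels: Mapping[str, np.ndarray],
    params: GanglionParams,
    opponents: Mapping[str, str] = OPPONENT_MAP,
) -> dict:
    """Run the full subunit -> pool -> opponent cascade for one polarity.

    ``channels`` must provide a plane for every centre channel and every
    opponent-surround channel named by ``opponents``.
    """
    needed = set(opponents) | set(opponents.values())
    missing = sorted(needed - set(channels))
    if missing:
        raise StructuralError(f"missing channels for ganglion layer: {missing}")
    pooled = {
        o: surround_pool(subunit_response(channels[o], params), params)
        for o in set(opponents.values())
    }
    return {
        c: ganglion_opponent(channels[c], pooled[o], params)
        for c, o in opponents.items()
    }


def ganglion_layer(
    mbp: ModulatedBipolar,
    params_on: GanglionParams | None = None,
    params_off: GanglionParams | None = None,
    opponents: Mapping[str, str] = OPPONENT_MAP,
) -> GanglionOutput:
    """Apply the opponent cascade to both modulated bipolar polarities."""
    params_on = params_on if params_on is not None else DEFAULT_ON
    params_off = params_off if params_off is not None else DEFAULT_OFF
    return GanglionOutput(
        on=opponent_channels(mbp.on, params_on, opponents),
        off=opponent_channels(mbp.off, params_off, opponents),
    )
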