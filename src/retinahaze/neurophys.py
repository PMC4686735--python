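"""In-silico electrophysiology on the model ganglion cells.

Two classical protocols are reproduced on a red-ON/green-OFF single-opponent
cell, driving the ganglion stage directly from the photoreceptor channels so
the measured response is a pure function of the opponent cascade:

* **Area-response**: a red patch covers the receptive-field centre and an
  equi-luminant green annulus extends from the centre's edge out to the
  stimulus radius over a dark field.  Without subunit disinhibition (A_u = 0)
  the response falls monotonically once the stimulus invades the surround;
  with A_u > 0 the mutual inhibition among surround subunits grows with the
  stimulated area and partially releases the centre — the secondary rise.
  Preset geometry: centre/surround/subunit radii 3/10/3, A_s = 3, A_cen = 1.

* **Dispersion**: a 5x5 patch with a 3x3 red block covering the full centre
  plus a white foreground whose total flux is held exactly constant while its
  spatial spread grows with a "dispersive angle" from 0 (maximally
  concentrated) to 180 degrees (spread uniformly over the patch).  With
  disinhibition the R-channel response rises with dispersion; with A_u = 0 the
  surround inhibition stays above the centre drive at every angle and the
  response sits flat at the rectification floor.  Geometry: radii 1/3/1 with
  A_cen = 1 and A_u = A_s / 2.

The dispersion pattern interpolates linearly between the most concentrated
representable configuration (centre-out Chebyshev rings filled to intensity 1)
and the uniform pattern, so flux conservation is exact by construction and
only ordinal properties of the curves are protocol-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .amacrine import modulate
from .bipolar import BipolarParams, bipolar_layer
from .exceptions import GeometryError, ParameterError
from .ganglion import GanglionParams, opponent_channels
from .photoreceptor import photoreceptor_layer

__all__ = [
    "ResponseCurve",
    "StimulusPatch",
    "area_preset",
    "area_response_curve",
    "dispersion_preset",
    "dispersion_response_curve",
    "make_area_stimulus",
    "make_dispersion_stimulus",
]

RED = np.array([1.0, 0.0, 0.0])
GREEN = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class StimulusPatch:
    """A small RGB stimulus with a protocol label."""

    image: np.ndarray
    description: str


@dataclass(frozen=True)
class ResponseCurve:
    """Paired stimulus parameters and centre-pixel GC_R responses."""

    abscissa: tuple
    response: tuple


def area_preset(A_u: float, A_s: float = 3.0, A_cen: float = 1.0) -> GanglionParams:
    """Ganglion parameters for the area-response protocol (radii 3/10/3)."""
    return GanglionParams(r_cen=3, r_sur=10, r_sub=3, A_cen=A_cen, A_s=A_s, A_u=A_u)


def dispersion_preset(A_s: float, A_u: float | None = None) -> GanglionParams:
    """Ganglion parameters for the dispersion protocol (radii 1/3/1).

    By default the subunit sensitivity is tied to the surround, A_u = A_s / 2.
    """
    return GanglionParams(
        r_cen=1,
        r_sur=3,
        r_sub=1,
        A_cen=1.0,
        A_s=A_s,
        A_u=0.5 * A_s if A_u is None else A_u,
    )


def make_area_stimulus(
    radius: float, patch_size: int = 25, center_radius: int = 3
) -> StimulusPatch:
    """Red centre disc plus an equi-luminant green annulus out to ``radius``.

    The red disc never exceeds ``center_radius`` (the receptive-field centre);
    the green surround fills the annulus (center_radius, radius].  Radius 0
    gives a dark field with no red pixels.  Red (1,0,0) and green (0,1,0) have
    equal rod luminance, so the two stimulus regions are equi-luminant.
    """
    if patch_size < 3 or patch_size % 2 == 0:
        raise GeometryError(f"patch_size must be odd and >= 3, got {patch_size}")
    if radius < 0:
        raise GeometryError(f"radius must be non-negative, got {radius}")
    if radius > (patch_size - 1) // 2:
        raise GeometryError(
            f"radius {radius} exceeds patch half-width {(patch_size - 1) // 2}"
        )
    c = patch_size // 2
    rows, cols = np.mgrid[0:patch_size, 0:patch_size]
    dist = np.hypot(rows - c, cols - c)
    image = np.zeros((patch_size, patch_size, 3))
    if radius > 0:
        image[dist <= min(radius, center_radius)] = RED
        image[(dist > center_radius) & (dist <= radius)] = GREEN
    return StimulusPatch(
        image=image,
        description=f"area stimulus: red centre r<={center_radius}, "
        f"green annulus to r={radius}",
    )


def _direct_channels(image):
    """Photoreceptor channels driving the ganglion stage directly."""
    pr = photoreceptor_layer(image)
    return {"R": pr.R, "G": pr.G, "B": pr.B, "Y": pr.Y}


def _front_end_channels(image):
    """Alternative routing through the bipolar and amacrine stages."""
    mbp = modulate(bipolar_layer(photoreceptor_layer(image), BipolarParams()))
    return mbp.on


def area_response_curve(
    radii: Sequence[float],
    A_u: float,
    preset: GanglionParams | None = None,
    patch_size: int = 25,
    through_front_end: bool = False,
) -> ResponseCurve:
    """Centre-pixel GC_R response as a function of total stimulus radius."""
    radii = list(radii)
    if any(b < a for a, b in zip(radii, radii[1:])):
        raise ParameterError("radii must be non-decreasing")
    params = replace(preset if preset is not None else area_preset(A_u), A_u=A_u)
    centre = patch_size // 2
    responses = []
    for radius in radii:
        stim = make_area_stimulus(radius, patch_size, center_radius=params.r_cen)
        channels = (
            _front_end_channels(stim.image)
            if through_front_end
            else _direct_channels(stim.image)
        )
        gc = opponent_channels(channels, params)
        responses.append(float(gc["R"][centre, centre]))
    return ResponseCurve(abscissa=tuple(radii), response=tuple(responses))


def _concentrated_pattern(patch_size: int, total_flux: float) -> np.ndarray:
    """Fill Chebyshev rings from the centre outwards, each pixel capped at 1."""
    c = patch_size // 2
    rows, cols = np.mgrid[0:patch_size, 0:patch_size]
    cheb = np.maximum(np.abs(rows - c), np.abs(cols - c))
    pattern = np.zeros((patch_size, patch_size))
    remaining = float(total_flux)
    for ring in range(c + 1):
        mask = cheb == ring
        n = int(mask.sum())
        value = min(1.0, remaining / n)
        pattern[mask] = value
        remaining -= value * n
        if remaining <= 0.0:
            break
    return pattern


def make_dispersion_stimulus(
    angle: float, total_flux: float = 16.0, patch_size: int = 5
) -> StimulusPatch:
    """Red 3x3 centre block plus a white foreground of fixed total flux.

    The white pattern interpolates between the most concentrated configuration
    (angle 0) and a uniform spread over the whole patch (angle 180); the
    summed white intensity equals ``total_flux`` at every angle.  White adds
    to all three colour planes; over the red block it saturates R and turns
    the block's G and B on.
    """
    if not (0.0 <= angle <= 180.0):
        raise ParameterError(f"dispersive angle must lie in [0, 180], got {angle}")
    if patch_size < 5 or patch_size % 2 == 0:
        raise GeometryError(f"patch_size must be odd and >= 5, got {patch_size}")
    if not (0.0 < total_flux <= patch_size**2):
        raise ParameterError(
            f"total flux must lie in (0, {patch_size**2}] to be representable "
            f"in [0, 1] pixels, got {total_flux}"
        )
    spread = angle / 180.0
    concentrated = _concentrated_pattern(patch_size, total_flux)
    uniform = np.full((patch_size, patch_size), total_flux / patch_size**2)
    white = (1.0 - spread) * concentrated + spread * uniform

    c = patch_size // 2
    rows, cols = np.mgrid[0:patch_size, 0:patch_size]
    block = (np.maximum(np.abs(rows - c), np.abs(cols - c)) <= 1).astype(float)
    image = np.stack(
        [np.minimum(block + white, 1.0), white.copy(), white.copy()], axis=2
    )
    return StimulusPatch(
        image=image,
        description=f"dispersion stimulus: angle={angle} deg, flux={total_flux}",
    )


def dispersion_response_curve(
    angles: Sequence[float],
    params: GanglionParams,
    with_disinhibition: bool = True,
    total_flux: float = 16.0,
    patch_size: int = 5,
) -> ResponseCurve:
    """Centre-pixel GC_R response as a function of dispersive angle."""
    angles = list(angles)
    if any(b < a for a, b in zip(angles, angles[1:])):
        raise ParameterError("angles must be non-decreasing")
    if not with_disinhibition:
        params = replace(params, A_u=0.0)
    centre = patch_size // 2
    responses = []
    for angle in angles:
        stim = make_dispersion_stimulus(angle, total_flux, patch_size)
        gc = opponent_channels(_direct_channels(stim.image), params)
        responses.append(float(gc["R"][centre, centre]))
    return ResponseCurve(abscissa=tuple(angles), response=tuple(responses))
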