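"""Koschmieder haze synthesis, MSE evaluation, and synthetic scene fixtures.

Atmospheric scattering is modelled by

    I(x) = J(x) * t(x) + A * (1 - t(x))

where J is the haze-free scene, t in [0, 1] the per-pixel transmission and A
the global airlight (pure white by default).  Transmission is tied to a
normalized disparity map by t = 0.8 * d, so near objects (large d) keep their
radiance while distant regions wash out towards the airlight.

``make_synthetic_scene`` builds a deterministic stand-in for stereo imagery
with known disparity: piecewise-constant, saturated coloured rectangles and
discs over a textured background, each object assigned a depth layer.  The
saturated hues exercise the single-opponent channels; the texture gives the
local-contrast metrics something to measure.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError, RangeError, StructuralError
from .image_model import as_plane, as_rgb_image

__all__ = [
    "HazeScene",
    "SyntheticScene",
    "haze_scene",
    "make_synthetic_scene",
    "mean_local_std",
    "mse",
    "recover_truth",
    "synthesize_haze",
    "transmission_from_disparity",
]

WHITE = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class HazeScene:
    """Ground-truth image J, transmission map t and airlight A."""

    J: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)
    A: tuple = WHITE

    def __post_init__(self):
        J = as_rgb_image(self.J)
        t = as_plane(self.t)
        if J.shape[:2] != t.shape:
            raise StructuralError(
                f"image shape {J.shape[:2]} and transmission shape {t.shape} disagree"
            )
        if t.min() < 0.0 or t.max() > 1.0:
            raise RangeError("transmission must lie in [0, 1]")
        if len(self.A) != 3 or not np.isfinite(self.A).all():
            raise ParameterError(f"airlight must be a finite RGB triple, got {self.A}")


def transmission_from_disparity(d, scale: float = 0.8) -> np.ndarray:
    """Map a normalized disparity plane to transmission, t = scale * d."""
    arr = as_plane(d)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise RangeError("disparity must lie in [0, 1]")
    if not (0.0 < scale <= 1.0):
        raise ParameterError(f"transmission scale must lie in (0, 1], got {scale}")
    return scale * arr


def synthesize_haze(scene: HazeScene) -> np.ndarray:
    """Apply the scattering model: I = J*t + A*(1 - t), per channel."""
    t = scene.t[:, :, None]
    airlight = np.asarray(scene.A, dtype=np.float64)
    return scene.J * t + airlight * (1.0 - t)


def recover_truth(hazy, t, A=WHITE) -> np.ndarray:
    """Algebraic inversion (I - A*(1-t)) / t; requires t > 0 everywhere."""
    arr = as_rgb_image(hazy)
    trans = as_plane(t)
    if trans.min() <= 0.0:
        raise ParameterError("inversion requires strictly positive transmission")
    airlight = np.asarray(A, dtype=np.float64)
    return (arr - airlight * (1.0 - trans[:, :, None])) / trans[:, :, None]


def mse(a, b) -> float:
    """Mean squared error over all pixels and channels."""
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise StructuralError(f"shape mismatch in MSE: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def mean_local_std(plane, size: int = 5) -> float:
    """Mean over the image of the local standard deviation in size x size windows.

    A simple detail-contrast metric: haze lowers it, enhancement raises it.
    """
    arr = as_plane(plane)
    m = ndimage.uniform_filter(arr, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(arr * arr, size=size, mode="reflect")
    var = np.clip(m2 - m * m, 0.0, None)
    return float(np.sqrt(var).mean())


@dataclass(frozen=True)
class SyntheticScene:
    """A generated haze-free image with its normalized disparity map."""

    J: np.ndarray = field(repr=False)
    d: np.ndarray = field(repr=False)
    seed: int = 0


def _saturated_color(rng) -> np.ndarray:
    hue = rng.uniform(0.0, 1.0)
    sat = rng.uniform(0.8, 1.0)
    val = rng.uniform(0.7, 1.0)
    return np.asarray(colorsys.hsv_to_rgb(hue, sat, val), dtype=np.float64)


def make_synthetic_scene(
    seed: int, height: int = 128, width: int = 128, n_objects: int = 6
) -> SyntheticScene:
    """Deterministic piecewise-constant scene with a layered depth map.

    Objects are coloured rectangles and discs drawn back-to-front; the later
    (nearer) an object is drawn, the larger its disparity.  The disparity
    plane is lightly smoothed to avoid step discontinuities and then rescaled
    to span [0, 1] exactly.  Identical seeds give bit-identical scenes.
    """
    if height < 32 or width < 32:
        raise ParameterError("scene dimensions must be at least 32 pixels")
    if n_objects < 1:
        raise ParameterError("n_objects must be at least 1")

    rng = np.random.default_rng(seed)
    base = rng.uniform(0.25, 0.5, size=3)
    image = np.broadcast_to(base, (height, width, 3)).copy()
    texture = rng.normal(0.0, 0.06, size=(height, width, 3))
    image += ndimage.gaussian_filter(texture, sigma=(1.2, 1.2, 0.0))

    disparity = np.full((height, width), 0.08)
    rows, cols = np.mgrid[0:height, 0:width]
    # draw order = depth order: later objects are nearer, hence larger d
    depths = 0.30 + 0.65 * (np.arange(1, n_objects + 1) / n_objects)
    for depth in depths:
        color = _saturated_color(rng)
        cy = rng.integers(height // 6, height - height // 6)
        cx = rng.integers(width // 6, width - width // 6)
        extent = int(rng.integers(min(height, width) // 10, min(height, width) // 4))
        if rng.random() < 0.5:
            mask = (np.abs(rows - cy) <= extent) & (np.abs(cols - cx) <= extent)
        else:
            mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= extent**2
        image[mask] = color
        disparity[mask] = depth

    disparity = ndimage.gaussian_filter(disparity, sigma=1.0)
    disparity = (disparity - disparity.min()) / (disparity.max() - disparity.min())
    return SyntheticScene(J=np.clip(image, 0.0, 1.0), d=disparity, seed=int(seed))


def haze_scene(scene: SyntheticScene, scale: float = 0.8, airlight=WHITE) -> HazeScene:
    """Bundle a synthetic scene with its transmission map and airlight."""
    return HazeScene(
        J=scene.J, t=transmission_from_disparity(scene.d, scale), A=tuple(airlight)
    )
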