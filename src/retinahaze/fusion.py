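"""ON/OFF pathway combination and the end-to-end dehazing pipeline.

Each pathway's scalar output is the mean of its three opponent channels,

    Out_ON  = (GC_R + GC_G + GC_B) / 3
    Out_OFF = (GC'_R + GC'_G + GC'_B) / 3

and the two pathways are fused with a luminance-driven weight,

    Out = w * Out_ON + (1 - w) * (1 - Out_OFF),        w = f_L(x, y),

so bright regions are read mainly through the ON system and dark regions
through the (inverted) OFF system.  For the colour result the same fusion is
applied channel-wise to each GC_c / GC'_c pair — the channel-averaged scalar
above is kept as a diagnostic luminance output — and the fused stack is
clipped to [0, 1] (or affinely rescaled, in ``rescale`` mode).
"""

from __future__ import annotations

import logging
import time
from typing import Mapping

import numpy as np

from .amacrine import modulate
from .bipolar import bipolar_layer
from .config import PipelineConfig, default_config
from .exceptions import RangeError, StructuralError
from .ganglion import ganglion_layer
from .image_model import as_plane, as_rgb_image, normalize_joint_max
from .photoreceptor import photoreceptor_layer

logger = logging.getLogger("retinahaze")

__all__ = ["dehaze", "fuse", "pathway_output"]


def pathway_output(gc: Mapping[str, np.ndarray]) -> np.ndarray:
    """Scalar retinal output of one pathway: the mean of GC_R, GC_G, GC_B."""
    missing = sorted(c for c in ("R", "G", "B") if c not in gc)
    if missing:
        raise StructuralError(f"pathway output missing channels: {missing}")
    return (gc["R"] + gc["G"] + gc["B"]) / 3.0


def fuse(out_on, out_off, w) -> np.ndarray:
    """Luminance-weighted combination ``w*Out_ON + (1-w)*(1-Out_OFF)``."""
    on = as_plane(out_on)
    off = as_plane(out_off)
    weight = as_plane(w)
    if not (on.shape == off.shape == weight.shape):
        raise StructuralError(
            f"shape mismatch in fusion: {on.shape}, {off.shape}, {weight.shape}"
        )
    if weight.min() < 0.0 or weight.max() > 1.0:
        raise RangeError("fusion weight must lie in [0, 1]")
    return weight * on + (1.0 - weight) * (1.0 - off)


def _finalize(stack: np.ndarray, mode: str) -> np.ndarray:
    if mode == "rescale":
        lo = float(stack.min())
        hi = float(stack.max())
        if hi > lo:
            return (stack - lo) / (hi - lo)
        return np.clip(stack, 0.0, 1.0)
    return np.clip(stack, 0.0, 1.0)


def dehaze(image, config: PipelineConfig | None = None, *, return_intermediates: bool = False):
    """Run the full retinal cascade on a single hazy image.

    normalize -> photoreceptors -> ON/OFF bipolar DOG -> amacrine modulation
    -> single-opponent ganglion cells -> channel-wise ON/OFF fusion.  The
    fusion weight is the rod luminance of the normalized input.  The result is
    a same-shape RGB image in [0, 1]; the operation is a pure function of
    (image, config).

    With ``return_intermediates=True`` a ``(result, info)`` pair is returned
    where ``info`` maps stage names to their channel planes plus per-stage
    wall times under ``"timings"``.
    """
    config = config if config is not None else default_config()
    arr = as_rgb_image(image)

    timings: dict[str, float] = {}

    def _timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        timings[name] = time.perf_counter() - t0
        logger.debug("stage %-13s %.4f s", name, timings[name])
        return out

    normalized = _timed("normalize", normalize_joint_max, arr)
    pr = _timed("photoreceptor", photoreceptor_layer, normalized)
    w = pr.L  # fusion weight comes from the input's rod luminance
    bp = _timed("bipolar", bipolar_layer, pr, config.bipolar)
    mbp = _timed("amacrine", modulate, bp, config.amacrine)
    gc = _timed("ganglion", ganglion_layer, mbp, config.ganglion_on, config.ganglion_off)

    t0 = time.perf_counter()
    fused = np.stack(
        [fuse(gc.on[c], gc.off[c], w) for c in ("R", "G", "B")], axis=2
    )
    result = _finalize(fused, config.output_mode)
    timings["fusion"] = time.perf_counter() - t0
    logger.debug("stage %-13s %.4f s", "fusion", timings["fusion"])

    if not return_intermediates:
        return result

    info = {
        "weight": w,
        "bipolar_on": bp.on,
        "bipolar_off": bp.off,
        "modulated_on": mbp.on,
        "modulated_off": mbp.off,
        "ganglion_on": gc.on,
        "ganglion_off": gc.off,
        "pathway_on": pathway_output(gc.on),
        "pathway_off": pathway_output(gc.off),
        "timings": timings,
    }
    return result, info
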