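"""AII amacrine modulation of cone bipolar responses by rod luminance.

The rod bipolar output BP_L reaches the cone pathways through AII amacrine
cells: multiplicatively (gap junctions) onto ON cone bipolars and divisively
(inhibitory synapses) onto OFF cone bipolars,

    MBP_c  = BP_c  * (eps + BP_L)
    MBP'_c = BP'_c / (eps + BP_L)

so ON responses are amplified where the scene is bright and OFF responses
where it is dark — the contrast-restoring step that compensates the detail
lost to the bipolar DOG.  The offset eps (default 0.5) keeps the divisor
positive and the gain near unity.  The two gains are exact reciprocals:
MBP_c * MBP'_c == BP_c * BP'_c pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bipolar import BipolarOutput
from .exceptions import ParameterError
from .photoreceptor import OFF_CHANNELS

__all__ = ["AmacrineParams", "ModulatedBipolar", "modulate"]


@dataclass(frozen=True)
class AmacrineParams:
    """Offset added to the rod drive before it multiplies/divides."""

    epsilon: float = 0.5

    def __post_init__(self):
        if not np.isfinite(self.epsilon) or self.epsilon <= 0:
            raise ParameterError(f"epsilon must be positive, got {self.epsilon}")


@dataclass
class ModulatedBipolar:
    """Luminance-modulated bipolar responses, channels R, G, B, Y per polarity."""

    on: dict
    off: dict


def modulate(bp: BipolarOutput, params: AmacrineParams | None = None) -> ModulatedBipolar:
    """Apply the rod-driven AII gain to both cone bipolar polarities.

    No re-normalization is performed afterwards: downstream rectification and
    the final output clip tolerate values exceeding 1.
    """
    params = params if params is not None else AmacrineParams()
    gain = params.epsilon + bp.on["L"]
    return ModulatedBipolar(
        on={c: bp.on[c] * gain for c in OFF_CHANNELS},
        off={c: bp.off[c] / gain for c in OFF_CHANNELS},
    )
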