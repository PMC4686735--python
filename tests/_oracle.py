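"""Independent brute-force oracles used to cross-check the fast implementations."""

import numpy as np


def direct_convolve(plane: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Direct double-loop windowed sum under mirror (symmetric) padding.

    Valid for the rotationally symmetric kernels used throughout the model,
    for which convolution and correlation coincide.
    """
    r = weights.shape[0] // 2
    padded = np.pad(plane, r, mode="symmetric")
    height, width = plane.shape
    out = np.zeros((height, width), dtype=np.float64)
    for i in range(height):
        for j in range(width):
            acc = 0.0
            for di in range(2 * r + 1):
                for dj in range(2 * r + 1):
                    acc += weights[di, dj] * padded[i + di, j + dj]
            out[i, j] = acc
    return out


def direct_dog(plane, center_weights, surround_weights, k):
    """Difference of Gaussians via the direct-sum convolution oracle."""
    return direct_convolve(plane, center_weights) - k * direct_convolve(
        plane, surround_weights
    )
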