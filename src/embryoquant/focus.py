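"""Best-focus z-slice selection.

The autofocus statistic is the variance of the 3x3 Laplacian response —
parameter-free, cheap, and invariant to global brightness offsets.
Defocus blur suppresses high spatial frequencies, so the score degrades
monotonically with blur on textured images and the in-focus slice of a
z-stack scores highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .errors import ParameterError

LAPLACIAN_3X3 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass(frozen=True)
class FocusProfile:
    """Per-slice focus scores and the selected slice (argmax, ties -> lowest)."""

    scores: np.ndarray
    best_index: int


def focus_score(image: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian of a 2D image.

    Non-negative; zero for a constant image; strictly larger for a
    textured image than for a Gaussian-blurred copy of it.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ParameterError("focus_score needs a 2D image of at least 3x3")
    resp = convolve(image, LAPLACIAN_3X3, mode="reflect")
    return float(resp.var())


def best_focus_slice(zstack: np.ndarray) -> FocusProfile:
    """Score every z-slice and pick the best-focused one.

    Ties are broken to the lowest z index.
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ParameterError("zstack must be (Z, Y, X) with at least one slice")
    scores = np.array([focus_score(sl) for sl in zstack])
    return FocusProfile(scores=scores, best_index=int(np.argmax(scores)))
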