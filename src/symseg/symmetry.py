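"""Reflection about the vertical midline and the signed difference image.

A healthy axial brain slice is approximately zygomorphic: mirror-symmetric
about the interhemispheric midline. Reflecting the slice O(x, y) about the
vertical image midline gives R(x, y), and the difference D = O - R cancels
everything bilaterally symmetric, leaving asymmetric structures — tumors —
as residuals. A lesion brighter than the tissue at its mirror position
produces a positive residual at its own location and a negative one at the
mirror site, whichever hemisphere it sits in; keeping only the positive
part (the *rectified* field) therefore localizes lesions on both sides and
keeps multiple lesions separable. Both pipelines share this stage.

The reflection axis is the geometric image midline (column c maps to
cols-1-c); for odd widths the center column is its own mirror. An optional
integer recentering shift is available for slices whose anatomical midline
is visibly off the image center, but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import validate_gray_image


def reflect(image: np.ndarray) -> np.ndarray:
    """Left-right mirror: R[r, c] = O[r, cols-1-c]. An involution."""
    return np.asarray(image)[:, ::-1].copy()


@dataclass(frozen=True)
class DifferenceImage:
    """Signed difference O - R and its positive (rectified) part.

    ``signed`` may be negative (it is exactly mirror-antisymmetric);
    ``rectified`` is max(signed, 0) and carries each lesion's evidence at
    its true location. All downstream stages consume ``rectified``.
    """

    signed: np.ndarray
    rectified: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.signed.shape


def difference_image(original: np.ndarray, reflection: np.ndarray) -> DifferenceImage:
    """D = O - R in real arithmetic (no unsigned clipping), plus positive part."""
    o = validate_gray_image(original, name="original")
    r = validate_gray_image(reflection, name="reflection")
    if o.shape != r.shape:
        raise ParameterError(f"shape mismatch: {o.shape} vs {r.shape}")
    signed = o - r
    return DifferenceImage(signed=signed, rectified=np.maximum(signed, 0.0))


def estimate_midline_shift(image: np.ndarray, max_frac: float = 0.1) -> int:
    """Integer column shift that best centers the slice's bilateral symmetry.

    Searches offsets within ±max_frac of the width for the roll that
    minimizes the mean squared mirror residual. Returns the offset to pass
    to :func:`recenter`; 0 means the image midline is already the best axis.
    """
    arr = validate_gray_image(image)
    span = max(1, int(round(max_frac * arr.shape[1])))
    best_shift, best_score = 0, np.inf
    for s in range(-span, span + 1):
        rolled = np.roll(arr, -s, axis=1)
        score = float(np.mean((rolled - rolled[:, ::-1]) ** 2))
        if score < best_score:
            best_score, best_shift = score, s
    return best_shift


def recenter(image: np.ndarray, shift: int) -> np.ndarray:
    """Roll columns so the estimated symmetry axis lands on the image midline."""
    return np.roll(np.asarray(image), -int(shift), axis=1)
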