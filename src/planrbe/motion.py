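"""Intrafractional-motion simulation by Gaussian blurring of the dose.

The expectation of the dose-to-structure under random Gaussian organ
displacements equals the convolution of the dose matrix with the
displacement kernel while the structures stay fixed; that convolution is
the default mode.  An explicit random-shift mode (sampling one rigid
displacement per fraction and averaging the shifted doses) is provided as
an alternative reading of the same motion model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DoseGrid

#: population-based intrafraction prostate motion, mm (LR, AP, CC)
DEFAULT_SIGMA_MM = (0.92, 1.59, 1.54)


@dataclass(frozen=True)
class MotionKernel:
    """Anisotropic Gaussian displacement kernel.

    sigma_mm : standard deviation per axis (LR, AP, CC), mm
    truncation : kernel support radius in multiples of sigma (>= 3)
    """

    sigma_mm: tuple[float, float, float] = DEFAULT_SIGMA_MM
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma_mm):
            raise ValueError("sigma must be non-negative")
        if self.truncation < 3:
            raise ValueError("truncation radius must be >= 3 sigma")

    def is_identity(self) -> bool:
        return all(s == 0 for s in self.sigma_mm)


def blur_dose(dose: DoseGrid, kernel: MotionKernel) -> DoseGrid:
    """Separable truncated-Gaussian convolution of the dose matrix.

    Sigma is converted from mm to voxels per axis; the discrete kernel is
    renormalized to unit sum and the grid edge is replicate-padded, so a
    constant field is invariant and no dose is lost at the border.
    Geometry and fractionation are unchanged; output is clipped at 0.
    """
    if kernel.is_identity():
        return dose.with_values(dose.values.copy())
    sigma_vox = [
        s / sp for s, sp in zip(kernel.sigma_mm, dose.geometry.spacing)
    ]
    blurred = ndimage.gaussian_filter(
        dose.values, sigma=sigma_vox, mode="nearest", truncate=kernel.truncation
    )
    return dose.with_values(np.maximum(blurred, 0.0))


def sample_shifted_dose(
    dose: DoseGrid, kernel: MotionKernel, rng: np.random.Generator
) -> DoseGrid:
    """Average of per-fraction rigidly shifted doses (alternative mode).

    One displacement per fraction is drawn from N(0, sigma) on each axis;
    the dose matrix is shifted by trilinear interpolation (replicate edge)
    and the per-fraction doses are averaged.  Converges to
    :func:`blur_dose` as the number of fractions grows.
    """
    n = dose.n_fractions
    acc = np.zeros_like(dose.values)
    for _ in range(n):
        shift_vox = [
            rng.normal(0.0, s) / sp
            for s, sp in zip(kernel.sigma_mm, dose.geometry.spacing)
        ]
        acc += ndimage.shift(dose.values, shift_vox, order=1, mode="nearest")
    return dose.with_values(np.maximum(acc / n, 0.0))
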