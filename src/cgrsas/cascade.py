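"""Multiplicative deterministic cascade measures and their exact spectra.

A cascade is built by splitting a square into four quadrants carrying
weights (p1, p2, p3, p4) and iterating the split inside every quadrant:
after n iterations the 2^n x 2^n field of cell weights is the n-fold
Kronecker power of the 2x2 weight block.  For these measures the whole
generalized-dimension spectrum is available in closed form,

    D_s = 1/(1-s) * log2( sum_j f_j^s ),   f_j = p_j / sum_i p_i,

with the Shannon-entropy limit at s = 1.  Terms with f_j = 0 are dropped
(0^s diverges for s < 0, and the support of the measure is what scales),
so the s -> +/-inf asymptotes are -log2(max f_j) and -log2(min nonzero f_j).

The seven benchmark weight sets M1..M7 used throughout the package are in
``CASCADE_MODELS``; M4 = (1,1,1,0) is a single-scale Sierpinski gasket and
M7 = (1,1,1,1) the uniform square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .cgr import MeasureGrid
from .multifractal import MultifractalSpectrum

__all__ = [
    "CascadeSpec",
    "CASCADE_MODELS",
    "cascade_field",
    "cascade_weights",
    "analytic_generalized_dimensions",
    "analytic_alpha_asymptotes",
]

#: Benchmark cascade probability sets (p1, p2, p3, p4).
CASCADE_MODELS: dict[str, tuple[float, float, float, float]] = {
    "M1": (1.0, 1.0, 1.0, 0.5),
    "M2": (1.0, 1.0, 0.5, 0.5),
    "M3": (1.0, 0.75, 0.75, 0.75),
    "M4": (1.0, 1.0, 1.0, 0.0),
    "M5": (1.0, 1.0, 0.5, 0.25),
    "M6": (0.5, 1.0, 1.0, 0.25),
    "M7": (1.0, 1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class CascadeSpec:
    """Cell probabilities and iteration count of a deterministic cascade.

    The block placement convention is (p1, p2) in the top row and
    (p3, p4) in the bottom row; all spectra are placement-invariant, only
    the image orientation changes.
    """

    p: tuple[float, float, float, float]
    n: int

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.p)
        object.__setattr__(self, "p", p)
        if len(p) != 4 or any(v < 0 or v > 1 for v in p):
            raise ValueError("need four probabilities in [0, 1]")
        if max(p) <= 0:
            raise ValueError("at least one probability must be positive")
        if self.n < 1:
            raise ValueError("iteration count must be >= 1")

    @property
    def block(self) -> np.ndarray:
        p1, p2, p3, p4 = self.p
        return np.array([[p1, p2], [p3, p4]])


def cascade_field(
    spec: CascadeSpec, normalize: bool = False, max_size: int = 4096
) -> MeasureGrid:
    """The 2^n x 2^n cascade field as the n-fold Kronecker power of the block.

    The raw field sums to (p1+p2+p3+p4)^n; with ``normalize=True`` it is
    rescaled to a probability grid.  ``max_size`` caps the grid edge
    (memory guard: the field is dense).
    """
    size = 2**spec.n
    if size > max_size:
        raise ValueError(
            f"iteration {spec.n} would need a {size}x{size} grid (cap {max_size})"
        )
    # Row 0 of MeasureGrid is the bottom of the square: flip the block so
    # (p1, p2) land in the top row of the rendered image.
    block = spec.block[::-1]
    field = np.array([[1.0]])
    for _ in range(spec.n):
        field = np.kron(field, block)
    grid = MeasureGrid(field, cell_size=1.0, counts=False)
    return grid.normalized() if normalize else grid


def cascade_weights(p) -> np.ndarray:
    """Nonzero normalized weights f_j = p_j / sum(p) of a cascade block."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or p.max() <= 0:
        raise ValueError("probabilities must be nonnegative with a positive sum")
    f = p / p.sum()
    return f[f > 0]


def analytic_generalized_dimensions(p, s_grid) -> MultifractalSpectrum:
    """Closed-form generalized-dimension spectrum of a cascade measure.

    Evaluates D_s over ``s_grid`` (the s = 1 point is filled with the
    entropy limit -sum f_j log2 f_j) and attaches tau(s) = (s-1) D_s.
    """
    f = cascade_weights(p)
    s = np.asarray(s_grid, dtype=float)
    log2f = np.log2(f)
    d = np.empty_like(s)
    at_one = np.isclose(s, 1.0)
    # log2 sum f^s via logsumexp for stability at large |s|
    with np.errstate(divide="ignore"):
        lse = logsumexp(np.outer(s[~at_one], np.log(f)), axis=1) / np.log(2.0)
    d[~at_one] = lse / (1.0 - s[~at_one])
    d[at_one] = -(f * log2f).sum()
    tau = (s - 1.0) * d
    return MultifractalSpectrum(s=s, D=d, tau=tau)


def analytic_alpha_asymptotes(p) -> tuple[float, float]:
    """(alpha_min, alpha_max) = limits of D_s as s -> +inf / -inf.

    These bound the singularity strengths: -log2 of the largest and of the
    smallest *nonzero* weight f_j.
    """
    f = cascade_weights(p)
    return float(-np.log2(f.max())), float(-np.log2(f.min()))
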