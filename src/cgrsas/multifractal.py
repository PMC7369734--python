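"""Box-counting multifractal analysis.

Given a normalized measure on a square grid, the partition function

    Z_s(l) = sum_i p_i(l)^s          (sum over boxes with p_i > 0)

scales as l^{(s-1) D_s} for small box size l.  Generalized dimensions D_s
are estimated as regression slopes of ln Z against ln l over a range of
box sizes obtained by exact block aggregation of the grid (box side must
divide the grid size, so no partial boxes occur).  D_1 uses the entropy
sum  sum_i p_i ln p_i  instead of interpolating across the s = 1 pole.

The singularity spectrum follows by Legendre transform of
tau(s) = (s-1) D_s:  alpha = dtau/ds (finite differences) and
f(alpha) = s*alpha - tau.  D_0 is the box-counting dimension, f(alpha(0))
= D_0, and alpha_max - alpha_min measures heterogeneity (zero for a
monofractal).

`dimension_from_scaling` solves the self-similarity equation
sum_i k_i beta_i^D = 1 for sets made of k_i copies scaled by beta_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import linregress

from .cgr import MeasureGrid

__all__ = [
    "MultifractalSpectrum",
    "BoxCountingConfig",
    "partition_function",
    "aggregate_measure",
    "generalized_dimensions",
    "legendre_spectrum",
    "heterogeneity_width",
    "HeterogeneityWidth",
    "dimension_from_scaling",
]


@dataclass
class MultifractalSpectrum:
    """Generalized dimensions and (optionally) the singularity spectrum.

    Fields
    ------
    s : exponent grid
    D : generalized dimensions D_s
    tau : mass exponents (s-1) D_s
    alpha, f : singularity strengths and f(alpha), filled by
        :func:`legendre_spectrum`
    diagnostics : per-s regression table (fit R^2, number of scales) for
        estimated spectra; None for analytic ones
    """

    s: np.ndarray
    D: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray | None = None
    f: np.ndarray | None = None
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)

    def at(self, s_value: float) -> float:
        """D_s at the grid point closest to ``s_value``."""
        return float(self.D[np.argmin(np.abs(self.s - s_value))])

    def to_tsv(self, path: str | Path) -> None:
        cols = {"s": self.s, "D": self.D, "tau": self.tau}
        if self.alpha is not None:
            cols["alpha"] = self.alpha
            cols["f"] = self.f
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass
class BoxCountingConfig:
    """Scales, exponents and fit range for box-counting estimates.

    ``box_sizes`` are box sides in grid cells (must divide the grid size);
    by default the dyadic chain M, M/2, ..., 4 extended with other
    divisors when the grid size is not a power of two.  The fit drops the
    largest scale (a single box carries no information and the next few
    saturate) and the two smallest (discretization bias), leaving at
    least three scales.  ``min_box_count`` guards s < 0 against boxes hit
    by only a few points when the grid holds counts.
    """

    box_sizes: list[int] | None = None
    s_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-10.0, 10.25, 0.25)
    )
    drop_largest: int = 1
    drop_smallest: int = 2
    min_box_count: int = 1

    def sizes_for(self, grid_size: int) -> list[int]:
        if self.box_sizes is not None:
            bad = [b for b in self.box_sizes if grid_size % b]
            if bad:
                raise ValueError(f"box sizes {bad} do not divide grid size {grid_size}")
            return sorted(set(self.box_sizes), reverse=True)
        # dyadic chain M, M/2, ... while it stays an integer >= 4
        sizes = []
        b = grid_size
        while b >= 4 and grid_size % b == 0:
            sizes.append(b)
            if b % 2:
                break
            b //= 2
        if len(sizes) < 6:
            # non-dyadic grid (e.g. 360): use all divisors >= 4, thinned to
            # at most 10 roughly log-evenly spaced scales
            divisors = [d for d in range(4, grid_size + 1) if grid_size % d == 0]
            if len(divisors) > 10:
                idx = np.unique(
                    np.round(np.linspace(0, len(divisors) - 1, 10)).astype(int)
                )
                divisors = [divisors[i] for i in idx]
            if len(divisors) > len(sizes):
                sizes = sorted(divisors, reverse=True)
        return sizes

    def fit_slice(self, n_sizes: int) -> slice:
        drop_l, drop_s = self.drop_largest, self.drop_smallest
        # relax the drops (smallest-scale first) when few scales exist
        while n_sizes - drop_l - drop_s < 3 and drop_s > 0:
            drop_s -= 1
        while n_sizes - drop_l - drop_s < 3 and drop_l > 0:
            drop_l -= 1
        if n_sizes - drop_l - drop_s < 3:
            raise ValueError(
                f"only {n_sizes} scales available; need >= 3 inside the fit range"
            )
        return slice(drop_l, n_sizes - drop_s)


def aggregate_measure(values: np.ndarray, box_cells: int) -> np.ndarray:
    """Exact block sums of a square array over boxes of ``box_cells`` cells."""
    m = values.shape[0]
    if box_cells < 1 or m % box_cells:
        raise ValueError(f"box side {box_cells} must divide the grid size {m}")
    k = m // box_cells
    return values.reshape(k, box_cells, k, box_cells).sum(axis=(1, 3))


def partition_function(measure: MeasureGrid, s: float, box_cells: int) -> float:
    """Z_s(l) over an aggregation of the measure into boxes of ``box_cells``.

    The measure must be in probability mode (summing to 1); empty boxes
    are excluded for every s.
    """
    if measure.counts:
        raise ValueError("partition_function needs a probability-mode grid")
    p = aggregate_measure(measure.values, box_cells)
    p = p[p > 0]
    return float(np.sum(p**s))


def generalized_dimensions(
    measure: MeasureGrid, config: BoxCountingConfig | None = None
) -> MultifractalSpectrum:
    """Estimate D_s by least-squares fits of ln Z_s(l) versus ln l.

    Accepts a counts grid (normalized internally; ``min_box_count`` then
    filters sparsely-hit boxes) or a probability grid.  Returns the
    spectrum with per-s fit diagnostics attached.
    """
    config = config or BoxCountingConfig()
    sizes = config.sizes_for(measure.size)
    sl = config.fit_slice(len(sizes))
    fit_sizes = sizes[sl]

    s_grid = np.asarray(config.s_grid, dtype=float)
    log_l = np.log([b * measure.cell_size for b in fit_sizes])

    raw = measure.values
    total = raw.sum()
    box_p = []
    for b in fit_sizes:
        agg = aggregate_measure(raw, b)
        occupied = agg > 0
        if measure.counts and config.min_box_count > 1:
            occupied = agg >= config.min_box_count
        box_p.append(agg[occupied] / total)

    d = np.empty_like(s_grid)
    r2 = np.empty_like(s_grid)
    for j, s in enumerate(s_grid):
        if np.isclose(s, 1.0):
            y = np.array([np.sum(p * np.log(p)) for p in box_p])
            res = linregress(log_l, y)
            d[j] = res.slope
        else:
            y = np.array([np.log(np.sum(p**s)) for p in box_p])
            res = linregress(log_l, y)
            d[j] = res.slope / (s - 1.0)
        r2[j] = res.rvalue**2
    tau = (s_grid - 1.0) * d
    diag = pd.DataFrame(
        {"s": s_grid, "r_squared": r2, "n_scales": len(fit_sizes)}
    )
    diag.attrs["box_sizes_cells"] = fit_sizes
    return MultifractalSpectrum(s=s_grid, D=d, tau=tau, diagnostics=diag)


def legendre_spectrum(spectrum: MultifractalSpectrum) -> MultifractalSpectrum:
    """Fill alpha(s) = dtau/ds and f(alpha) = s*alpha - tau.

    alpha uses central finite differences on the s grid (one-sided at the
    endpoints), so the grid must have at least 3 points.
    """
    if spectrum.s.size < 3:
        raise ValueError("need at least 3 s-grid points for finite differences")
    alpha = np.gradient(spectrum.tau, spectrum.s)
    f = spectrum.s * alpha - spectrum.tau
    return MultifractalSpectrum(
        s=spectrum.s,
        D=spectrum.D,
        tau=spectrum.tau,
        alpha=alpha,
        f=f,
        diagnostics=spectrum.diagnostics,
    )


class HeterogeneityWidth(NamedTuple):
    alpha_min: float
    alpha_max: float
    width: float


def heterogeneity_width(spectrum: MultifractalSpectrum) -> HeterogeneityWidth:
    """Extrema of alpha over the evaluated s grid and their difference.

    A width of (numerically) zero marks a homogeneous (mono)fractal.  Note
    the extrema depend on how far the s grid extends; for cascade measures
    the exact asymptotes are available separately
    (:func:`cgrsas.cascade.analytic_alpha_asymptotes`).
    """
    if spectrum.alpha is None:
        raise ValueError("alpha not filled; call legendre_spectrum first")
    lo = float(spectrum.alpha.min())
    hi = float(spectrum.alpha.max())
    return HeterogeneityWidth(lo, hi, hi - lo)


def dimension_from_scaling(k_list, beta_list) -> float:
    """Solve  sum_i k_i beta_i^D = 1  for the similarity dimension D.

    ``k_list`` are copy counts (>= 1) and ``beta_list`` the matching
    scaling factors in (0, 1).  The left side is strictly decreasing in D,
    so the root in [0, 10] is unique; it is bracketed and solved to 1e-10.
    """
    k = np.asarray(np.atleast_1d(k_list), dtype=float)
    beta = np.asarray(np.atleast_1d(beta_list), dtype=float)
    if k.shape != beta.shape:
        raise ValueError("k_list and beta_list must have the same length")
    if (k < 1).any():
        raise ValueError("copy counts must be >= 1")
    if (beta <= 0).any() or (beta >= 1).any():
        raise ValueError("scaling factors must lie in (0, 1)")

    def g(d: float) -> float:
        return float(np.sum(k * beta**d) - 1.0)

    if g(0.0) < 0 or g(10.0) > 0:
        raise ValueError("no root in [0, 10]: inconsistent copy counts / factors")
    return float(brentq(g, 0.0, 10.0, xtol=1e-10, rtol=8.9e-16))
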