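"""Simulated small-angle scattering (SAS) of planar point sets.

The orientationally averaged intensity of N identical point scatterers is
the Debye formula

    I(q) = N + 2 * sum_{i<j} sin(q r_ij) / (q r_ij),

which is evaluated through the pair-distance histogram g(r) so the cost
is O(N^2) once (histogram build, chunked) and O(M_bins) per q value:

    I(q) = N + 2 * sum_i g(r_i) sin(q r_i)/(q r_i).

The 3-D orientational average sin(qr)/(qr) is kept even though the points
are planar: the square is free to rotate in space.  I(0) = N^2 exactly,
and the normalized structure factor S(q) = I(q)/I(0) shows three regimes
for a fractal of overall size l built from features of size l0:

    Guinier    S ~ q^0          for q l  <~ 2*pi
    fractal    S ~ q^-D         for 2*pi <~ q l <~ 2*pi l/l0
    asymptotic S ~ 1/N          for q l0 >~ 2*pi

Deterministic (exactly self-similar) structures additionally modulate the
fractal region log-periodically: the minima of q^D S(q) are equally
spaced on a log-q axis with period log(1/beta), giving the scaling factor
beta and (from the number of minima) the iteration depth.

The real-space counterpart, the pair-distance distribution function
p(r) = g(r)/(sum g * dr), is a probability density over pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .cgr import PointSet2D

__all__ = [
    "PairDistanceHistogram",
    "ScatteringCurve",
    "pair_distance_histogram",
    "debye_intensity",
    "default_q_grid",
    "RegimeBoundaries",
    "detect_regimes",
    "fractal_q_range",
    "direct_debye_intensity",
    "PowerLawFit",
    "fit_power_law_exponent",
    "LogPeriodicity",
    "log_periodicity_analysis",
    "PairDistanceDistribution",
    "pddf",
]


@dataclass
class PairDistanceHistogram:
    """Binned unordered pair distances of a point set.

    ``counts[i]`` is the number of pairs whose distance falls in
    ``[bin_edges[i], bin_edges[i+1])``; the counts sum to N(N-1)/2
    exactly.  Distances are in the same units as the point coordinates.
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        expected = self.n_points * (self.n_points - 1) // 2
        if int(self.counts.sum()) != expected:
            raise ValueError(
                f"histogram holds {int(self.counts.sum())} pairs, expected {expected}"
            )

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def pair_distance_histogram(
    points: PointSet2D, bin_width: float | None = None, chunk: int = 512
) -> PairDistanceHistogram:
    """Histogram all N(N-1)/2 pair distances of a point set.

    The default bin width is edge/1000 (fine enough that the histogram
    route reproduces the direct pair double-sum; see
    :func:`debye_intensity`).  Distances are accumulated in row chunks so
    the full N x N distance matrix is never materialized.
    """
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    if bin_width is None:
        bin_width = points.edge / 1000.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rmax = np.sqrt(2.0) * points.edge
    n_bins = int(np.ceil(rmax / bin_width)) + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    xy = points.xy
    for start in range(0, n - 1, chunk):
        stop = min(start + chunk, n - 1)
        block = cdist(xy[start:stop], xy[start + 1 :])
        # row r holds point start+r, column c holds point start+1+c: the
        # unordered pairs are exactly those with c >= r
        mask = np.arange(block.shape[1])[None, :] >= np.arange(block.shape[0])[:, None]
        d = block[mask]
        idx = np.minimum((d / bin_width).astype(np.int64), n_bins - 1)
        counts += np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return PairDistanceHistogram(counts=counts, bin_edges=edges, n_points=n)


@dataclass
class ScatteringCurve:
    """Debye intensity I(q) and normalized structure factor S = I/I(0)."""

    q: np.ndarray
    intensity: np.ndarray
    n_points: int

    @property
    def structure_factor(self) -> np.ndarray:
        return self.intensity / float(self.n_points) ** 2

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"q": self.q, "I": self.intensity, "S": self.structure_factor}
        ).to_csv(path, sep="\t", index=False)


def debye_intensity(hist: PairDistanceHistogram, q_grid) -> ScatteringCurve:
    """Debye intensity from a pair-distance histogram.

    I(q) = N + 2 sum_i g(r_i) sinc(q r_i) with bin centers r_i and
    sinc(x) = sin(x)/x (=1 at x=0, so I(0) = N^2 exactly).
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("empty q grid")
    if (q < 0).any():
        raise ValueError("q values must be >= 0")
    nz = hist.counts > 0
    r = hist.centers[nz]
    g = hist.counts[nz].astype(float)
    # np.sinc is sin(pi x)/(pi x)
    phase = np.outer(q, r) / np.pi
    intensity = hist.n_points + 2.0 * (np.sinc(phase) @ g)
    return ScatteringCurve(q=q, intensity=intensity, n_points=hist.n_points)


def direct_debye_intensity(points: PointSet2D, q_grid) -> ScatteringCurve:
    """Exact O(N^2) pair double-sum Debye intensity (reference route).

    Intended for validation on small N; the histogram route converges to
    this as the bin width shrinks.
    """
    xy = points.xy
    n = len(points)
    d = cdist(xy, xy)[np.triu_indices(n, k=1)]
    q = np.asarray(q_grid, dtype=float)
    intensity = n + 2.0 * np.sinc(np.outer(q, d) / np.pi).sum(axis=1)
    return ScatteringCurve(q=q, intensity=intensity, n_points=n)


def default_q_grid(l: float, l0: float, n: int = 256) -> np.ndarray:
    """Log-spaced q grid covering all three scattering regimes.

    Spans 0.2*(2*pi/l) (inside the Guinier plateau of a structure of
    overall size ``l``) to 20*(2*pi/l0) (past the crossover set by the
    smallest feature size ``l0``).
    """
    if not 0 < l0 <= l:
        raise ValueError("need 0 < l0 <= l")
    return np.geomspace(0.2 * 2 * np.pi / l, 20.0 * 2 * np.pi / l0, n)


class RegimeBoundaries(NamedTuple):
    q_guinier: float      # Guinier/fractal crossover, ~2*pi/l
    q_asymptotic: float   # fractal/asymptotic crossover, ~2*pi/l0
    plateau: float        # mean S(q) beyond q_asymptotic
    k_estimate: float     # 1/plateau: apparent number of scatterers


def detect_regimes(curve: ScatteringCurve, l: float, l0: float) -> RegimeBoundaries:
    """Locate the three structure-factor regimes of a fractal of size ``l``
    with smallest features ``l0``.

    The crossovers are the geometric conditions q*l = 2*pi and
    q*l0 = 2*pi; the asymptotic plateau is measured as the mean of S(q)
    beyond the second crossover and inverted into the scatterer count
    (S ~ 1/k there).
    """
    q1 = 2.0 * np.pi / l
    q2 = 2.0 * np.pi / l0
    tail = curve.q >= q2
    if not tail.any():
        raise ValueError("q grid does not reach the asymptotic region q >= 2*pi/l0")
    if not (curve.q <= q1).any():
        raise ValueError("q grid does not reach the Guinier region q <= 2*pi/l")
    plateau = float(curve.structure_factor[tail].mean())
    return RegimeBoundaries(q1, q2, plateau, 1.0 / plateau)


def fractal_q_range(
    curve: ScatteringCurve,
    l: float,
    l0: float | None = None,
    plateau_margin: float = 10.0,
) -> tuple[float, float]:
    """Fit interval for the fractal (power-law) region of S(q).

    Starts at the Guinier crossover q = 2*pi/l and stops where S(q) has
    decayed to within ``plateau_margin`` times the finite-N incoherent
    floor 1/N (beyond which the plateau flattens the slope), capped at
    the geometric bound q = 2*pi/l0 when ``l0`` is given.
    """
    q1 = 2.0 * np.pi / l
    floor = plateau_margin / curve.n_points
    q_hi = 2.0 * np.pi / l0 if l0 is not None else float(curve.q.max())
    above = (curve.q > q1) & (curve.structure_factor > floor)
    if above.any():
        q_hi = min(q_hi, float(curve.q[above].max()))
    return q1, q_hi


class PowerLawFit(NamedTuple):
    exponent: float       # D in S ~ q^-D
    stderr: float
    r_squared: float
    n_used: int
    n_excluded: int       # non-positive S values dropped from the log fit


def fit_power_law_exponent(
    curve: ScatteringCurve, q_range: tuple[float, float]
) -> PowerLawFit:
    """Fit S(q) ~ q^-D over ``q_range`` by least squares in log-log space.

    Returns the negated slope with its standard error and R^2.
    Non-positive S values (possible at finite N) are excluded.
    """
    lo, hi = q_range
    s = curve.structure_factor
    sel = (curve.q >= lo) & (curve.q <= hi)
    pos = sel & (s > 0)
    n_excluded = int(sel.sum() - pos.sum())
    if pos.sum() < 5:
        raise ValueError("need at least 5 positive S values inside the fit range")
    res = linregress(np.log(curve.q[pos]), np.log(s[pos]))
    return PowerLawFit(
        exponent=float(-res.slope),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_used=int(pos.sum()),
        n_excluded=n_excluded,
    )


class LogPeriodicity(NamedTuple):
    beta: float           # scaling factor (nan when no significant period)
    n_minima: int         # accepted (pronounced) minima in the window
    minima_q: np.ndarray
    autocorr_peak: float  # height of the accepted autocorrelation peak


def log_periodicity_analysis(
    curve: ScatteringCurve,
    exponent: float,
    q_range: tuple[float, float] | None = None,
    prominence_fraction: float = 0.05,
    smooth_window: int | None = None,
    min_autocorr: float = 0.2,
) -> LogPeriodicity:
    """Extract the scaling factor from the log-periodicity of q^D S(q).

    For a deterministic fractal the compensated curve q^D S(q) oscillates
    periodically in log q with period log(1/beta).  The curve is lightly
    smoothed (Savitzky-Golay on the log-log data, uniform because the q
    grid is log-spaced) and linearly detrended; the period is the lag of
    the highest autocorrelation peak of the residual.  The autocorrelation
    route is used rather than ratios of successive minima because exactly
    self-similar sets interleave a second, shallower dip per period, which
    systematically biases pairwise ratios.  Minima above
    ``prominence_fraction`` of the curve range are still located and
    counted (their number tracks the iteration depth).

    A curve without significant periodicity (autocorrelation peak below
    ``min_autocorr``, or no oscillation at all) returns beta = nan and is
    a valid result, not an error.
    """
    q = curve.q
    s = curve.structure_factor
    sel = np.ones_like(q, dtype=bool) if q_range is None else (
        (q >= q_range[0]) & (q <= q_range[1])
    )
    sel &= s > 0
    q = q[sel]
    if q.size < 8:
        return LogPeriodicity(float("nan"), 0, np.empty(0), 0.0)
    lq = np.log(q)
    y = np.log(q**exponent * s[sel])
    dlq = float(np.mean(np.diff(lq)))
    if smooth_window is None:
        # cover ~0.25 natural-log units, about a third of a beta=1/2 period
        smooth_window = int(np.clip(0.25 / dlq, 5, 51))
    window = min(smooth_window | 1, q.size if q.size % 2 else q.size - 1)
    y_smooth = savgol_filter(y, window_length=window, polyorder=2)

    y_range = float(y_smooth.max() - y_smooth.min())
    if y_range < 1e-9:  # exactly featureless power law
        return LogPeriodicity(float("nan"), 0, np.empty(0), 0.0)
    prominence = prominence_fraction * y_range
    minima, _ = find_peaks(-y_smooth, prominence=prominence)
    q_min = q[minima]

    resid = y_smooth - np.polyval(np.polyfit(lq, y_smooth, 1), lq)
    resid -= resid.mean()
    power = float(np.dot(resid, resid))
    if power < 1e-12:  # featureless power law
        return LogPeriodicity(float("nan"), int(q_min.size), q_min, 0.0)
    ac = np.correlate(resid, resid, "full")[resid.size - 1 :] / power
    lo = max(3, int(0.25 / dlq))          # skip lags inside the smoothing scale
    hi = int(0.7 * ac.size)               # long lags are poorly averaged
    if hi <= lo:
        return LogPeriodicity(float("nan"), int(q_min.size), q_min, 0.0)
    peaks, props = find_peaks(ac[lo:hi], height=min_autocorr)
    if peaks.size == 0:
        return LogPeriodicity(float("nan"), int(q_min.size), q_min, 0.0)
    best = peaks[np.argmax(props["peak_heights"])] + lo
    beta = float(np.exp(-best * dlq))
    return LogPeriodicity(
        beta, int(q_min.size), q_min, float(ac[best])
    )


class PairDistanceDistribution(NamedTuple):
    r: np.ndarray         # bin centers
    p: np.ndarray         # probability density, integrates to 1
    mode: float           # bin center of the maximum of p
    support_max: float    # largest bin center with a nonzero count


def pddf(hist: PairDistanceHistogram) -> PairDistanceDistribution:
    """Pair-distance distribution function p(r) = g(r) / (sum g * dr).

    The density integrates to 1 over the binning; the mode and the
    support endpoint (largest observed distance bin) summarize the
    geometry — for points filling a square of edge l the mode sits near
    0.5 l and the support ends near sqrt(2) l.
    """
    dr = hist.bin_width
    p = hist.counts / (hist.counts.sum() * dr)
    r = hist.centers
    nz = np.nonzero(hist.counts)[0]
    return PairDistanceDistribution(
        r=r,
        p=p,
        mode=float(r[np.argmax(p)]),
        support_max=float(r[nz[-1]]) if nz.size else float("nan"),
    )
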