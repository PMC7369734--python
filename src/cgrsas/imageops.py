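"""Grayscale preprocessing of measure grids: histograms, equalization,
threshold binarization and support extraction.

The imaging convention follows the standard rendering of chaos-game and
cascade figures: *structure is dark*.  Grey level 0 (black) is the
densest cell and level 1 (white) carries no measure, i.e. the level field
is one minus the min-max rescaled measure.  Because most cells of a
cascade carry a tiny fraction of the maximum, the raw level histogram is
concentrated near white — which is why histogram equalization is needed
before thresholding.

Equalization is the standard cumulative-histogram level remapping on
``n_levels`` quantized levels; it is monotone (level ordering preserved,
ties stay tied), spreads the output over the full [0, 1] range, and is
idempotent up to quantization.  Binarization keeps the cells at or below
a grey-level threshold t (the dark cells — the structure), so the
occupied set grows monotonically with t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgr import MeasureGrid, PointSet2D

__all__ = [
    "LevelHistogram",
    "rescale_levels",
    "pixel_histogram",
    "equalize_histogram",
    "binarize",
    "occupied_points",
    "write_png",
    "read_png",
]


def rescale_levels(
    values: np.ndarray, scale: str = "linear", dark_high: bool = True
) -> np.ndarray:
    """Map a nonnegative field to grey levels in [0, 1].

    With ``dark_high`` (default) the largest value maps to level 0
    (black) and zero measure to level 1 (white).  ``scale`` is "linear"
    (min-max) or "log" (decades of the positive values, zeros pinned to
    the empty level).  A constant field maps entirely to the structure
    level.
    """
    v = np.asarray(values, dtype=float)
    if scale == "log":
        pos = v > 0
        out = np.zeros_like(v)
        if pos.any():
            lo, hi = np.log(v[pos].min()), np.log(v[pos].max())
            out[pos] = (np.log(v[pos]) - lo) / (hi - lo) if hi > lo else 1.0
        levels = out
        if not pos.all():
            # zeros sit strictly below every positive level already (0.0)
            pass
    elif scale == "linear":
        lo, hi = v.min(), v.max()
        levels = (v - lo) / (hi - lo) if hi > lo else np.ones_like(v)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return 1.0 - levels if dark_high else levels


@dataclass
class LevelHistogram:
    """Counts of grey levels over ``n_levels`` equal bins of [0, 1]."""

    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def pixel_histogram(
    grid: MeasureGrid, n_levels: int = 256, scale: str = "linear"
) -> LevelHistogram:
    """Histogram of the grey levels of a grid (dark-structure convention).

    Counts sum to the number of cells; a constant grid puts all mass in a
    single bin.  For cascade fields the mass sits near the white end
    before equalization, since cell values span many decades below the
    maximum.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels = rescale_levels(grid.values, scale=scale)
    counts, edges = np.histogram(levels, bins=n_levels, range=(0.0, 1.0))
    return LevelHistogram(counts=counts, bin_edges=edges)


def equalize_histogram(
    grid: MeasureGrid, n_levels: int = 256, scale: str = "linear"
) -> MeasureGrid:
    """Histogram-equalize a grid onto grey levels spanning [0, 1].

    Levels are quantized to ``n_levels``; the cumulative distribution of
    occupied levels is remapped so the output covers the full black-to-
    white range as uniformly as the level multiplicities allow.  The
    remap is monotone, so thresholding the output selects the same cell
    ranking as thresholding the input.  A constant grid is returned
    unchanged (single level).
    """
    levels = rescale_levels(grid.values, scale=scale)
    q = np.minimum((levels * n_levels).astype(int), n_levels - 1)
    hist = np.bincount(q.ravel(), minlength=n_levels)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    total = q.size
    if total == cdf_min:  # single occupied level
        return MeasureGrid(
            np.full_like(levels, levels.flat[0]), cell_size=grid.cell_size, counts=False
        )
    lut = (cdf - cdf_min) / (total - cdf_min)
    return MeasureGrid(lut[q], cell_size=grid.cell_size, counts=False)


def binarize(grid: MeasureGrid, threshold: float, direction: str = "le") -> PointSet2D:
    """Centers of the cells on one side of a grey-level threshold.

    With the default ``direction="le"`` a cell is occupied when its level
    is <= threshold — the dark cells, i.e. the structure under the
    dark-high convention — so the occupied set is non-decreasing in the
    threshold.  ``direction="ge"`` selects the bright side instead.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if direction == "le":
        mask = grid.values <= threshold
    elif direction == "ge":
        mask = grid.values >= threshold
    else:
        raise ValueError("direction must be 'le' or 'ge'")
    return PointSet2D(
        grid.cell_centers(mask).reshape(-1, 2),
        edge=grid.edge,
        label=f"binarized_t{threshold:g}_{direction}",
    )


def occupied_points(grid: MeasureGrid, min_value: float = 0.0) -> PointSet2D:
    """Centers of the cells carrying measure (raw value > ``min_value``).

    This extracts the *support* of a field — e.g. the gasket cells of a
    cascade with a zero probability, or the hit cells of a rasterized
    point set — without any grey-level rescaling.
    """
    mask = grid.values > min_value
    return PointSet2D(
        grid.cell_centers(mask).reshape(-1, 2), edge=grid.edge, label="support"
    )


def write_png(grid: MeasureGrid, path, scale: str = "linear") -> None:
    """Write a grid as an 8-bit grayscale PNG (structure dark).

    Raw measure grids are rescaled with :func:`rescale_levels`; level
    grids (already in [0, 1]) are written as-is.  The image is flipped so
    its first row is the top of the square.
    """
    from PIL import Image

    v = grid.values
    levels = v if (not grid.counts and v.min() >= 0 and v.max() <= 1) else rescale_levels(v, scale)
    img = (levels[::-1] * 255.0).round().astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def read_png(path, cell_size: float = 1.0) -> MeasureGrid:
    """Read an 8-bit grayscale PNG into a level grid with values in [0, 1]."""
    from PIL import Image

    img = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    if img.shape[0] != img.shape[1]:
        raise ValueError("only square images are supported")
    return MeasureGrid(img[::-1], cell_size=cell_size, counts=False)
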