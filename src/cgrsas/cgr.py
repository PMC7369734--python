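"""Chaos-game engine: IFS attractors, CGR of DNA, and rasterization.

Two ways of producing planar point sets live here.  The *random
iteration* chaos game draws one of a set of contractive affine maps at
each step with fixed probabilities and converges to the attractor of the
iterated function system.  The *chaos game representation* (CGR) of a DNA
sequence replaces the random choice by the sequence itself: starting from
the centre of the ACGT square, each base moves the current point half-way
toward that base's vertex, so the point set is in one-to-one
correspondence with the sequence.

Point sets are rasterized onto square counting grids (`MeasureGrid`),
which are the common currency for the multifractal and image-processing
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .seqio import ALPHABET, NucleotideSequence

__all__ = [
    "AffineMap2D",
    "VertexLayout",
    "PointSet2D",
    "MeasureGrid",
    "square_ifs_maps",
    "chaos_game_attractor",
    "cgr_map",
    "rasterize",
]


@dataclass(frozen=True)
class AffineMap2D:
    """Planar affine map w(x, y) = (a x + b y + e, c x + d y + f).

    The chaos games used here require contractions; the canonical
    square-filling maps have a = d = 1/2, b = c = 0 and translations
    placing each copy in one quadrant.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[..., 0], xy[..., 1]
        return np.stack(
            [self.a * x + self.b * y + self.e, self.c * x + self.d * y + self.f],
            axis=-1,
        )

    @property
    def scaling_factor(self) -> float:
        """Operator (spectral) norm of the linear part."""
        m = np.array([[self.a, self.b], [self.c, self.d]])
        return float(np.linalg.norm(m, 2))


def square_ifs_maps(edge: float = 1.0) -> list[AffineMap2D]:
    """The four half-scale maps sending a square of the given edge onto its
    quadrants (bottom-left, top-left, bottom-right, top-right).

    Played with equal probabilities these fill the square uniformly;
    dropping one map yields a Sierpinski-gasket attractor.
    """
    h = edge / 2.0
    return [
        AffineMap2D(0.5, 0, 0, 0.5, 0.0, 0.0),
        AffineMap2D(0.5, 0, 0, 0.5, 0.0, h),
        AffineMap2D(0.5, 0, 0, 0.5, h, 0.0),
        AffineMap2D(0.5, 0, 0, 0.5, h, h),
    ]


@dataclass(frozen=True)
class VertexLayout:
    """Assignment of the four bases to the corners of a square of edge ``l``.

    The default places A at the origin, T bottom-right, G top-right and C
    top-left on a square of edge 1/2 — the convention used throughout for
    DNA CGR figures.  Other CGR conventions (unit square, different corner
    order) can be expressed by constructing a different layout.
    """

    vertices: dict = field(
        default_factory=lambda: {
            "A": (0.0, 0.0),
            "T": (0.5, 0.0),
            "G": (0.5, 0.5),
            "C": (0.0, 0.5),
        }
    )
    edge: float = 0.5

    def __post_init__(self) -> None:
        if set(self.vertices) != set(ALPHABET):
            raise ValueError("layout must map exactly the bases A, C, G, T")
        pts = np.asarray([self.vertices[b] for b in ALPHABET], dtype=float)
        if len({tuple(p) for p in pts}) != 4:
            raise ValueError("layout vertices must be distinct")

    @classmethod
    def unit_square(cls) -> "VertexLayout":
        return cls(
            vertices={
                "A": (0.0, 0.0),
                "T": (1.0, 0.0),
                "G": (1.0, 1.0),
                "C": (0.0, 1.0),
            },
            edge=1.0,
        )

    @property
    def center(self) -> np.ndarray:
        return np.asarray(list(self.vertices.values()), dtype=float).mean(axis=0)


DEFAULT_LAYOUT = VertexLayout()


@dataclass
class PointSet2D:
    """An ordered set of planar points inside a closed axis-aligned square
    ``[0, edge] x [0, edge]``.

    ``xy`` has shape (N, 2), in the same length units as ``edge``.
    """

    xy: np.ndarray
    edge: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (N, 2)")
        eps = 1e-9 * self.edge
        if self.xy.size and (
            self.xy.min() < -eps or self.xy.max() > self.edge + eps
        ):
            raise ValueError("points fall outside the closed square [0, edge]^2")

    def __len__(self) -> int:
        return self.xy.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.xy, delimiter="\t", header="x\ty", comments="")

    @classmethod
    def from_tsv(cls, path: str | Path, edge: float = 1.0, label: str = "") -> "PointSet2D":
        return cls(np.loadtxt(path, delimiter="\t", skiprows=1), edge=edge, label=label)


@dataclass
class MeasureGrid:
    """A square nonnegative field on an M x M partition of a square.

    ``values[0, 0]`` is the bottom-left cell (y-up convention);
    ``cell_size`` is the physical cell edge, so the grid spans a square of
    edge ``M * cell_size``.  ``counts=True`` marks integer hit counts,
    ``counts=False`` a probability (or level) field.
    """

    values: np.ndarray
    cell_size: float = 1.0
    counts: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be a square 2-D array")
        if (self.values < 0).any():
            raise ValueError("measure values must be nonnegative")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def edge(self) -> float:
        return self.size * self.cell_size

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "MeasureGrid":
        """Return the probability-mode grid (values summing to 1)."""
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero grid")
        return MeasureGrid(self.values / tot, cell_size=self.cell_size, counts=False)

    def cell_centers(self, mask: np.ndarray) -> np.ndarray:
        """Coordinates of the centers of the cells selected by a boolean mask."""
        iy, ix = np.nonzero(mask)
        return np.stack(
            [(ix + 0.5) * self.cell_size, (iy + 0.5) * self.cell_size], axis=-1
        )

    def to_text(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t")

    @classmethod
    def from_text(
        cls, path: str | Path, cell_size: float = 1.0, counts: bool = True
    ) -> "MeasureGrid":
        return cls(np.loadtxt(path, delimiter="\t"), cell_size=cell_size, counts=counts)


def chaos_game_attractor(
    maps: list[AffineMap2D],
    probabilities,
    n_points: int,
    seed: int,
    burn_in: int = 100,
    x0=(0.5, 0.5),
    edge: float = 1.0,
) -> PointSet2D:
    """Render an IFS attractor with the random iteration algorithm.

    At each step map ``n`` is applied with probability ``probabilities[n]``;
    the first ``burn_in`` iterates are discarded so the returned points lie
    on the attractor, and exactly ``n_points`` points are returned.
    """
    if not maps:
        raise ValueError("need at least one affine map")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (len(maps),) or (p <= 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    choices = rng.choice(len(maps), size=burn_in + n_points, p=p)
    pts = np.empty((burn_in + n_points, 2))
    x = np.asarray(x0, dtype=float)
    for k, c in enumerate(choices):
        x = maps[c](x)
        pts[k] = x
    return PointSet2D(pts[burn_in:], edge=edge, label="chaos_game")


def cgr_map(
    sequence: NucleotideSequence, layout: VertexLayout = DEFAULT_LAYOUT
) -> PointSet2D:
    """Chaos-game representation of a DNA sequence.

    Starting at the square centre, the point for base k is the midpoint of
    the previous point and the vertex assigned to base k, yielding exactly
    one point per base, in order.  The map is invertible: the sequence of
    quadrants visited recovers the sequence.
    """
    verts = np.array([layout.vertices[b] for b in sequence.bases])
    x0 = layout.center
    # x_k = x_{k-1}/2 + v_k/2 is a first-order linear recursion; run it with
    # an IIR filter per coordinate instead of a Python loop.
    zi = np.array([0.5]) * x0  # filter state carrying x0/2 into the first step
    xs = np.empty_like(verts)
    for dim in range(2):
        xs[:, dim], _ = lfilter([0.5], [1.0, -0.5], verts[:, dim], zi=[zi[dim]])
    return PointSet2D(xs, edge=layout.edge, label=sequence.id)


def rasterize(points: PointSet2D, grid_size: int = 360) -> MeasureGrid:
    """Count points on an M x M partition of the point set's square.

    Cells are half-open ``[i*d, (i+1)*d)``; points exactly on the top or
    right boundary are assigned to the last cell.  Row 0 of the result is
    the bottom of the square.  The total count equals the number of points.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    m = grid_size
    delta = points.edge / m
    idx = np.floor(points.xy / delta).astype(int)
    np.clip(idx, 0, m - 1, out=idx)
    counts = np.zeros((m, m))
    np.add.at(counts, (idx[:, 1], idx[:, 0]), 1.0)
    return MeasureGrid(counts, cell_size=delta, counts=True)
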