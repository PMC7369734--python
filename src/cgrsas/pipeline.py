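"""End-to-end analysis pipelines and benchmark fixture generation.

`run_pipeline` drives one input — a FASTA file, a forbidden-pair model
(TR12/TR13/TR33), a cascade model (M1..M7), a uniform square or a
chaos-game Sierpinski gasket — through the full chain: point set, raster,
box-counting multifractal spectrum, Debye scattering curve, power-law /
log-periodicity analysis and pair-distance distribution, and returns a
bundle with a flat machine-readable summary.  Everything is deterministic
given the seed; every analysis default is an explicit `RunConfig` field
and is echoed into the summary for reproducibility.

`fixture_suite` materializes all benchmark inputs (FASTA sequences, point
TSVs, cascade matrices) into a directory so analyses can be re-run
offline from files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cascade as _cascade
from . import imageops, multifractal, sas, seqio
from .cgr import MeasureGrid, PointSet2D, cgr_map, chaos_game_attractor, rasterize, square_ifs_maps

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "fixture_suite"]

_CASCADE_NAMES = set(_cascade.CASCADE_MODELS)
_TR_NAMES = set(seqio.TR_MODELS)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``source`` is one of: a FASTA path, a TR model name, a cascade model
    name (M1..M7), "uniform" or "sierpinski".  All other fields carry the
    defaults of the standard analysis and are recorded in the summary.
    """

    source: str
    seed: int = 0
    n_points: int = 20_000          # uniform/sierpinski point budget
    sequence_length: int = 80_000   # TR model sequence length
    grid_size: int = 360            # raster resolution for point sources
    cascade_n: int = 6              # cascade iteration count
    threshold: float = 0.4          # binarization threshold for cascades
    equalize_levels: int = 256
    bin_width_fraction: float = 1e-3  # pair-histogram bin width / edge
    s_grid: tuple = (-5.0, 5.0, 0.5)  # (start, stop, step) for D_s
    prominence_fraction: float = 0.05
    out_dir: str | None = None

    def s_values(self) -> np.ndarray:
        start, stop, step = self.s_grid
        return np.arange(start, stop + step / 2, step)


@dataclass
class RunBundle:
    """All artifacts of one pipeline run."""

    config: RunConfig
    points: PointSet2D
    grid: MeasureGrid
    spectrum: multifractal.MultifractalSpectrum
    curve: sas.ScatteringCurve
    distribution: sas.PairDistanceDistribution
    summary: dict


def _build_input(config: RunConfig) -> tuple[PointSet2D, MeasureGrid, float]:
    """Resolve the source into (scattering points, measure grid, l0)."""
    rng_seed = config.seed
    if config.source in _CASCADE_NAMES:
        spec = _cascade.CascadeSpec(
            _cascade.CASCADE_MODELS[config.source], config.cascade_n
        )
        grid = _cascade.cascade_field(spec)
        equalized = imageops.equalize_histogram(grid, config.equalize_levels)
        points = imageops.binarize(equalized, config.threshold)
        return points, grid, grid.cell_size
    if config.source in _TR_NAMES:
        seq = seqio.generate_forbidden_pair_sequence(
            config.sequence_length, seqio.TR_MODELS[config.source], rng_seed,
            id=config.source,
        )
        points = cgr_map(seq)
    elif config.source == "uniform":
        rng = np.random.default_rng(rng_seed)
        points = PointSet2D(rng.random((config.n_points, 2)), edge=1.0, label="uniform")
    elif config.source == "sierpinski":
        maps = square_ifs_maps()[:3]
        points = chaos_game_attractor(
            maps, [1 / 3] * 3, config.n_points, rng_seed
        )
    else:
        path = Path(config.source)
        if not path.exists():
            raise ValueError(
                f"source {config.source!r} is neither a known model nor a file"
            )
        seq = seqio.read_fasta(path)[0]
        points = cgr_map(seq)
    grid = rasterize(points, config.grid_size)
    if config.source in ("uniform", "sierpinski"):
        # scatter the points themselves; the smallest structural scale is
        # the typical nearest-neighbour spacing, not the raster cell
        return points, grid, points.edge / np.sqrt(len(points))
    # sequence sources: scatter the occupied raster cells (fixed-resolution
    # image of the CGR, as for experimental data)
    return imageops.occupied_points(grid), grid, grid.cell_size


def run_pipeline(config: RunConfig) -> RunBundle:
    """Run the full multifractal + scattering analysis for one input.

    Writes point set, grid, spectrum, curve and a JSON summary to
    ``config.out_dir`` when set.  Deterministic given ``config.seed``.
    """
    points, grid, l0 = _build_input(config)
    bc = multifractal.BoxCountingConfig(s_grid=config.s_values())
    spectrum = multifractal.legendre_spectrum(
        multifractal.generalized_dimensions(grid, bc)
    )
    het = multifractal.heterogeneity_width(spectrum)

    edge = points.edge
    hist = sas.pair_distance_histogram(
        points, bin_width=config.bin_width_fraction * edge
    )
    q_grid = sas.default_q_grid(edge, l0)
    curve = sas.debye_intensity(hist, q_grid)
    regimes = sas.detect_regimes(curve, edge, l0)
    fit = sas.fit_power_law_exponent(
        curve, sas.fractal_q_range(curve, edge, l0)
    )
    periodicity = sas.log_periodicity_analysis(
        curve,
        fit.exponent,
        q_range=sas.fractal_q_range(curve, edge, l0, plateau_margin=3.0),
        prominence_fraction=config.prominence_fraction,
    )
    dist = sas.pddf(hist)

    summary = {
        "source": config.source,
        "seed": config.seed,
        "n_scatterers": len(points),
        "D0": spectrum.at(0.0),
        "D1": spectrum.at(1.0),
        "alpha_min": het.alpha_min,
        "alpha_max": het.alpha_max,
        "heterogeneity_width": het.width,
        "scattering_exponent": fit.exponent,
        "scattering_fit_r2": fit.r_squared,
        "plateau_k": regimes.k_estimate,
        "beta": periodicity.beta,
        "n_minima": periodicity.n_minima,
        "pddf_mode_over_l": dist.mode / edge,
        "pddf_support_over_l": dist.support_max / edge,
        "defaults": {
            "grid_size": config.grid_size,
            "cascade_n": config.cascade_n,
            "threshold": config.threshold,
            "equalize_levels": config.equalize_levels,
            "bin_width_fraction": config.bin_width_fraction,
            "prominence_fraction": config.prominence_fraction,
        },
    }
    bundle = RunBundle(config, points, grid, spectrum, curve, dist, summary)
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: RunBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.points.to_tsv(out_dir / "points.tsv")
    bundle.grid.to_text(out_dir / "grid.tsv")
    bundle.spectrum.to_tsv(out_dir / "spectrum.tsv")
    bundle.curve.to_tsv(out_dir / "curve.tsv")
    (out_dir / "summary.json").write_text(
        json.dumps(bundle.summary, indent=2, sort_keys=True) + "\n"
    )


def fixture_suite(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write every benchmark input as plain-text files.

    Produces FASTA files for the TR forbidden-pair models and a uniform
    random sequence, TSV point sets for the uniform square and the
    chaos-game Sierpinski gasket, the Table of cascade probabilities and
    one cascade field matrix per model.  Regeneration with the same seed
    is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for i, (name, pairs) in enumerate(sorted(seqio.TR_MODELS.items())):
        seq = seqio.generate_forbidden_pair_sequence(80_000, pairs, seed + i, id=name)
        path = out / f"{name}.fasta"
        seqio.write_fasta([seq], path)
        written[name] = path
    rand = seqio.generate_random_sequence(80_000, seed + 100, id="random_uniform")
    written["random"] = out / "random_uniform.fasta"
    seqio.write_fasta([rand], written["random"])

    rng = np.random.default_rng(seed + 200)
    uniform = PointSet2D(rng.random((20_000, 2)), edge=1.0, label="uniform")
    written["uniform_points"] = out / "uniform_points.tsv"
    uniform.to_tsv(written["uniform_points"])
    sierpinski = chaos_game_attractor(
        square_ifs_maps()[:3], [1 / 3] * 3, 20_000, seed + 300
    )
    written["sierpinski_points"] = out / "sierpinski_points.tsv"
    sierpinski.to_tsv(written["sierpinski_points"])

    table = out / "cascade_models.tsv"
    with table.open("w") as fh:
        fh.write("model\tp1\tp2\tp3\tp4\n")
        for name, p in _cascade.CASCADE_MODELS.items():
            fh.write(name + "\t" + "\t".join(f"{v:g}" for v in p) + "\n")
    written["cascade_models"] = table
    for name, p in _cascade.CASCADE_MODELS.items():
        grid = _cascade.cascade_field(_cascade.CascadeSpec(p, 6))
        path = out / f"cascade_{name}_n6.tsv"
        grid.to_text(path)
        written[f"cascade_{name}"] = path
    return written
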