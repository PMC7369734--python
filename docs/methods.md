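# Methods

This note records the models implemented in `cgrsas`, the defaults that
matter, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## Chaos-game representation

The ACGT square follows the common genomics convention: edge 1/2 with
A = (0,0), T = (1/2,0), G = (1/2,1/2), C = (0,1/2) (configurable via
`VertexLayout`, e.g. a unit square). The walk starts at the square
centre and the first plotted point corresponds to the first base; no
points are discarded, so the map is one-to-one (`cgr_map` ↔ the
quadrant sequence). The recursion xₖ = (xₖ₋₁ + v(bₖ))/2 runs through a
first-order IIR filter, which is exact and fast. Random-iteration IFS
attractors (`chaos_game_attractor`) default to a 100-step burn-in so the
returned points lie on the attractor.

Rasterization uses half-open cells with the top/right boundary folded
into the last cell and row 0 at the *bottom* of the square (y-up); the
default resolution is 360, the working figure resolution for genome
CGRs.

## Sequence generators

`generate_random_sequence` draws i.i.d. uniform bases.
`generate_forbidden_pair_sequence` is a first-order Markov chain,
uniform over the successors not banned by the forbidden set — the
minimal-assumption reading of "random sequence that never contains XY".
Construction guarantees zero forbidden dinucleotides. A forbidden set
must leave every base at least one successor, checked at construction.
Non-ACGT symbols in FASTA input are removed (not an error) with the
removal count logged; the CGR is only defined on the four bases.

## Cascades and the closed-form spectrum

`cascade_field` is the n-fold Kronecker power of the 2×2 block
[[p1,p2],[p3,p4]] (block placement is a rendering convention only; all
spectra are placement-invariant). The exact spectrum

  Dₛ = log₂(Σⱼ fⱼˢ)/(1−s),  fⱼ = pⱼ/Σᵢpᵢ,

drops fⱼ = 0 terms (0ˢ diverges for s < 0 and only the support scales),
is evaluated by log-sum-exp for stability at large |s|, and fills s = 1
with the entropy limit −Σ fⱼ log₂ fⱼ instead of a numerical 0/0. The
s → ±∞ asymptotes −log₂(max fⱼ) and −log₂(min fⱼ) are reported exactly
by `analytic_alpha_asymptotes`; finite s-grids approach them only as
O(1/s), so grid extrema are always reported separately from asymptotes.

## Box counting

Box sizes are block aggregations whose side divides the grid size —
block sums are exact, no partial boxes. For power-of-two grids this is
the dyadic chain M, M/2, …, 4; for other sizes (e.g. 360) up to ten
divisors, roughly log-evenly spaced. The regression over ln Z vs ln l
drops the largest scale (a single box carries no information) and the
two smallest (discretization bias), relaxing those drops only when few
scales exist. Empty boxes are excluded for every s; for counts grids a
configurable minimum occupancy additionally guards s < 0 against
sparsely hit boxes. D₁ uses the entropy-sum regression. On cascade
fields the dyadic aggregation reproduces the lower-iteration cascade
exactly, so the estimate matches the closed form to machine precision —
a strong self-check, but *not* evidence about estimator bias on point
rasters, where finite sampling enters.

α(s) = dτ/ds uses central finite differences (one-sided at the ends);
f = sα − τ. `dimension_from_scaling` brackets Σ kᵢβᵢᴰ = 1 on [0, 10]
and solves with Brent to 1e−10 (the left side is strictly decreasing in
D, so the root is unique).

## Grey levels, equalization, thresholds

Structure is rendered dark: grey level = 1 − minmax(measure), so the
densest cell is black and empty cells are white. This matches the usual
rendering of CGR/cascade figures and makes "keep cells ≤ t" select the
*structure*. Because cascade cell values are products of probabilities
spanning decades, nearly all mass sits near white before equalization —
the reason equalization is required at all. Equalization is the standard
cumulative-histogram remap on 256 quantized levels (128/512 change the
fitted scattering exponent by < 0.1, tested); it is monotone and
idempotent up to quantization. For a cascade with a zero probability
(M4) every interior threshold recovers exactly the 3ⁿ support cells.

## Scattering

The Debye sum is evaluated through the pair-distance histogram
(default bin width l/1000, validated against the direct O(N²) double
sum to < 1% where the binning resolves the phase, q·Δr ≲ 1). The 3-D
orientational average sin(qr)/(qr) is used although points are planar
(the square may rotate in space); contrast and volume prefactors are set
to 1 and curves reported as S(q) = I(q)/I(0), with I(0) = N² exact.
The default q grid covers 0.2·(2π/l) to 20·(2π/l₀) with 256 log-spaced
points.

**Fractal-region fit.** The geometric upper bound q = 2π/l₀ lies beyond
the finite-N incoherent floor S ≈ 1/N for desk-scale point sets, and
including the plateau crossover biases the slope down (a uniform square
fits at 1.48 with the literal bound, 1.97 with the adaptive one). The
fit window therefore stops where S decays to 10× the 1/N floor
(`fractal_q_range`), capped at 2π/l₀.

**Log-periodicity.** The compensated curve qᴰS(q) of an exactly
self-similar set has *two* dips per period — a pronounced minimum and a
shallow harmonic — so ratios of successive minima systematically
overestimate the period (β ≈ 0.42–0.44 instead of 0.5 on gasket
benchmarks). β is instead the lag of the highest autocorrelation peak of
the linearly detrended, lightly smoothed log-log residual, computed over
the fractal window extended to a 3× plateau margin (the oscillations
persist into the crossover). A peak below height 0.2 means no
significant periodicity: β = NaN is a valid result (uniform and
featureless controls return it). Minima are still located and counted
with a 5%-of-range prominence; their number grows by one per cascade
iteration and estimates the iteration depth. Measured on benchmarks:
β = 0.468/0.486/0.494 for the binarized M4 cascade at n = 5/6/7, 0.50
for 2·10⁴ chaos-game gasket points, NaN for uniform points.

The pddf p(r) = g(r)/(Σg·Δr) integrates to 1 by construction; its mode
and last occupied bin are reported. For uniform points in a square these
land at r/l ≈ 0.49 and ≈ 1.41 (diagonal √2), in line with the exact
square line-picking density.

## Pipeline and fixtures

`run_pipeline` resolves one source — FASTA path, TR model, cascade
model, uniform or Sierpinski — into points + grid, then runs box
counting, scattering, periodicity and pddf with every default recorded
in the summary. Sequence sources are scattered as the occupied cells of
their 360² raster (the fixed-resolution image of the CGR); uniform and
gasket clouds are scattered directly, with the smallest structural scale
taken as the nearest-neighbour spacing l/√N. Everything is deterministic
given the seed; `fixture_suite` writes all benchmarks as plain-text
FASTA/TSV, byte-identical under regeneration.

## What the benchmarks do not establish

* The synthetic generators state ideal worlds: i.i.d. or first-order
  Markov sequences, exactly self-similar cascades. Real genomes mix
  regimes, so a green benchmark says the estimators work on clean
  scaling, not that any particular genome is fractal.
* Finite iteration matters. The binarized M5 exponent measures
  1.76–1.83 at n = 6–8 against an n → ∞ value of 2: the thresholded set
  holds ~40% of 4ⁿ cells, whose coarse-count dimension log k / log 2ⁿ
  approaches 2 only slowly, and a uniform control at matched N and
  window still reads 1.89–1.93. Published values at n = 11 imply ~1.7M
  scatterers, beyond an O(N²) pair histogram at desk scale. We report
  the honestly measured exponent rather than extrapolating.
* Box-counting α extrema depend on the s-grid and fit range (exposed in
  the per-s diagnostics); only the analytic asymptotes of cascades are
  grid-free.
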