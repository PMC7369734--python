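"""Three scattering regimes of a binarized multiplicative cascade.

Builds the M5 cascade at 7 iterations, equalizes its grey-level
histogram, keeps the dark (dense) cells below threshold 0.4, and
computes the Debye structure factor of the occupied cell centers.
S(q) is flat in the Guinier region (q l < 2*pi), decays as q^-D in the
fractal region, and plateaus at 1/k at high q — so the curve encodes the
overall size l, the mass-fractal dimension D and the number of
scatterers k.
"""

import cgrsas as c

grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M5"], 7))
points = c.binarize(c.equalize_histogram(grid), threshold=0.4)
l, l0 = points.edge, grid.cell_size

hist = c.pair_distance_histogram(points, bin_width=l / 1000)
curve = c.debye_intensity(hist, c.default_q_grid(l, l0))
regimes = c.detect_regimes(curve, l, l0)
fit = c.fit_power_law_exponent(curve, c.fractal_q_range(curve, l, l0))

print(f"occupied cells k = {len(points)} of {grid.size**2}")
print(f"Guinier/fractal crossover  q1 = 2*pi/l  = {regimes.q_guinier:.4f}")
print(f"fractal/asymptotic bound   q2 = 2*pi/l0 = {regimes.q_asymptotic:.4f}")
print(f"fractal-region exponent D = {fit.exponent:.3f}  (R^2 = {fit.r_squared:.4f})")
print(f"high-q plateau = {regimes.plateau:.3e}  ->  k = {regimes.k_estimate:.0f}")
print(
    "\nThe plateau inverts to the occupied-cell count within a few percent.\n"
    "The exponent sits below its infinite-iteration limit 2 because at 7\n"
    "iterations the thresholded set spans barely over a decade of scales."
)
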