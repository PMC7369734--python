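"""Reading the scaling factor of a deterministic fractal off its
scattering curve.

The M4 cascade (probabilities 1,1,1,0) is a single-scale Sierpinski
gasket: each iteration shrinks the structure by beta = 1/2.  That makes
the compensated curve q^D S(q) log-periodic with period log(1/beta), so
the scaling factor can be recovered from the scattering data alone, and
the number of pronounced minima tracks the iteration depth.
"""

import cgrsas as c

for n in (5, 6, 7):
    grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M4"], n))
    points = c.binarize(c.equalize_histogram(grid), 0.4)
    l, l0 = points.edge, grid.cell_size
    hist = c.pair_distance_histogram(points, bin_width=l / 1000)
    curve = c.debye_intensity(hist, c.default_q_grid(l, l0))
    fit = c.fit_power_law_exponent(curve, c.fractal_q_range(curve, l, l0))
    lp = c.log_periodicity_analysis(
        curve,
        fit.exponent,
        q_range=c.fractal_q_range(curve, l, l0, plateau_margin=3.0),
    )
    print(
        f"n={n}: k={len(points):4d} cells  D={fit.exponent:.3f}  "
        f"beta={lp.beta:.3f}  pronounced minima={lp.n_minima}"
    )

print(
    "\nbeta ~ 0.5 recovers the construction scale of the gasket (and of the\n"
    "CGR half-distance rule when applied to DNA); the minima count grows\n"
    "by one per added iteration."
)
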