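"""Pair-distance distribution of points filling a square.

Draws 2e4 uniform points in a unit square, histograms all ~2e8 pair
distances and normalizes to the probability density p(r).  The geometry
of the square fixes the two landmarks: the most common distance is about
half the edge, and no pair is farther apart than the diagonal sqrt(2).
CGR point clouds of real genomes follow this same envelope, with small
deterministic wriggles superimposed.
"""

import numpy as np

import cgrsas as c

rng = np.random.default_rng(0)
points = c.PointSet2D(rng.random((20_000, 2)), edge=1.0, label="uniform")
hist = c.pair_distance_histogram(points, bin_width=1 / 200)
dist = c.pddf(hist)

print(f"points N = {len(points)},  pairs = {hist.counts.sum():,}")
print(f"pddf integrates to {np.sum(dist.p) * hist.bin_width:.6f}")
print(f"mode of p(r):        r/l = {dist.mode:.3f}   (expected ~0.5)")
print(f"support endpoint:    r/l = {dist.support_max:.3f}   (diagonal sqrt(2) ~ 1.414)")
print(
    "\np(r) is the real-space fingerprint of the point set; deviations from\n"
    "this uniform-square envelope reveal ordered structure in a CGR."
)
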