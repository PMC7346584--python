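"""Projected-radius laws of the flattened-sphere null model.

A signal at 3D radius rho in a randomly oriented nucleus projects to a
planar radius r <= rho.  This script simulates the three placement laws
and compares each Monte Carlo sample with its closed-form CDF.
"""

import numpy as np

from nucleotopo import nullmodel as nm

rng = np.random.default_rng(0)

for name, model in [
    ("surface (envelope)", nm.PlacementModel.surface()),
    ("ball (whole nucleus)", nm.PlacementModel.ball()),
    ("shell 0.40-0.70 (relocated loci)", nm.PlacementModel.shell(0.4, 0.7)),
]:
    r = nm.simulate_projected_r(model, 100_000, rng)
    xs = np.sort(r)
    f = np.asarray(nm.closed_form_cdf(model, np.clip(xs, 0, 1)))
    i = np.arange(1, xs.size + 1)
    gap = max((i / xs.size - f).max(), (f - (i - 1) / xs.size).max())
    print(f"{name:34s} median r = {np.median(r):.4f}   "
          f"P(r > 0.75) = {(r > 0.75).mean():.4f}   ECDF-vs-CDF sup gap = {gap:.4f}")

print()
print("Surface placement concentrates signals near the projected rim:")
print("median sqrt(3)/2 = 0.8660, mean pi/4 = 0.7854, P(r>0.75) = 0.6614.")
print("The sup gaps (~0.003 at n=1e5) show the simulation and the")
print("closed forms describe the same law.")
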