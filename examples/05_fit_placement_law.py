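"""Infer the 3D placement law from observed 2D radii.

Given only projected radii (what a 2D FISH experiment measures), the
shell fit inverts the projection: a grid search over shell bounds
(ain, aout) minimizes the KS distance between the observed ECDF and the
closed-form projected-radius CDF.
"""

import numpy as np

from nucleotopo import nullmodel as nm

rng = np.random.default_rng(3)

for label, truth in [
    ("envelope-bound (resting cells)", nm.PlacementModel.surface()),
    ("relocated to shell 0.40-0.50", nm.PlacementModel.shell(0.40, 0.50)),
    ("central ball 0.5 (nucleolus-like)", nm.PlacementModel.ball(0.5)),
]:
    observed = nm.simulate_projected_r(truth, 2000, rng)
    fit = nm.fit_placement(observed)
    ain, aout = fit.model.bounds
    print(f"{label:36s} fitted shell = ({ain:.2f}, {aout:.2f}), "
          f"KS distance = {fit.ks_distance:.3f}")
print()
print("Bounds are recovered to within the 0.05 grid refinement; the KS")
print("distance is the residual mismatch at n=2000 observations.")
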