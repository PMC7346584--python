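"""Control vs activated: the full comparison pipeline.

Generates two 60-nucleus populations (resting cells with envelope-bound
signals; activated cells whose small signals relocated inward), runs
segmentation + measurement + the nonparametric comparisons, and prints
the radial-shift and size-disproportionation statistics.
"""

import json
from pathlib import Path

import pandas as pd

from nucleotopo.pipeline import run_pipeline

config = {
    "seed": 11,
    "stages": ["generate", "segment", "measure", "compare", "report"],
    "populations": {
        "control": {"condition": "control",
                    "overrides": {"n_nuclei": 60, "noise_sigma": 8.0}},
        "activated": {"condition": "activated",
                      "overrides": {"n_nuclei": 60, "noise_sigma": 8.0}},
    },
    "compare": {"a": "control", "b": "activated"},
    "report": {"model_curve": "surface"},
}
out = run_pipeline(config, Path("scratch/example_compare"))

comp = pd.read_csv(out / "comparison.csv")
r_row = comp[comp.metric == "r"].iloc[0]
print(f"radial shift (r): D = {r_row.D:.3f}, KS sig = {r_row.ks_sig:.2e}, "
      f"U p = {r_row.p:.2e}")
print(f"  median r: control {r_row.median_a:.3f} -> activated {r_row.median_b:.3f}")

splits = json.loads((out / "fraction_split.json").read_text())["splits"]
for grp, name in (("a", "control"), ("b", "activated")):
    s = splits[grp]
    lo, hi = s["ratio_ci"]
    print(f"{name:10s} median-area ratio S(r>0.75)/S(r<0.75) = "
          f"{s['median_ratio']:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print("Activated cells: small signals moved inward, so the interior group")
print("is small-area and the ratio rises above 1; the control ratio is ~1.")
print(f"Figures and tables in {out}/")
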