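# nucleotopo

Radial-position analysis of FISH and AgNOR signals in 2D images of
interphase nuclei — for cell biologists who ask *where* a locus or a
nucleolus sits in the nucleus and whether that position changes between
conditions (resting vs irradiated/stimulated cells, patient vs control
populations).

The motivating biology: large heterochromatin domains (e.g. the 1q12
pericentromeric block, probed by FISH) sit at the nuclear envelope in
resting lymphocytes and move toward the interior under stress, while
nucleoli (silver-stained AgNORs) enlarge and move outward — and only
*small* loci relocate.  Detecting this from flat 2D images needs three
pieces, which this package provides end to end:

1. **Measurement.**  A nucleus mask is fitted as a circle (equivalent
   radius `R = sqrt(Sn/pi)`) or a moment-equivalent ellipse
   (`a >= b`, orientation `theta`).  Each signal blob yields its
   normalized radius vector

   `r = |p - c| / R`  (circle)    `r = sqrt((x'/a)^2 + (y'/b)^2)`  (ellipse)

   running from 0 (center) to 1 (envelope), its area fraction
   `S_norm = S / Sn`, the homolog pair's normalized distance `d` and
   central angle `alpha`, AgNOR copy number and total area, and the
   FISH-to-nucleolus surface distance.

2. **Null model.**  A flattened-sphere projection model: signals placed
   on the surface, in a volume-uniform ball, or in a shell
   `(a_in, a_out)` of a randomly oriented, Z-compressed unit sphere are
   orthogonally projected.  The projected radius has closed-form CDFs —
   surface `F(x) = 1 - sqrt(1 - x^2)` (median `sqrt(3)/2 ~ 0.866`),
   ball `F(x) = 1 - (1 - x^2)^{3/2}` — and a grid KS-fit inverts the
   projection to recover the 3D shell from observed 2D radii.

3. **Statistics.**  Pooled per-signal distributions are compared with
   the two-sample Kolmogorov-Smirnov statistic (exact sup `D`,
   asymptotic significance) and the Mann-Whitney U test (exact for
   small tie-free samples), significant at p < 0.01; the `r = 0.75`
   split with the `median S(r>0.75)/median S(r<0.75)` ratio (bootstrap
   95% CI) captures size-dependent relocation.

Because this kind of microscopy data is rarely shareable, the package
ships a first-class synthetic generator: rendered nucleus crops with
exact ground truth (true geometry, centroids, pixel areas, 3D placement
radii), with `control`/`activated` condition presets.  Every stage of
the pipeline is validated against that truth.

## Worked example

`examples/04_compare_conditions.py` renders 60 control and 60 activated
nuclei (noise sigma 8), segments and measures them, and compares the
populations:

```
radial shift (r): D = 0.617, KS sig = 6.17e-21, U p = 8.92e-20
  median r: control 0.805 -> activated 0.499
control    median-area ratio S(r>0.75)/S(r<0.75) = 1.12 (95% CI 0.81-1.51)
activated  median-area ratio S(r>0.75)/S(r<0.75) = 1.56 (95% CI 1.45-1.72)
```

Reading: control signals are peripheral (median r 0.805, tracking the
surface-placement law); in activated cells the median drops to 0.499
and the KS/U tests reject emphatically.  The control area ratio is
compatible with 1 (size and position independent), while the activated
ratio rises above 1 because only small-area signals moved inward.

The other examples show the null-model curves and constants
(`01_null_model_curves.py`), ground-truth generation
(`02_generate_population.py`), single-image measurement
(`03_measure_single_image.py`), and placement-law inference — e.g. 2000
projected radii from a shell (0.40, 0.50) are fitted back to
(0.39, 0.50) (`05_fit_placement_law.py`).

A thin CLI wraps the same stages:

```
nucleotopo generate --condition control --n-nuclei 50 --seed 1 --outdir out/control
nucleotopo simulate-null --law surface --n 100000 --seed 1 --outdir out/null
nucleotopo run --config pipeline.json --outdir out/run
```

## Library layout

| module            | contents                                              |
|-------------------|-------------------------------------------------------|
| `synthetic_nuclei`| population specs, condition presets, renderer, truth  |
| `segmentation`    | nucleus masks, blob detection, AgNOR counting         |
| `geometry`        | circle/ellipse fits, `r`, `d`, `alpha`, distances     |
| `nullmodel`       | placement laws, projection MC, closed-form CDFs, fits |
| `popstats`        | KS/U comparisons, fraction split, median-ratio CI     |
| `pipeline`/`cli`  | file-contract pipeline, manifests, figures            |

See `docs/methods.md` for models, conventions, numerical choices and
limitations.

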