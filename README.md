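# ki67calib

Accuracy validation, calibration and measurement-error correction of Ki67
labelling-index (LI) estimation by automated digital image analysis (DIA),
benchmarked against stereological counting-frame reference counts — all
exercised end-to-end on synthetic tissue-microarray (TMA) spot images with
exact per-cell ground truth.

## Who this is for

Quantitative-pathology and bio-image-analysis developers who need to answer:
*how accurate is my automated Ki67 read-out, and how do I fix the bias it
has?*  The Ki67 LI — the percentage of tumour cell nuclear profiles positive
for the Ki67 proliferation marker,

    LI = 100 · P / (P + N),

drives clinically relevant decisions through cutoffs at 10, 15 and 20 %, so
automated read-outs must be validated against a criterion standard, not just
against pathologists' impressions.  The package implements that methodology
with every ingredient testable:

1. **Synthetic spots** (`ki67calib.synthetic`) — 1-mm TMA cores at
   0.5 µm/px with DAB-brown positive and hematoxylin-blue negative tumour
   nuclei, controllable true LI, cellularity, nucleus overlap, stromal and
   lymphocytic admixture, and seeded bit-identical reproducibility.
2. **Stereology reference arm** (`ki67calib.stereology`) — a lattice of
   counting frames (size *b* = 125 px, spacing *a* = 250 px) with
   forbidden-line counting rules.  Sampling uncertainty follows the
   coefficient of error

       CE = t · sqrt(Cg · m / n²),

   with *n* frames inside the tumour, *m* external sides of that frame set,
   grid factor Cg = 0.049 for b/a = ½ and Student factor t = 2, yielding a
   per-spot 95 % interval LI·(1 ± CE).
3. **DIA stand-in** (`ki67calib.dia`) — an open nuclear-detection pipeline
   with the full commercial settings surface (smoothing radius, intensity
   window, declumping curvature, size and shape filters, weak/moderate/
   strong staining bins) plus three bundled calibration profiles
   `DIA_0`/`DIA_1`/`DIA_2` and an automated settings-calibration search.
4. **Method comparison** (`ki67calib.method_comparison`) — OLS and
   PCA-orthogonal regression, confidence ellipses and the *accuracy factor*
   (regression-line tilt over ellipse-axis tilt), Bland–Altman limits,
   one-way ANOVA with Duncan multiple-range letters, Pearson matrices.
5. **Error correction** (`ki67calib.correction`) — inverse regression
   (reference on measurement), optionally restricted to references < 40 %,
   and dichotomization misclassification reports at clinical cutoffs.
6. **Pipeline + CLI** (`ki67calib.pipeline`, `ki67calib` console command) —
   the whole experiment from a JSON/YAML config, one spot per simulated
   case, fully deterministic given a seed.

## Worked example

```python
import ki67calib as k

spec = k.SpotSpec(true_li_percent=30.0, seed=42)   # 1-mm spot, 2000 cells/mm²
spot = k.generate_spot(spec)
print(len(spot.truth), spot.true_li_percent)        # 1272 cells, 26.81 %

grid = k.build_grid((spec.image_size_px,) * 2, frame_size_px=125, spacing_px=250)
ref = k.grid_count(spot, grid)
# 79+/235- profiles over n=48 frames (m=32): LI 25.16 %, CE 0.052,
# 95 % CI (23.8, 26.5)

res = k.run_dia(spot, k.DIA_1)
# 1220 nuclei, LI 28.93 %

model = k.fit_inverse_regression(
    *k.default_bias_simulation()[["measurement", "reference"]].to_numpy().T)
# slope 1.2082, intercept -4.7344
k.apply_correction(model, 30.1)                     # 31.63 %
```

Reading the numbers: the requested LI of 30 % is realized binomially as
26.81 % over this spot's 1272 tumour cells; the counting-frame subsample
estimates 25.16 % with a CE-based interval of ±5 %, and the visually tuned
DIA profile reads 28.93 % — a small positive bias of the kind the
inverse-regression correction is built to remove (last two lines: a
correction model fitted on the packaged bias simulation, applied to a raw
measurement of 30.1 %).

Or run the whole experiment from the shell:

```sh
ki67calib run-all results/ --seed 42 --n-spots 24
ki67calib report results/
```

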