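# rodmap

Quantitative morphometry of **rod microglia** in whole-mount retinal
fluorescence images.

After optic nerve injury, retinal microglia at the ganglion-cell layer
activate into an elongated "rod" phenotype whose hallmark is mutual
alignment: neighbouring rod cells share a common axis. Judging that
alignment by eye is subjective; `rodmap` replaces it with a reproducible
measurement pipeline for Iba1-stained whole-mount confocal frames:

1. **Preprocess** — convert 8/16-bit TIFF/PNG frames to floats, collapse
   RGB to grayscale, compress dynamic range with a log transform
   `v ↦ log(1 + κv)` (κ = 1000), normalise to [0, 1].
2. **Segment** — Otsu's threshold *T* (between-class variance maximised
   over a 256-bin histogram) and the binary mask *S* = (*I* > *T*).
3. **Detect cells** — 8-connected components; small components flagged as
   noise, ragged ones (solidity < 0.5, i.e. overlapping cells) excluded.
4. **Measure area** — a weighted count over all 2×2 windows of the padded
   mask (weights 0, ¼, ½, ¾, ⅞, 1 by window pattern), which corrects the
   staircase bias of raw pixel counting; a solid m×n rectangle scores
   exactly m·n.
5. **Fit ellipses** — each cell is approximated by an ellipse
   (a, b, X_c, Y_c, φ) maximising |E ∩ CC| − |E Δ CC|, starting from
   image moments; the major-axis angle φ ∈ [0°, 180°) is the cell
   orientation. A minimum-covering-ellipse mode is also available.
6. **Analyse angles** — 1°-bin histograms over [0°, 180°), averages over
   the 7–8 images of a timepoint, a Rayleigh test on doubled angles
   (axial data) with mean resultant length R̄ and p-value, and a 2-D FFT
   log-magnitude view of the frame.

Because no annotated confocal data ship with the package, a synthetic
scene generator renders ground-truth cells (rotated ellipses with a
raised-cosine edge, Poisson + Gaussian noise on a 16-bit range) so every
stage is validated by parameter recovery.

## Worked example

```python
from rodmap.simulate import SceneSpec, generate_scene
from rodmap.pipeline import analyze_frame
from rodmap.analysis import axial_uniformity

spec = SceneSpec(n_cells=40, angle_model="vonmises", vonmises_mu_deg=60.0,
                 vonmises_kappa=8.0, seed=7)      # aligned rods around 60 deg
img, truth = generate_scene(spec)                 # 512x512 uint16 frame
res = analyze_frame(img)

print("Otsu threshold:", round(res.segmentation.threshold, 4))
kept = res.table[res.table.status == "kept"]
r_bar, p, axis = axial_uniformity(kept["phi_deg"].tolist())
print(f"R_bar={r_bar:.3f}  p={p:.2e}  mean_axis={axis:.1f} deg")
```

Output:

```
Otsu threshold: 0.6953
R_bar=0.939  p=8.36e-15  mean_axis=62.0 deg
```

All 40 rendered cells are detected and kept (first table rows:
`id=1, pixel_count=173, weighted_area=177.38, a=15.91, b=3.52,
phi_deg=49.44`, …). The Rayleigh test on doubled angles firmly rejects
uniformity (p ≈ 10⁻¹⁴) and recovers the common axis at 62° versus the
60° used to generate the scene — the quantitative signature of an
aligned rod-microglia population. A scene generated with
`angle_model="uniform"` instead yields a small R̄ and a non-significant
p, the signature of resting/amoeboid populations.

## Command line

Each stage is also a subcommand, chained through plain files:

```sh
rodmap simulate --spec spec.json --out scene.tif --truth truth.csv
rodmap preprocess scene.tif --out enhanced.png --kappa 1000
rodmap segment scene.tif --out mask.png            # [--threshold 0.1]
rodmap measure mask.png --out cells.csv            # [--fit-mode cover]
rodmap histogram cells.csv --out hist.csv --summary summary.json
rodmap fftview scene.tif --out spectrum.png
```

`cells.csv` has one row per component (including noise/overlap-flagged
ones) with pixel counts, weighted areas, solidity, status, and the
fitted ellipse parameters; `summary.json` carries pooled area statistics
and the axial-uniformity result.

## Documentation

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and known limitations (including what the synthetic scenes do
and do not emulate).
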