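# Methods

## Scope and model

`rodmap` measures the spatial signature of rod microglia — elongated,
mutually aligned cells appearing in the retinal ganglion-cell layer after
optic nerve injury — from whole-mount fluorescence frames. Each cell is
modelled as a bright, roughly elliptical region on a dark background; the
pipeline estimates, per cell, a sub-pixel area and an axial orientation,
and per image (or group of images from one timepoint) an orientation
histogram and a test of axial alignment.

## Preprocessing

Integer frames (uint8/uint16, 1 or 3 channels) are scaled by
`1/(2^depth − 1)`. RGB frames are collapsed with the full-precision NTSC
luma weights (0.298936…, 0.587043…, 0.114021…, summing to exactly 1), so
a gray pixel is a fixed point of the collapse. Dynamic-range compression
uses `v ↦ log(1 + κv)` with default **κ = 1000**, followed by a min-max
rescale to [0, 1]. A plain logarithm on a [0, 1] image diverges at 0; the
`log1p` form reproduces the same rank-preserving compression while being
defined everywhere. κ controls how hard dim structure is boosted: κ = 1000
maps typical dark-background levels (~1% of full scale) to roughly 45% of
the output range. Constant images normalise to all-zeros by convention
(min-max rescale is otherwise undefined); callers are expected to skip
such frames.

## Segmentation

Otsu's threshold is computed on a **256-bin** uniform histogram of [0, 1];
candidate thresholds are the interior bin edges, a cut at edge k assigns
bins 0..k−1 to background, and ties go to the smallest qualifying edge.
Foreground is the strict comparison `value > T`, making T = 1 an empty
mask and foreground monotonically shrinking in T. The implementation is
exact with respect to an exhaustive within-class-variance scan (tested),
and agrees with `skimage.filters.threshold_otsu` to within one bin.

Two practical properties of Otsu's criterion matter for interpretation:

- Between two well-separated narrow modes the between-class variance is
  nearly flat, so on small samples the selected edge wanders within the
  inter-mode gap. On 128×128 bimodal frames (modes 0.2/0.8, σ = 0.08) the
  threshold separates the modes beyond ±3σ in 500/500 seeded replicates;
  on much smaller frames the hit rate drops into the ~95% range. This is
  a property of the criterion, not of the implementation.
- Thresholding happens in whatever intensity domain the image is in. After
  log enhancement, the midpoint between background and cell modes in the
  *compressed* domain corresponds to ≈14% of the *linear* cell intensity,
  so masks extend ~0.4 px beyond the half-intensity boundary of a cell
  with a smooth edge. See "Area estimation" below.

A fixed threshold can be supplied instead (`--threshold`), which supports
sensitivity studies around the automatically selected value.

## Cell detection

Connected components use **8-connectivity** by default (edge and corner
neighbours; 4-connectivity is available for comparison) and are labelled
in raster order of their first pixel. Nothing is deleted: components with
fewer than **min_pixels = 20** pixels are flagged `noise` (the cutoff is a
configurable convention — there is no principled size below which a
detection cannot be a cell), and components whose **solidity**
(pixel count / convex-hull pixel count) falls below **0.5** are flagged
`overlap_excluded`. Low solidity is an automated, auditable proxy for
manual curation of overlapping cells: crossing rods form concave unions
with solidity well below any single convex soma (an X of two rods measures
≈0.48 versus ≈0.94 for one rod). Merged cells are excluded, not split;
no watershed or concavity-cut machinery is included. Explicit IDs can
also be excluded manually (`--interactive-exclude`).

## Area estimation

The area of a component is the sum of pattern weights over all 2×2
windows of its mask padded by one background pixel on every side:
0, 1/4, 1/2 (two edge-adjacent), 3/4 (two diagonal), 7/8, 1 by the number
and arrangement of foreground pixels. The padding gives each boundary
pixel its full four windows, making the measure translation-invariant and
additive over components separated by ≥2 background pixels; a solid m×n
rectangle scores exactly m·n and a single pixel 1.0. The estimator
matches a brute-force window enumeration exactly on random masks.

Measured on synthetic scenes, weighted areas track true ellipse pixel
counts within ~2.6% on average when segmentation runs in the linear
intensity domain, but overshoot by ~16% under default log enhancement —
the log-domain Otsu cut lands low on the 1.5 px edge ramp and dilates
every mask by ~0.4 px of perimeter. Users comparing absolute areas across
conditions should either hold the enhancement fixed (the bias is
systematic and cancels in relative comparisons) or segment with
`--no-log`; orientation and count estimates are unaffected.

## Ellipse fitting and orientation

Every kept component CC is approximated by a 5-parameter ellipse
(a, b, X_c, Y_c, φ) maximising

    objective(E, CC) = |E ∩ CC| − |E Δ CC|,

which rewards overlap and penalises missed and spurious area
symmetrically; its maximum |CC| is attained only at E = CC. The fit
starts from image moments — centroid, φ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂), axes
2√λ from the covariance eigenvalues (a solid ellipse has variance a²/4
along its major axis) — and is refined by Nelder-Mead simplex search
(max 400 iterations, 10⁻³ tolerance, deterministic, no randomness) on the
component's padded bounding box. The returned score never falls below the
initialiser's, and optimizer failure falls back to the initialiser with
`converged=False` rather than aborting a batch.

The pixel-centre covariance is regularised by +1/12 per axis (the
variance of a unit square), which removes the thinning bias for 2–3 px
wide rods and keeps collinear pixel runs well-posed (a 1×k run gets
φ = 0 exactly). Components with fewer than 3 pixels are unfittable and
recorded as such.

**Angle convention.** φ is measured counterclockwise from the +x (column)
axis with y pointing *up* (the vertical offset of row r from the centre
is Y_c − r), matching the region-orientation convention of common image
analysis platforms; row-down rasters flip the sign of naive angles. All
orientations are folded into [0°, 180°) — axial data, where θ and θ+180°
are the same axis — and an isotropic region (a = b) reports 0° by
convention. Only this folded range is emitted; representations using
negative degrees are avoided as their sign convention is ambiguous.

An alternative `cover` mode returns the minimum-area ellipse enclosing
the component's pixel centres (Khachiyan's algorithm on the convex hull,
semi-axes inflated by half a pixel to cover pixel extents). For ragged
cells the covering ellipse and the overlap-optimal ellipse genuinely
disagree — the covering ellipse is driven entirely by extremal pixels —
so the overlap criterion is the default and `cover` is offered for
comparison.

Recovery, measured on 200 rasterised rods (a ∈ [10, 40], a/b ∈ [3, 8],
random φ): mean absolute angle error ≈ 0.15° and mean relative axis
errors ≈ 1%, comfortably inside the 2° / 5% acceptance bands.

## Angle analysis

Histograms use 180 half-open 1° bins [k, k+1) over [0°, 180°); "0 to 180"
taken literally would need a 181st edge, but 180° is the same axis as 0°
and is folded there. Counts sum to the number of kept cells. Timepoint
aggregation averages *counts* (not frequencies) elementwise across the
images of a timepoint, so the averaged histogram sums to the mean cell
count; `--normalize` emits frequencies instead. Pooled area statistics
use linearly interpolated quartiles.

Alignment is tested with the **Rayleigh test on doubled angles** (the
standard treatment of axial data): R̄ is the mean resultant length of
{2θ}, the p-value uses the standard large-sample series approximation
(cross-checked against `pingouin.circ_rayleigh`), and the mean axis is
half the circular mean of the doubled angles. Calibration on seeded
simulations: uniform samples keep p > 0.05 in ≈94% of replicates, and
axially concentrated samples (von Mises κ = 8 on doubled angles, n = 100)
are detected in 200/200 replicates.

The spectral view is the centred `log(1+|F|)` of the 2-D FFT, min-max
rescaled; populations of aligned rods concentrate off-centre energy along
the axis perpendicular to the rod orientation.

## Synthetic scenes

The generator emulates green-channel confocal frames: solid rotated
ellipses (peak 20 000 DN) on a dark background (800 DN) with Poisson shot
noise and Gaussian read noise (σ = 300 DN) on the 16-bit range — SNR
(peak − background)/σ = 64 at defaults, adjustable downward. Defaults:
512×512 frames (2048×2048 supported), 60 cells with semi-major axes
10–20 px and semi-minor 2.5–5 px, centres ≥45 px apart by rejection
sampling, orientations uniform or axial von Mises (sampled on 2θ and
halved). Cell edges fall off over a **1.5 px raised-cosine ramp** so that
a threshold at half intensity recovers the true pixel mask to sub-pixel
accuracy (`hard_edges` disables the ramp). Everything is reproducible
from a single integer seed.

What the scenes do *not* emulate: ramified processes and soma-plus-branch
morphologies, intensity heterogeneity within a cell, staining gradients
and vignetting, out-of-focus light, and genuinely overlapping cells.
Passing recovery tests therefore demonstrates correctness of the
measurement chain on well-separated elliptical somata — the quantity the
pipeline is designed to measure — not robustness to every artefact of
real immunofluorescence data; on real frames the noise filter, solidity
exclusion and manual-exclusion escape hatch carry that weight.

## Test problem sizes

The shipped suite validates: the six pattern-weight values exactly;
weighted areas against brute-force enumeration on 100 random 32×32 masks;
Otsu against an exhaustive scan on 200 random 16×16 images and mode
separation on 500 bimodal 128×128 frames; ellipse recovery on 200 rods;
and the full pipeline on 20 seeded 512×512 scenes of 60 cells each
(10 uniform, 10 aligned at κ = 8) — exact count recovery, angle MAE
≤ 2°, area recovery ≤ 6% (linear segmentation), and alignment detection
in every aligned scene.

## Known limitations

- Merged cells are excluded rather than split; dense fields bias counts
  and the kept-cell area distribution toward isolated cells.
- Absolute areas depend on the enhancement domain (see "Area
  estimation"); comparisons should fix the preprocessing.
- The Otsu threshold is global per image; no local/adaptive thresholding.
- Orientation is the only shape descriptor fitted; no skeletons, process
  counts or ramification indices.
- The Rayleigh test detects unimodal axial concentration; multi-modal
  orientation fields (two crossing alignment axes) can score as uniform.
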