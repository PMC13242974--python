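# Methods

## Measurement model

An air jet of gauge pressure `p` through a nozzle of bore diameter `D`
(default 2 mm) loads the skin with force `F = p · π (D/2)²`; the contact
area is taken as the nozzle bore area. The area enters only as a
multiplicative constant, so a calibrated jet footprint can be substituted by
adjusting the nozzle diameter. The protocol is 5 s baseline, 5 s loading,
5 s recovery at 10 fps. Typical proportional valves on such rigs regulate
0–0.5 MPa; the package default is 150 kPa (F ≈ 0.47 N), and all examples
that use small rasters run at 80 kPa so the softest test phantom's dent
fits the image depth.

Displacement Δd is the maximum tracked depth during the on-window minus the
mean depth over the pre-window (the mean, rather than a single initial
frame, suppresses baseline noise). The tracked landmark is, by default, the
centroid of stratum-corneum (SC) mask pixels within the central 10% of
image columns — the sub-pixel centroid averages out raster quantization —
with the band's minimum row (`top_boundary`) as an alternative. The maximum
over the on-window is taken raw; an optional 3-frame running median guards
against single-frame outliers, and the test suite bounds the max-of-window
noise bias empirically (≈2.2 noise SDs for a 50-frame plateau). Δd is
floored at 0, and K = F/Δd is refused (not returned as infinity) when
Δd ≤ 0. The axial depth convention everywhere: row 0 is shallowest, depth
grows with row index, indentation increases depth.

## Phantom generator

The phantom emulates the features of the real data that the downstream
algorithms rely on:

- a layered reflectance profile — dark air gap, bright SC band (default mean
  reflectance 0.85), two dimmer deeper layers (0.45, 0.30);
- multiplicative unit-mean gamma speckle with std/mean 0.35 (shape
  1/contrast², drawn independently per frame);
- exponential depth attenuation (0.8 mm⁻¹ below the tissue surface);
- deformation: the whole layer stack translates downward by
  `w(t) · exp(−x²/2σ²)` with σ = 0.8 mm laterally, where `w(t)` is zero in
  the pre-window, a 0.5 s smoothstep ramp to a plateau of `Δd_max = F/K_true`
  in the on-window, and a symmetric release in the post-window. The
  smoothstep avoids single-frame discontinuities at 10 fps.

Because the dent amplitude is constructed as `F/K_true`, ground truth is
exact up to raster quantization: the rasterised SC boundary sits within one
axial pixel of the analytic waveform, and the truth displacement equals
`F/K_true` up to the lateral envelope at the tracked column (a half-pixel
off exact centre for even widths, a relative effect of ~2·10⁻⁵).

What the phantom does **not** model: physically rigorous light transport
(no Monte-Carlo photon simulation), viscoelastic creep (the plateau is
static), surface curvature, motion artifacts, shadowing, or correlated
speckle decorrelation under strain. Passing tests therefore demonstrate
that the algorithmic chain is correct and quantization-limited, not that
the trained network transfers to human OCT appearance.

Default raster is 512×512 at 7.5 µm axial / 10 µm lateral pitch (the native
device raster is 997×997 and is supported). Tests and the acceptance script
use 96×96 at 15 µm axial pitch — a deliberate desk-scale choice: it keeps
the physical scene (SC at ~0.3 mm depth, dents of 0.1–0.5 mm) inside the
1.44 mm depth budget while training in minutes on one CPU.

## Segmentation

The U-Net is implemented directly in NumPy (`octstiff.nn`): 3×3 'same'
convolutions via im2col, ReLU, 2×2 max pooling, nearest-neighbour
upsampling, skip concatenations, a 1×1 sigmoid head, hand-written backward
passes validated against finite differences, and Adam. Defaults: depth 4,
base 16 channels (8 in the desk-scale runs), combined BCE + soft-Dice loss,
learning rate 1e-3, batch 8, up to 50 epochs with early stopping
(patience 10) on validation loss; the best-validation checkpoint is
returned. Mask threshold 0.5, with ties broken to background so an
all-zero-weight model yields an empty (deterministic, conservative) mask.

Splits are patient-level: patients are shuffled with the split seed and
assigned greedily to the subset with the largest remaining item-count
deficit, so no subject's frames leak across subsets; with single-item
patients the subset sizes equal the largest-remainder rounding of the
ratios exactly (700 items at 60/20/20 → 420/140/140). The validation subset
drives checkpoint selection; the test subset is used only for reported
metrics. Evaluation macro-averages pixel accuracy, Dice and IoU over
images; "accuracy" is pixel accuracy (the natural reading for a binary
mask, though with a thin foreground class it is dominated by background and
should be read alongside Dice/IoU).

## Statistics

All estimators are coded from their closed forms; scipy supplies only the
t- and F-distributions. ANOVA uses the classical between/within
decomposition; Fisher's LSD applies pairwise t-tests with the pooled ANOVA
error term and deliberately no multiplicity correction (that is the
definition of LSD; a Holm option would be a different procedure and is not
emulated). The t-test is pooled-variance by default (Welch is available via
`scipy` directly if wanted). The ICC is the consistency-type two-way mixed
model — ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E) and its Spearman–Brown
step-up ICC(3,k) — with 95% CIs from F-distribution bounds; the six
(status × location) conditions play the role of the k raters, and an
absolute-agreement form is available behind a flag. Cohen's d is the
pooled-SD independent-groups form with the normal-approximation CI
`d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`, plus a pooled-t CI for the
mean difference. Degenerate inputs (zero pooled variance with unequal
means, zero-variance correlation inputs, missing ICC cells) raise rather
than return sentinel values.

### Synthetic cohort generator

`synthetic_stiffness_table` simulates the repeated-measures design: the
same `n = 14` subjects measured in all six conditions, with a subject
random intercept (SD 0.25 N/mm) shared across conditions plus condition
noise (SD 0.25 N/mm). Condition means default to wound skin stiffer than
normal and post-treatment skin, with the location contrast confined to
wound status (upper/lower: normal 0.90/0.95, wound 1.45/2.05, after
0.95/0.95 N/mm). These magnitudes were fixed once by a power analysis of
the independent-groups tests actually applied to the table: each true
contrast carries ≥97% power at n = 14 while the null contrasts stay at or
below nominal α (the shared subject intercept makes between-condition
tests conservative), so the qualitative significance signature reproduces
in ≳93% of generator seeds. The reference device reads the same latent
stiffness scaled to N/m (×450) with instrument noise, giving the strong
cross-device Pearson correlations expected of two probes of one quantity.

## Problem sizes and numerical choices

- Acceptance run: 200 frames (50 phantoms × 4 time points) at 96×96,
  depth-4 / base-8 U-Net, 12 epochs — ~3 min on one CPU.
- Stiffness recovery sweep: K_true ∈ {0.5, 1.0, 1.5, 2.0, 2.5} N/mm at
  80 kPa; with truth masks the median relative error is quantization-bound
  (≤5%); with trained masks ≤20%, and the recovered ordering is monotone.
- Training is bit-reproducible for a fixed seed (NumPy RNG for
  initialisation and shuffling; no threading nondeterminism in the update
  path on a given BLAS).
- Series I/O quantizes frames to 8/16-bit on write; a save/load round trip
  is exact after the first quantization.
- float32 forward/backward for speed; losses accumulated in float64; the
  gradient check runs the engine in float64.

## Known limitations

- The NumPy engine is CPU-only and desk-scale; it is not intended for
  997×997 training runs.
- Phantom realism limits transfer claims (see above): reported Dice/IoU on
  phantoms are upper bounds on what identical settings would achieve on
  human OCT.
- The vendor's raw "time-bin" format is not parsed; TIFF/PNG + JSON sidecar
  is the interchange format, and pixel pitch is carried as metadata without
  reconciling nominal optical resolution against crop geometry.
- Stiffness is structural (geometry-inclusive), deliberately not a Young's
  modulus; no viscoelastic parameters are estimated.
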