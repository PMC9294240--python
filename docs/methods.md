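# Methods

`ezseg` re-implements a hybrid deep-learning pipeline for segmenting
the outer retinal layers in spectral-domain OCT (SD-OCT) scans of
retinitis pigmentosa, and the downstream ellipsoid-zone (EZ) and
photoreceptor outer-segment (OS) metrics used to track disease. All
clinical datasets behind the original method are private, so the
package ships a synthetic phantom generator with exact ground truth and
exercises the whole method end to end on phantoms.

## The segmentation model

Two convolutional networks cooperate:

**U-Net.** A 4-stage encoder / 4-stage decoder with a bridge, 5x5
kernels, 8 initial feature channels doubling per stage
(8-16-32-64, bridge 128), "same" zero padding, and batch
normalization between convolution and ReLU in the encoder only. Input
patches are 256x32 (height x width); output is a per-pixel score over 5
classes: background (0), ILM-dINL (1), dINL-EZ (2), EZ-pRPE (3),
pRPE-BM (4). Where the EZ band is absent the class-2 region extends
down to pRPE. Whole B-scans are segmented by tiling: 256x32 windows at
horizontal stride 16 (50% overlap; stride 128 vertically when the scan
is taller than 256), mirror padding to tile multiples, softmax scores
averaged over overlaps, argmax with ties resolved toward the lower
class index.

**Sliding-window (SW) classifier.** 3 convolutions (32, 32, 64
channels, 5x5 kernels, batch norm before each ReLU), 3 max poolings, 2
fully connected layers (64 then 6) with a ReLU between them — 4 ReLUs
in total — and a softmax over 6 classes: centre pixel on the ILM, dINL,
EZ, pRPE or BM boundary line (1..5) or background (0). Input is a
33x33 patch; borders are mirror-reflected.

**Hybrid post-processing.** From each U-Net label map, single-pixel
boundary lines are read off: ILM = top pixel of class 1, dINL = top of
class 2 (top of class 3 where class 2 is absent), EZ = top of class 3
(undefined where absent), pRPE = top of class 4, BM = bottom of class
4 (BM is included in class 4). With fragmented runs the topmost run
decides; BM is the bottom of the topmost class-4 run. Lines are
checked for breaks: *gaps* (undefined columns strictly inside the
defined extent) and *jumps* (adjacent-column steps larger than
`max_jump`, default 5 px). For breaks on ILM/dINL/pRPE/BM, the SW model
re-scores pixels within +-15 rows of the linear interpolation across
the break; per column the row with the highest probability for the
line's class is accepted when that probability reaches 0.5, otherwise
the interpolated row is used, and ordering violations are clipped.
The EZ line is deliberately exempt from gap repair: it legitimately
ends at the transition zone, and disconnected EZ fragments would need
rules beyond this model (config-gated, off by default). These
break/repair thresholds have no published values; they are
conservative defaults and all config-exposed.

An optional confirm/eliminate pass (`HybridConfig.ez_confirm`, off by
default) re-classifies the pixel on every column's claimed EZ row with
the SW model and drops the column's EZ when the SW probability of the
EZ class falls below the same `p_min` used for repairs. Semantic
models at modest training scales produce two systematic false-EZ
artifacts in EZ-free columns — 1-2-pixel "slivers" where the decoder
interpolates the ordered class sequence across the dINL-pRPE
interface, and few-pixel tails flanking a true band's transition zone
— and the confirmation pass removes both by checking the image
evidence at the claimed row. The scaled-down study enables it; it
costs one SW sweep per B-scan.

At volume level, the EZ presence map (one row per B-scan line) is
cleaned of likely segmentation errors: 8-connected components whose
physical area is below 0.5 mm^2 AND whose centroid lies more than
1.5 mm from the scan centre are removed; the component containing (or
nearest to) the centre is always kept. "Small" and "off-centre" are
not quantified in the source method; these two thresholds are declared
substitutes and config-exposed.

## Training recipe

Batch size 128; up to 45 epochs; initial learning rate 0.01 (U-Net) or
0.05 (SW); learning rate divided by 10 every 10 epochs; random initial
weights. Choices the recipe leaves open, fixed here: SGD with momentum
0.9, unweighted cross-entropy (per pixel for the U-Net, per patch for
the SW model), fan-scaled uniform (Glorot) initialization, no batch
norm in the U-Net decoder. Because the scaled-down studies run only a
few optimizer steps per epoch, exponential-moving-average batch-norm
statistics lag badly; before each validation pass the norm layers'
statistics are therefore re-estimated as population statistics over
(up to 256) training patches, the convention of the MATLAB-era
framework this recipe originates from. `TrainConfig.stop_at_val_accuracy`
optionally ends training early once a validation target is reached,
always within the 45-epoch schedule; `stop_min_class_recall`
additionally requires every class to reach a recall floor before
stopping, because overall pixel accuracy can exceed 95% while the
thin EZ-pRPE band (a few percent of pixels) is still entirely missed.
`TrainConfig.class_weights="balanced"` enables inverse-frequency class
weighting of the loss; the default is the plain unweighted
cross-entropy, which converged faster in practice.

Patch extraction follows the published scheme: U-Net patches on a
4-pixel horizontal stride (32-wide patches overlapping by 28 px), one
baseline patch per position plus one patch vertically centred on each
defined boundary line at the patch's centre column. The baseline
vertical placement (midpoint of ILM and BM) is this package's choice —
the source states only the boundary-centred augmentation. SW patches
sit on every defined boundary pixel plus `bg_per_column` (default 2)
background pixels sampled uniformly per column outside a 1-px guard
band around the boundaries. Patches are split 80/20 at patch level, so
one scan can contribute to both halves.

## The phantom generator

Phantoms emulate Spectralis-like high-resolution macular volumes: a
9-mm field, 121 B-scan lines (default), 1536 columns x 496 rows per
B-scan (defaults), 0.0039 mm axial pixel pitch. Five boundary surfaces
are built as the ILM height field plus strictly positive layer
thicknesses, each modulated by bounded low-order cosine terms in
(line, column) — ordering therefore holds by construction, and with
`surface_mod = 0` the surfaces are exactly flat. The EZ band exists
only inside an elliptical footprint on the fundus plane (semi-axes a, b
in mm; analytic area pi*a*b); outside it the EZ surface is removed and
the dINL region extends to pRPE, imitating a transition zone. Regions
get distinct mean reflectances; speckle is a Gamma-distributed
multiplicative field (mean 1, standard deviation `noise_level`) plus an
additive Gaussian floor, clipped to [0, 1]. Intensity statistics of
real Spectralis scans are not published, so contrast levels are free
parameters, not calibrated to the device.

What the phantoms do *not* model: cystoid macular edema, outer retinal
tubulation, drusen, vessel shadows, motion/registration artifacts,
depth-dependent signal roll-off, or EZ bands that taper gradually
rather than truncate. Passing end-to-end tests on phantoms therefore
demonstrates that the pipeline machinery (patching, training, tiling,
boundary logic, area metrics, statistics) is correct under the stated
geometry and noise model — not that the trained networks would reach
clinical accuracy on real RP scans.

## Metrics

OS thickness per column is `(pRPE - EZ) * z_res` millimetres (0 where
EZ is absent). Per-line thickness rows are linearly interpolated along
the slow axis onto an isotropic fundus grid (y spacing defaults to the
lateral pixel pitch, config-exposed, since the device's infrared-fundus
y resolution is metadata this package cannot know). EZ area is the
presence-pixel count times the single-pixel area `x_res * y_res`; OS
volume is the thickness sum times pixel area; mean OS thickness is
taken over presence pixels or the whole grid.

Where the EZ band ends between a measurable and a non-measurable line,
the default `presence_rule="midpoint"` places the edge halfway between
them (interpolated presence indicator >= 0.5). The alternative
`"support"` rule counts any strictly positive interpolated thickness,
which systematically extends the band by up to one line spacing per
edge (several percent of area at 121-line sampling); it is kept as an
option because "measurable OS" could be read either way, but the
midpoint rule is the unbiased estimator of a truncated band's edge and
is what the oracle-equivalence tests (area within 2% of the analytic
footprint) require. Dice comparisons of EZ presence operate on the
(n_lines x n_cols) line-grid maps; areas use the dense grid.

## Agreement statistics

Pearson r with a Fisher-z 95% CI; ordinary least squares y-on-x with
t-based 95% CIs (df = n-2); R^2 = r^2; Bland-Altman of differences
taken model-minus-reference: mean, sample SD (n-1), SE = SD/sqrt(n),
coefficient of repeatability CoR = 1.96*SD, limits of agreement =
mean -+ CoR, and mean absolute error. Dice of two binary maps is
2|A∩B|/(|A|+|B|); two empty maps raise an error rather than returning a
convention value, forcing callers to handle absent-EZ scans explicitly.

The fixed-shift model predicts the Dice coefficient of two equal-size
circles of area A whose centres are d apart: with r = sqrt(A/pi), the
lens-shaped intersection is `2 r^2 arccos(d/2r) - (d/2) sqrt(4r^2 - d^2)`
and DSC = intersection / (pi r^2); 1 at d = 0, 0 for d >= 2r. The
shift is parameterised in millimetres: the source quotes both 50 and
55 pixels for the same 0.315 mm, and the implied pixel pitch matches
neither scan format, so mm is the primary unit. EZ size subgroups
follow the ETDRS-derived cuts: < 1 mm^2 very small, [1, 7) small,
[7, 30) medium, >= 30 mm^2 large.

## Scaled-down study sizes

The end-to-end study (`ezseg.study`) runs the full method at sizes
chosen for a single CPU: 512-column, 256-row B-scans; 11-line volumes
over the 9-mm field; 32 low-noise (`noise_level = 0.05`) training
B-scans drawn from phantoms with extended EZ footprints (transition
zones crossing most sampled lines — under-representation of extended
EZ is this method's known failure mode, so the emphasis is
deliberate); 640 U-Net patches kept by a stratified subsample (one
third containing the EZ band, one third straddling a transition zone,
the rest uniform) and 2048 SW patches; a 13-epoch training budget
(within the 45-epoch schedule) stopping once validation accuracy
reaches 95% with every region class at >=80% recall; non-overlapping
inference tiles and the SW confirm/eliminate pass enabled; and 10
held-out test volumes with footprint areas spanning 2-36 mm^2,
centred so the ellipse stays inside the field and the analytic area
is the in-field truth. Agreement between hybrid-measured and analytic
EZ areas is summarised by r, the regression slope, and the mean
difference as a percentage of the mean area. One seeded run of the
study (training to the stop rule plus segmentation of all test
volumes) takes roughly fifteen minutes of CPU time, dominated by
network training; the acceptance checks therefore evaluate a single
seeded run end-to-end, and other seeds can be probed by rerunning
with a different seed.

## Numerical notes

The networks run on a compact numpy engine (`ezseg.nn`): NHWC float32
activations; convolution as a numba-jitted im2col gather feeding one
large BLAS matrix product per batch slice, with a jitted scatter-add
for the input gradient and shared scratch buffers to avoid allocation
churn. All randomness flows through explicit seeded generators —
identical seeds give bit-identical phantoms, initial weights, batch
orders and therefore models. Max pooling breaks ties toward the first
element; stitching argmax breaks score ties toward the lower class
index; `fixed_shift_dsc` returns exactly 1.0 at d = 0 and 0.0 at
d >= 2r rather than relying on floating-point arccos at the endpoints.

## Known limitations

* Phantom realism as above; no claim of clinical performance.
* The repair rules for jumps re-place only the far side of the step;
  which side of a jump is wrong is genuinely ambiguous without the
  unpublished original rules.
* The SW model's confirm/eliminate role for small central EZ islands
  (reported as not working well in the source) is config-gated off.
* EZ-band tail errors at the transition zone are not re-examined,
  matching the source's stated behaviour.
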