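# Methods

`deepvnc` implements a two-stage framework for synthesizing non-contrast brain
CT from a contrast-enhanced dual-energy acquisition: a physics-informed
intensity lookup that reproduces a vendor-style virtual non-contrast (VNC)
decomposition, followed by a residual convolutional network that predicts the
remaining difference to a true non-contrast (TNC) scan. This note describes
the models, the synthetic data they are validated on, the numerical choices,
and what the tests do and do not demonstrate.

## Three-material decomposition (the S-VNC stand-in)

Clinical dual-energy workstations produce VNC images with a proprietary
decomposition. The package implements the textbook image-domain form it is
built on: each pixel p = (HU_low, HU_high) is expressed as

    p = w + a (b − w) + c d,

where w and b are the spectral coordinates of the two base materials (water,
defaulting to the origin, and hemorrhage, defaulting to (68, 62) HU — blood
attenuates slightly more at low energy) and d = (r, 1) is the iodine
direction with ratio r = 2.12, iodine's low-energy enhancement per unit of
high-energy enhancement under the 80/150Sn brain protocol. Solving the 2×2
system gives the iodine image c (in HU of high-energy enhancement) and the
VNC point q = w + a(b − w); the scalar VNC value is μ q_low + (1−μ) q_high
with μ = 0.5. The vendor's scalar blend is not published; μ is configuration.

Two exact properties follow from linearity and are enforced by tests:
iodine invariance (adding any enhancement along d leaves VNC unchanged) and
linearity of the decomposition in the input pair.

## Synthetic phantom cohort

No public DECT stroke cohort exists, so every stage is validated on a
generated one. Each "patient" is one 2-D slice: an elliptical brain section
(semi-axes 30–42 % of the image size, giving mask fractions of roughly
0.28–0.55) partitioned into CSF (10 %), white and gray matter by
thresholding a smooth Gaussian random field, with optional elliptical
hemorrhagic lesions (probability 0.6, up to two per slice) and a smooth
non-negative iodine map over ~40 % of the brain (peak concentration 1.0
unit = 25 HU of high-energy enhancement). Class means are CSF 8, white 25,
gray 38, hemorrhage 65 HU — standard adult brain values.

The dual-energy forward model places unenhanced tissues **on the
water–hemorrhage spectral line** of the decomposition basis: a tissue with
non-contrast value B maps to (B·68/65, B·62/65). This is the minimal model
under which the three-material decomposition is exact — noiseless zero-tilt
simulation followed by decomposition returns the TNC image to machine
precision, which closes the physics loop end to end. On top of the line
model, each class can carry a spectral *tilt* (a small (low, high) HU offset,
≤ 3 HU in the default presets) representing departures from the two-material
mixture assumption, and each energy channel receives independent Gaussian HU
noise (σ_low 3, σ_high 2 for "80/150Sn"; 2.4/1.8 for "100/150Sn" — the
low-kVp channel of a dual-source scanner is noisier). Noise levels are
typical of soft-tissue brain CT. Beam hardening, correlated CT noise
textures, 3-D anatomy and projection-domain effects are out of scope.

Anatomy-dependent decomposition error — the reason a learned correction
helps at all — is injected by choosing tilts along the hemorrhage-line
direction, tilt = (bias/65)·(68, 62), so the decomposed VNC is shifted by
exactly `bias` HU for that class while the iodine image is untouched. The
default bias set (CSF +4, white −8, gray +10, hemorrhage −15 HU) gives
class-dependent offsets up to 15 HU.

Scenes (= patients) are assigned to train/validation/test partitions at the
subject level (largest-remainder apportionment of the 74.5/14.5/11.0 %
fractions, every partition non-empty), so no patient's slices cross
partitions.

## The physics lookup

Every brain-mask pixel of the training partition contributes its decomposed
VNC value to the 2-D cell containing its (low, high) pair; cells hold the
mean of their contributions. Bins are 1 HU square over [−200, 400] HU per
axis (the brain-plus-contrast range after skull stripping); the bin width is
a configuration choice — the published raster is dense, and 1 HU keeps the
quantization error of applying the table at or below 0.5 HU RMSE.

Unobserved cells are imputed by an iterative penalized-least-squares
smoother: each of 100 iterations re-imposes the observed cells and applies a
DCT-domain low-pass filter 1/(1 + s λ²) (λ: Laplacian eigenvalues under
reflective boundaries), with s decreasing geometrically from 10³ to 10⁻³.
Because the lookup surface is dominated by a linear trend (the decomposition
map is affine in (low, high)) and the DCT's reflective boundary conditions
bias linear trends near the grid edges, a least-squares plane is fitted to
the observed cells, removed before smoothing and restored afterwards; the
smoother then only has to interpolate the trend-free residual. Observed
cells are never modified, and any table with no observations at all is
filled with zeros. Convergence is not tested; the iteration count is fixed
at 100.

Application is nearest-cell lookup with out-of-range coordinates clamped to
the edge bins (bilinear interpolation between cell centers is available as a
flag). The resulting image is median filtered with a 5×5 kernel (reflective
borders) to suppress the noise the decomposition amplified; the filtered
image is the L-VNC used both as a network input channel and in the residual
target.

## Residual network

The network maps the 3-channel input (low, high, median-filtered L-VNC, each
affinely windowed from [−100, 300] HU to [0, 1]) to the predicted
TNC − L-VNC difference in raw HU, at constant spatial resolution. A 3×3
convolution lifts the input to the working width, then three groups of three
residual blocks follow with dilations 1, 2 and 4 per group (enlarging the
receptive field without downsampling), and a 1×1 convolution maps back to
one channel. Each block is conv → batch-norm → ReLU → dropout → conv →
batch-norm added to its input; batch normalization can be switched off.

The loss is the RMSE between predicted and target difference over the pooled
brain-mask pixels of each batch, plus an L2 penalty on convolution kernels,
optimized with Adam. "Trained until the validation loss plateaus" is
operationalized as early stopping: no improvement > 0.01 HU for 5
consecutive epochs; the best-validation weights are restored.

Two profiles are provided:

| parameter      | `paper` | `desk` |
|----------------|---------|--------|
| channels       | 64      | 8      |
| input size     | 256     | 64     |
| batch size     | 8       | 8      |
| learning rate  | 1e−5    | 1e−3   |
| dropout        | 0.5     | 0.1    |
| L2 weight      | 0.02    | 1e−4   |

The `paper` profile carries the published optimization settings. The `desk`
profile is this package's CPU-scale configuration for the synthetic study:
with an 8-channel network and ~150 training slices, the published learning
rate is far too small to move the weights in tens of epochs, and heavy
dropout/L2 are unnecessary at this data-to-capacity ratio; 1e−3/0.1/1e−4 are
conventional values for a small CNN regression and were fixed as part of the
profile. Training is fully deterministic given the seed (initialization,
batch order, dropout masks), implemented directly on NumPy arrays (im2col
convolutions with manual backpropagation, Adam, inverted dropout), which
keeps desk-scale training reproducible bit for bit across runs.

The end-to-end study conditions used by the acceptance checks are 200
scenes of 64×64 at the default split, the default bias set and noise, and
desk-profile training for up to 12 epochs — enough for the validation loss
to approach its plateau at this scale while keeping a full 10-seed replicate
set inside a half hour of CPU time.

Deep non-contrast (DNC) images are L-VNC plus the predicted difference,
unclipped. Evaluation (masked RMSE and Spearman rank correlation with
average ranks for ties) pools the masked voxels of randomly grouped batches
of images — 32 in the clinical protocol, 8 at desk scale where the test
partition holds 22 slices — dropping a trailing incomplete batch so batches
are size-stratified; summaries report mean ± 1.96·SD/√n over batches.
Batches are drawn without replacement.

## Mask conditioning

Brain masks are eroded with a disk of diameter 5 (the 13-pixel set of
offsets within Euclidean distance 2) before any lookup construction,
training or evaluation; out-of-raster pixels count as background. The
erosion is 2-D per slice — whether the original pipeline eroded per slice or
with a 3-D ball is not published, and the package processes single slices.
Cropping to the mask bounding box (with optional margin) is provided for
preprocessing; HU values are clamped to [−1024, 3071] at load time with a
logged warning.

## What the synthetic validation does and does not show

Passing tests demonstrate that the implementation is internally consistent
(exact physics inversions, quantization-limited lookup recovery, metric
oracles) and that the *direction* of the published clinical finding —
learned DNC images track TNC more closely than physics-only VNC images when
the decomposition carries anatomy-dependent error — is reproduced by this
pipeline on data whose generating process is known. They do not validate
clinical image quality: the phantom has no skull, no registration error, no
beam hardening, simplified noise, and its decomposition bias is exactly
class-dependent rather than the more complex spatial error of a vendor
algorithm. Absolute RMSE/correlation values on the phantom are therefore not
comparable to the published clinical numbers.

## Numerical notes

- The construction identity DNC = L-VNC + (TNC − L-VNC) = TNC holds to one
  floating-point rounding (≤ 1e−12 HU at CT magnitudes), exactly when the
  predicted difference is identically zero.
- Ties in largest-remainder apportionment break toward the earlier
  partition; assignment of scenes to partitions is a seeded permutation.
- Lookup cells hit by out-of-range (low, high) pairs are clamped to edge
  bins and counted in the log.
- The median filter and the mask erosion use edge-including (symmetric)
  reflection at borders.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; no global state is used.
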