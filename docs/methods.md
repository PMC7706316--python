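# Methods

## Problem and overall approach

Field-based phenotyping of maize needs training imagery of tassels (the
male inflorescence: a central spike with lateral branches) against natural
sky, but most available tassel datasets are lab-based. `tasselgen`
synthesises field-like labelled images in three stages: a generative model
for foreground tassel patches, a second generative model for sky-background
patches, and a deterministic compositing step that merges a tassel onto a
sky with a binary mask — so every synthetic image arrives with a
pixel-exact segmentation label.

Foreground and background are generated *separately* because natural scenes
are hard to model jointly; each sub-problem (dark-background plant object,
textured blue sky) is far easier for a small generative model.

## The generative model

Both generators are deep convolutional GANs built from 4×4
transposed convolutions with stride 2 and padding 1, doubling resolution per
stage from 4×4 up to the target (so 5 stages at 64×64, 6 at 128×128; in
general log2(R/4)+1). Each stage is followed by ReLU except the last, which
uses tanh so samples live in [−1, 1] like the normalised training data
(x ↦ x/127.5 − 1). The discriminator mirrors this with strided 4×4
convolutions, leaky-ReLU (slope 0.2) and a final 4×4 convolution + sigmoid.
Weights are initialised N(0, 0.02²); latents are 100-dimensional standard
normal; optimisation is Adam with betas (0.5, 0.999). Channel widths follow
the standard doubling scheme (1024→512→256→128→64→3 for the 128-pixel
generator with the default base width of 64; the width is configurable via
`base_channels`, and the scaled-down runs below use 8).

Two modifications define the variant:

**No batch normalisation.** On tassel data — a small bright object on a
uniformly black background, with little colour variation — batch-norm's
faster loss convergence lets the discriminator reach near-zero loss within
a few epochs, after which the generator receives no useful gradient and
never learns. Removing batch-norm from *both* networks delays discriminator
convergence and keeps the adversarial game alive. The package exposes
`use_batchnorm` so the comparison itself is reproducible
(`training.run_ablation`).

**Residual paths in the generator.** Growing the generator from 5 to 6
stages (64→128 px) triggers a degradation problem: the deeper network
trains worse than the shallower one. A ResNet-style skip is added to chosen
stages: the previous stage's activated feature maps are upsampled ×2 by
interpolation (nearest-neighbour by default, bilinear optional), projected
to the next stage's channel count by a learned 1×1 convolution (zero
padding, stride 1), and added to that stage's pre-activation output. The
default attachment set for the tassel model is the stages with output
resolutions {16, 32, 64, 128}. Residual addition follows a schedule: it is
enabled for epochs 0..`residual_disable_epoch`−1 and switched off
afterwards, because late-training residual injection adds noise to samples.
The sky model needs no residuals (sky patches have little structure), so it
uses the residual-free spec.

The whole network stack (convolutions, transposed convolutions, batch-norm,
upsampling, activations, Adam, manual backpropagation) is implemented in
NumPy (`tasselgen.nn`), with the backward passes verified against central
finite differences in the test suite. With batch-norm off, every operation
is per-sample, so discriminator outputs are exactly independent of batch
composition — also asserted in tests.

## Data preparation

Lab tassel photographs are centre-cropped (half-open, 0-based intervals; the
crop extent is a per-dataset configuration value), converted to YCbCr
(ITU-R BT.601 **full-range** coefficients — the common still-image
convention), and segmented by Otsu thresholding of the blue-chroma (Cb)
channel: a brownish tassel and a bluish backdrop separate cleanly in Cb.
The thresholder maximises between-class variance over the 256-bin
histogram with pixels ≤ t in class 0 and ties broken toward the smallest t;
a constant channel raises a degenerate-input error. The tassel-side class
is the one whose mean Cb lies farther from the backdrop's modal Cb (ties go
to the smaller class, since the plant is a minority of the frame).
Background is forced to exact black, images are resized bicubically (the
one resampling kernel is used everywhere for consistency).

Sky patches are augmented by scaling HSV saturation by 0.6 and, for a
second augmented copy, luminance by 1.3; overly dark patches are removed.
The darkness criterion is a heuristic of this package: mean HSV value below
a configurable fraction of full brightness (default 0.35).

## Compositing

Generated tassels come out brighter than their training data (a known
spectral-response mismatch of GAN-generated imagery), so the luma channel
is first scaled by a correction factor — default 0.85, configurable; only
the need for a correction, not its magnitude, is dictated by the method.
The mask is Otsu on the Y channel (maximum tassel/background separation);
tassel, sky and mask are upscaled ×2 bicubically; the tassel+mask are
shifted by a seeded integer offset (uniform in ±`shift_range` per axis,
clipped so the tassel bounding box stays in frame, with a warning); the
pair is merged per pixel,

    I_m = mask · I_f + (1 − mask) · I_b,

edges are blended, and the result is scaled back down ×2 (mask re-binarised
at 0.5).

Edge blending operates row-wise: for each maximal run of mask=1 in a row,
the first and last foreground pixels are edge pixels; with L and R the
pre-blend values of an edge pixel's left and right neighbours,

    edge ← 0.5·L + 0.5·R, left ← 0.75·L + 0.25·R, right ← 0.25·L + 0.75·R.

All three assignments are evaluated simultaneously from pre-blend values
(sequential evaluation would be order-dependent), transitions touching the
image border are skipped, and the pass runs once, horizontally only.
Vertical blending and iterated passes are deliberately out of scope.

## Evaluation protocols

* **Bounding-box morphometrics** — luma-channel Otsu, tightest box over
  foreground pixels (0-based inclusive coordinates), per-set mean and
  *population* (÷N) standard deviation of widths/heights plus the fraction
  strictly wider than a cutoff (default 60 px).
* **SSIM** — single-scale structural similarity on the full-range luma
  channel, K1=0.01, K2=0.03, dynamic range 255, 11×11 Gaussian window
  σ=1.5 (delegated to scikit-image). The paired protocol matches each
  image of one set with a uniformly random partner from the other and
  averages over 3 repeats; the intraclass variant draws partners from the
  same set with self-pairing excluded (an ambiguity resolved here and
  documented: a self-pair would trivially inflate the score).
* **Inter-annotator disagreement** — the lower bound
  e ≥ (1/KN)·Σᵢ minⱼ(K − X(i,j)) for K annotators and N items, where
  X(i,j) counts annotators labelling item i with label j; 0 means
  unanimity, and for binary labels e ≤ 0.5. Expert subsets are selected by
  ranking annotators on correctly identified true-positive items, ties
  broken by annotator index.
* **KNN augmentation experiment** — 50/50 stratified split of real
  (width, height) features (stratification prevents class-absent halves at
  small n), then ⌊f·|train|⌋ generated samples appended for
  f ∈ {0, 0.25, 0.5, 0.75} (a seeded shuffle taken as a prefix, so rows
  nest) and a 5-nearest-neighbour classifier (unscaled Euclidean — both
  features share pixel units) scored on the fixed test half.
* **Perception-deck utilities** — seeded shuffling of real+generated images
  with an answer key, and a 2×2 confusion table normalised to column
  percentages (each true class sums to 100%).

## Synthetic fixtures

All stages are exercised on procedural imagery (`tasselgen.fixtures`), not
on the original lab/sky corpora. Tassel fixtures draw a wavy central spike
plus alternating lateral branches with hard (non-anti-aliased) pixels in
jittered brownish tones on an exactly black background, so the ground-truth
mask is binary-exact (the painted pixel set, no ambiguity). Sky fixtures
are a blue-dominant vertical gradient blended toward white by 3 octaves of
Gaussian-smoothed noise. Lab-scene fixtures place the tassel on a uniform
bluish (high-Cb) backdrop. Annotation fixtures give each item a latent
label that each annotator independently corrupts at a set rate.

These fixtures reproduce the *statistical structure* each stage assumes —
dark background, bimodal chroma, blue-dominant sky — not botany. Passing
tests therefore demonstrate that the pipeline's mechanics (segmentation,
training dynamics, compositing, metrics) behave correctly under those
assumptions; they do not certify visual quality on real field imagery,
which requires the original data and full-scale training.

## Scaled-down study conditions

Full-scale training (128×128, 2500 epochs at learning rate 1.5×10⁻⁵ for
tassels; 600 epochs at 2×10⁻⁵ for skies) is supported but takes GPU-scale
effort. The package's reference experiments — used by the test suite and
`scripts/acceptance.py` — run at fixture scale: 200 tassel fixtures at
32×32, batch 32, `base_channels=8`, 100 epochs (60 for the ablation), and
the stock DC-GAN learning rate 2×10⁻⁴, which is the appropriate step size
for runs this short. At this scale the qualitative training phenomena
reproduce: without batch-norm the discriminator loss stays well away from
zero for the whole run, while the batch-norm variant drives its loss an
order of magnitude lower and undercuts the no-batch-norm run's minimum
within the first ~10 epochs (majority over 3 seeds).

## Numerical choices and degenerate inputs

* Probabilities are clamped to [10⁻⁷, 1−10⁻⁷] before logs in the losses.
* Otsu on a constant channel, an all-dark compositing input, an empty
  bounding-box foreground, and a single-annotator matrix raise typed errors
  (`DegenerateInputError` / `ParameterError`) rather than returning
  arbitrary values.
* Epoch indexing is 0-based; "disable at epoch E" means epochs 0..E−1 run
  with residuals.
* The mask survives ×2 up/downscaling by bicubic resampling followed by
  re-binarisation at 0.5.
* normalise/denormalise round-trips exactly on all 256 grey levels.

## Known limitations

* Fixture-scale results say nothing about photorealism; SSIM values on
  fixtures are not comparable to values measured on real tassel corpora.
* Edge blending is horizontal-only and single-pass; columns of the mask
  boundary are left to the ×2 downscale to soften.
* One tassel per composite; no illumination matching between foreground
  and background.
* The NumPy network stack is single-device and unaccelerated; it is meant
  for correctness and reproducibility, with full-scale runs being slow.
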