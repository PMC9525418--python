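# Methods

`patlaknet` implements, end to end, direct convolutional inference of
whole-body Patlak net-influx (Ki) parametric maps from late dynamic PET
passes and/or a static SUV image, together with the two pieces of
machinery needed to develop and validate such a model without patient
data: a kinetic simulator with exact ground truth, and the classical
image-derived-input-function Patlak pipeline that produces the reference
maps the network is trained against.

## Kinetic model and ground truth

Tissue activity follows a two-tissue compartment model with plasma-to-free
uptake K1 (mL s⁻¹ mL⁻¹), efflux k2, binding k3 and release k4 (all s⁻¹),
plus a fractional blood volume vb ∈ [0, 1]:

    C(t) = (1 − vb) · C_tissue(t) + vb · Cp(t).

With irreversible trapping (k4 = 0),

    C_tissue(t) = Ki · ∫₀ᵗ Cp dτ + (K1·k2/(k2+k3)) · (e^{−(k2+k3)t} ⊛ Cp),
    Ki = K1·k3/(k2+k3),

which is the basis of Patlak graphical analysis: plotting C/Cp against
x = ∫Cp/Cp yields asymptotic slope Ki and intercept V (distribution
volume). Two properties of this model matter for interpretation of our
tests:

- **Blood volume.** The measurable Patlak slope of C(t) is (1 − vb)·Ki,
  not Ki. Identity tests that compare fitted slopes against the
  closed-form Ki therefore use vb = 0 tissues; the cohort default keeps
  realistic vb > 0, which is consistent end to end because the network's
  target is the Patlak reference map itself.
- **Equilibrium window.** The tri-exponential plasma curve retains an
  intermediate decay component (λ ≈ 2×10⁻³ s⁻¹) well past the nominal
  5–10 min equilibrium, so a fit starting at 10 min carries a small
  tissue-dependent negative slope bias (1–5 % at vb = 0). This is the
  documented early-window Patlak bias of multi-pass protocols, and we
  keep it: the reference pipeline fits all thirteen passes, as the
  clinical protocol we emulate does. Identity tests use a fit window at
  ≥ 30 min, where the residual bias is below 2 %.

k4 > 0 (reversible washout) is supported only as a model-mismatch stress
input — it generates the "visible on SUV, invisible on Ki" lesion class —
and never enters ground-truth Ki, which is always K1·k3/(k2+k3).

## Plasma input function

A Feng-type tri-exponential with delay t0,

    Cp(t) = (A1·(t−t0) − A2 − A3)·e^{−λ1(t−t0)} + A2·e^{−λ2(t−t0)} + A3·e^{−λ3(t−t0)},

λ1 > λ2 > λ3 > 0. The default shape is the classic FDG blood curve
(λ = 4.134, 0.1191, 0.0104 min⁻¹ converted to s⁻¹), rescaled so that a
~280 MBq injection in a 75 kg subject yields a peak of ~30 kBq/mL at
~27 s after appearance and a late tail of ~4 kBq/mL — SUV ≈ 1 blood at
60 min, which is clinically plausible. Per subject, the amplitude scales
with the drawn dose-per-kg (the physical premise of SUV normalization)
times a small log-normal physiological factor (σ = 2 % at default
cohort variability); the shape parameters are shared. Tissue curves are
computed by numerical convolution on a 0.25 s grid (exponential kernels
via FFT convolution) and frame-averaged analytically over each
acquisition window.

## Acquisition model

The default protocol mirrors a hybrid whole-body dynamic FDG exam:
20 early single-bed frames over the blood pool (8×5 s, 4×10 s, 4×25 s,
4×45 s, ending at 6 min), thirteen 180 s whole-body passes back-to-back
from 10 min p.i. (the per-pass start times of such protocols are not
standardized; back-to-back passes from 600 s are our configurable
default), and one 20 min SUV acquisition from 60 min p.i. Rendering
paints per-label frame-averaged TACs into a multi-slice 2-D atlas
(head / thorax / abdomen / pelvis sections with brain, lungs, cardiac
blood pool, liver, aorta, soft tissue), applies a 2 mm FWHM Gaussian
post-reconstruction filter, and adds frame-independent Gaussian noise
with variance proportional to signal/duration — a scaled-Poisson
surrogate appropriate for image-space simulation; no sinogram physics,
attenuation, scatter, or bed-motion geometry is modeled. The 20 min SUV
frame is correspondingly less noisy than a 3 min pass.

Two generator constants are calibrated to the printed error budget of
the clinical study this package replicates, chosen a priori from those
published numbers rather than tuned against our own outputs: organ Ki
defaults (lung/soft ~1×10⁻⁴, liver ~1.5×10⁻⁴, brain ~5.5×10⁻⁴, in
mL s⁻¹ mL⁻¹) sit well inside the evaluated intensity range implied by
the study's MAE-to-MRAE ratio (mean evaluated Ki ≈ 1.8×10⁻⁴), clear of
the 5×10⁻⁵ evaluation threshold; and the noise scale (1.0, i.e. ~3 %
voxel noise on a 10 kBq/mL 3-min pass) gives reference-map voxel CVs of
2–6 %, the level consistent with a whole-volume MRAE of ~7.5 % being
achievable at all (the MRAE floor against a noisy reference is ≈ 0.8·CV).

Lesions (8 mm radius disks by default, three per subject) cycle through
contrast recipes that populate the visibility taxonomy: high K1·k3
(visible on both SUV and Ki), k3-only elevation in liver (Ki-visible,
SUV-faint — the hepatic case the taxonomy is built around), reversible
k4 > 0 washout in lung (SUV-visible, Ki-invisible), and a 1.2× nudge
(invisible on both).

## Reference pipeline

The input function is image-derived: the mean over an eroded cardiac
blood-pool VOI, concatenating the 20 early frames with the blood-pool
samples of each pass (33 samples). The Patlak transform integrates Cp by
trapezoid from t = 0 with Cp(0) = 0, drops non-positive Cp samples (with
a count), and the voxelwise fit is unweighted OLS of C/Cp on x over
frames with mid-time ≥ t\*, with t\* defaulting to the first pass start
so all thirteen passes enter the reference, and a weighted option
exposed but off. Negative slopes are kept; exclusion happens only at
evaluation time (reference voxels below 5×10⁻⁵ after denormalization).
Frame mid-times represent frames throughout.

## Network and training

The regressor is a 2-D dilated residual network in the highres-net
style: one 3×3 stem convolution, nine pre-activation residual blocks
(BN → ReLU → conv, two convolutions per block) with dilations 1/2/4 in
three stages of three blocks, a penultimate 1×1 feature-fusion
convolution — 20 convolutional layers in all — and an excluded 1×1
regression head. Dilation replaces pooling: the forward pass is
shape-preserving, with an 87-pixel receptive-field diameter
(1 + 2·(7·1 + 6·2 + 6·4)). Width changes at stage boundaries are carried
by zero-padding the identity path. Each residual branch's closing
convolution is zero-initialized so blocks start as identities, which
substantially accelerates convergence of this deep residual stack; the
remaining convolutions use He initialization. Kernels are 3×3 in 2-D:
training is two-dimensional (each transaxial slice pair is one sample),
so the third kernel dimension of the reference architecture collapses.

Layers are implemented in NumPy (`patlaknet.nnet`) with hand-written
backward passes; convolutions evaluate as nine shifted BLAS products.
Everything is float32 and fully deterministic given the seed and thread
count.

Training follows the clinical study's recipe: Adam, L2 loss, batch 20,
10 epochs, learning rate interpolated linearly 3×10⁻³ → 1×10⁻⁴ and L2
weight decay 1×10⁻⁵ → 0 across epochs (the endpoints are specified;
the linear interpolation is our reading — a geometric interpolation was
evaluated and converged worse), 5 % of samples held out for monitoring,
one sample per volume slice. Two standard stabilizers are applied:
gradients are rescaled when their global norm exceeds 2.0 (measured
norms are heavy-tailed — median 0.6, occasional 30× outliers — and the
clip touches only those outlier steps), and the returned model is the
epoch checkpoint with the lowest monitoring loss, which is what the 5 %
holdout exists for. Batches draw random 32×32
spatial windows of the (64×64) slices at desk scale — the window-based
sampling mirrors how such platforms train on fixed-size spatial windows.
Inputs are the SUV image and/or passes converted to SUV units; all image
types are normalized by fixed per-type factors (across-subject mean of
per-subject maxima, divided by two, computed on the training split by
default with a global option), so images land in [0–2] without
clipping. Predictions are denormalized with the Ki factor before any
evaluation. The prediction path consumes no input function, by
construction of its interface.

## Evaluation

Voxel metrics (MAE, ME, MRAE%, RE%, MSE, RMSE, PSNR with I² the squared
max intensity of both maps, and a single global SSIM with
C1 = (0.01·I)², C2 = (0.02·I)²) are computed patient-wise over the
reference-defined mask (ref ≥ 5×10⁻⁵). The printed SSIM denominator in
our source study mixes a mean and a variance term; we implement the
standard symmetric form, which its reported SSIM ≈ 1.00 ± 7×10⁻⁷ is
consistent with. Organ statistics are AME = |mean Δ| and
AMRE% = |ΣΔ|/Σref·100 over 10 mm spherical VOIs; lesion detectability
uses TBR = max(tumor)/mean(background) − 1 and CNR = TBR/SD(background);
joint-histogram analysis fits OLS of predicted on reference with Pearson
correlation; Spearman coefficients use exact permutation p-values for
n ≤ 9 and the t-approximation otherwise. Lesion visibility is a TBR
threshold proxy (default 1.5, calibrated once so the synthetic contrast
recipes classify as designed) for what is a human reading in the clinic.

## Desk-scale problem sizes

The default run configuration is a 19-subject cohort of 64×64 phantoms
with 120 thin slices, 10 % kinetic variability, three lesions per
subject, a reduced-width network (16/32/64 → 8/16/24 channels, selected
among reduced-width candidates by held-out error at desk scale), and one
evaluation fold (two held-out subjects). These sizes keep a full
simulate → reference → train → predict → evaluate cycle to roughly
fifteen minutes on one CPU core while preserving the study's structure (19
subjects, nine-fold partition, 10 epochs, batch 20). The trend analysis
across input configurations uses a smaller cohort (12 subjects, 24
slices, 48×48, 6/10/14 widths) averaged over two seeds.

## What the synthetic cohort does and does not show

The phantoms share the study's acquisition timing, noise-versus-duration
scaling, PSF, normalization and training protocol, and they reproduce
the qualitative structure of the clinical result: near-floor errors in
brain, the largest relative errors and subject-level biases in liver
(where high distribution volume decouples late activity from Ki), and
error that falls as passes are added with a plateau after pass 11. They
do not contain respiratory motion, attenuation/scatter residuals,
inter-scanner effects, pathology heterogeneity, or realistic organ
texture — all organs are piecewise-constant ellipses — so absolute error
levels on real data cannot be inferred from passing tests here; the
clinical study's printed values serve as upper bounds for this cleaner
setting.

## Numerical choices and degenerate inputs

Convolution grids use dt = 0.25 s (results stable at 1 % tolerances down
to dt = 0.05 s). The Patlak fit requires ≥ 2 frames past t\* with
positive Cp and raises otherwise; empty VOIs, all-zero normalization
stacks, channel-count mismatches, sub-voxel lesions and overlapping
protocol frames raise immediately with named errors. PSNR of identical
maps is reported as +inf with SSIM 1. Zero-variance backgrounds give
CNR = +inf sentinels. File writes are atomic (temp + rename), and every
pipeline artifact is reproducible from the config snapshot and seed
alone.
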