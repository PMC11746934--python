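# Methods

## Problem and model

Serial-sectioning OCT produces scattering-coefficient (SC) maps of
block-face brain tissue: single-channel whole-slide images (~12 µm/px)
in which myelin-rich white matter scatters strongly and appears bright.
Gallyas silver staining of the cut sections produces RGB whole-slide
images with the opposite contrast (myelin dark).  Because the stained
section and the SC map come from *adjacent* physical sections, the two
modalities are only weakly paired: related by an unknown smooth
deformation and by genuine content differences (vessels and fibers that
exist in one section but not the other).

The package trains a translator `G` that maps an equalized SC map to a
stain-like RGB image, using four cooperating objectives:

1. **Least-squares adversarial loss.**  A patch discriminator `D`
   scores real stain patches toward 1 and translated patches toward 0;
   `G` is trained to push its outputs' scores toward 1:

       L_GAN(D) = E[(D(y) − 1)²] + E[D(G(x))²]
       L_GAN(G) = E[(D(G(x)) − 1)²]

2. **Patch-wise contrastive loss.**  Encoder features of `x` and of
   `G(x)` are sampled at identical spatial sites, projected by
   per-layer two-layer MLPs `f` and unit-normalized; each positive pair
   is contrasted against the other sampled sites of the same image:

       −log( exp(z_s·ẑ_s/τ) / Σ_t exp(z_s·ẑ_t/τ) ),

   averaged over sites and layers, temperature τ = 0.07.  (The loss is
   implemented in the standard minimized negative-log form with a
   temperature; only the translated-side embeddings propagate gradients
   into the encoder.)

3. **Optical-density pseudo-supervision.**  The optical density
   OD(Y) = −(1/3)·Σ_c log10(Y_c) of a stain image is a grayscale proxy
   with SC-like contrast and is pixel-aligned with Y by construction,
   so `‖G(OD(y)) − y‖₁` gives aligned supervision.  The OD→stain and
   SC→stain input domains differ; histogram equalization of both inputs
   plus passing `G(OD(y))` through the discriminator (on by default)
   closes that gap.

4. **Registration-based weak supervision.**  A registration network `R`
   predicts a dense displacement field φ for a (fixed, moving) pair
   under backward warping: `(φ∘Y)(p) = Y(p + φ(p))`.  Stage I
   pre-trains R with the cross-modal loss
   `‖X − φ∘OD(Y)‖₁ + λ·TV(φ)`; stage II alternates
   `‖G(X) − φ∘Y‖₁ + λ·TV(φ)` for R (G frozen, WSI scale) with
   `‖G(x) − φ_y∘y‖₁` for G (R frozen, patch scale, shared crop grid).
   During stage II the G update optimizes the weighted sum of all four
   objectives — dropping the adversarial/contrastive/pseudo anchors and
   training on the misaligned L1 term alone measurably washes out the
   learned tone mapping.
   TV is the isotropic total variation with the two displacement
   channels combined under one square root.

The weighted sum uses default weights (w_gan, w_nce, w_pseudo, w_reg) =
(1, 1, 10, 10): the two L1-type paired terms are up-weighted, as is
conventional when mixing adversarial and paired reconstruction losses.
Inside the registration losses the TV term is divided by the number of
field pixels so that λ_TV (default 0.1) is independent of image size;
the exported `tv_norm` itself is the raw sum.

## Networks and numerical core

No GPU framework is assumed: the package carries a small reverse-mode
automatic-differentiation engine (`scstain.autodiff`) over float64
numpy arrays — broadcasted arithmetic, im2col convolution, pooling,
padding, a differentiable bilinear warp with gradients to both image
and field, and spatial gathering for the contrastive sampling.  All
backward passes are verified against central finite differences in the
test suite.

Two architecture profiles are provided.  The **tiny** profile (~25k
parameters across all four networks) is the one every experiment here
uses; the **paper** profile reproduces conventional full-size layouts
(6 residual blocks, 70×70-receptive-field discriminator, 256-dim
projection heads) and is provided for completeness.

* `G`: residual encoder–decoder, instance normalization, reflection
  padding, sigmoid output; fully convolutional (any input size).  The
  first half of the residual stack is the encoder whose taps feed the
  contrastive loss (3 taps in tiny, 4 in paper).
* `D`: strided (pool-based) patch discriminator emitting a score map.
* `f`: per-tap two-layer MLPs with unit-norm outputs.
* `R`: a conv trunk that predicts the field at 1/4 resolution and
  upsamples it in-graph.  Several details matter in practice and were
  adopted after observing failure modes:
  - the final conv is **zero-initialized** (training starts at the
    identity warp) and its output is multiplied by a fixed flow gain
    of 8 so multi-pixel displacements are reachable with small weights;
  - activations are **leaky** (slope 0.2): with plain ReLUs the large
    early Adam steps can silence the trunk entirely, freezing the
    zero-initialized head at φ ≡ 0 permanently;
  - upsampling is **zero-stuffing followed by a fixed triangular
    kernel**, i.e. an exactly grid-aligned bilinear interpolation.
    (Nearest-neighbour repetition followed by symmetric smoothing
    carries a ~1.5 px systematic shift that places an artificial floor
    under the endpoint error.)
  - the network input is 4 channels: the (fixed, moving) pair plus
    Gaussian-smoothed (σ = 4 px) copies, giving the trunk explicit
    coarse-scale evidence;
  - the output is saturated to ±16 px per axis with a tanh.  Adjacent-
    section deformations are physically bounded, and the bound also
    removes a degenerate optimum of the stage-II loss: a constant large
    field costs zero total variation yet lets the warped stain sample
    only its white border background, pulling the whole alternation
    into an all-white fixed point when the translator is still weak.

Stage-I pre-training uses a two-scale pyramid of the data term (the
σ = 4 smoothed pair at weight 1.0 for the first half of training, 0.2
afterwards) and steps the learning rate down 3.3× for the last quarter
— the classic coarse-to-fine schedule of deformable registration.
Inference (`register`) applies R three times, warping the moving image
and composing the increments; this roughly halves the endpoint error
relative to a single pass.  Optimizers are Adam with β = (0.5, 0.999)
at learning rate 10⁻³ throughout the tiny profile: the conventional
2·10⁻⁴ of full-size translation networks leaves these very small
models underfit within the declared stage lengths (the pseudo-
supervision term plateaus early and the stain polarity fails to form
at some seeds).

## Training schedule (tiny profile)

Declared stage lengths: 1600 registration pre-training iterations,
1200 combined backbone iterations (each = one adversarial/contrastive
step on an (x, y) patch pair plus one pseudo-supervised step), and 250
alternation iterations, with 64×64 training patches cut from 128×128
phantom WSIs on the deterministic non-overlapping grid.  The zero-
initialized flow head needs several hundred updates before the field
leaves the identity, which is why the registration stage dominates; the
patch-phase lengths were chosen so the full protocol fits in roughly a
quarter hour on one CPU core.  Everything is deterministic under a
fixed seed: data order, patch choice and contrastive site sampling all
derive from it.

## The phantom generator

`scstain.phantom` builds both modalities from one latent myelin field
over a layered geometry: a curved pial surface (two random sinusoidal
harmonics; the amplitude parameter produces gyrus/sulcus-like folds),
bands for layers I–III, IV, V, VI and white matter at configurable
height fractions, tubular vessel voids, and a smooth within-layer
texture.  Per-label myelin levels are 0.15 / 0.45 / 0.62 / 0.55 / 0.95
(supra / IV / V / VI / WM) with vessels at 0.02 — deep layers darker
than supragranular cortex, V ≈ VI, and white matter well separated so
that the minimum-method histogram threshold can isolate it, as it does
on real silver stains.

* SC model: `sc = (3 + 10·myelin) mm⁻¹` times unit-mean multiplicative
  gamma speckle (default variance 0.15), zero on background.
* Stain model: `y_c = 1 − myelin^γ · s_c` with absorption vector
  s = (0.70, 0.82, 0.96) (dark brown: blue absorbed most) and a
  per-slice tone nonlinearity γ drawn near 1 — a learnable, non-identity
  monotone color map whose exact inverse (`invert_ps_colormap`) serves
  as the evaluation oracle.
* Weak pairs: the stain side is re-rendered with a fresh tone curve and
  (optionally) a fraction of vessels re-placed, then warped by the
  numerical inverse of a random smooth field (Gaussian-filtered noise,
  σ ≈ min(H,W)/8, scaled to a maximum displacement); the forward field
  is returned as ground truth.
* Volumes: boundary phases drift boundedly across z and a subset of
  vessels follow continuous 3-D paths, so 3-D connectivity checks and
  MIP visualizations have ground truth.

What the phantom does **not** emulate: realistic coherent-speckle
statistics (gamma noise is i.i.d., real speckle is correlated),
individual fiber bundles and somas, staining artifacts such as
tears or stitching seams, and anatomically realistic folding.  Passing
tests therefore demonstrate that the algorithms recover known structure
under controlled nuisances — not clinical-grade performance on real
tissue.

## Evaluation design

* **Registration recovery** is scored on noise-free, content-matched
  weak pairs (amplitude 8 px).  Under the default speckle the L1 data
  term is dominated by noise — the ground-truth field reduces it by
  only ~10% — so its reduction stops measuring registration.  On
  noise-free pairs the ground-truth reduction ceiling is ~55–60%, and
  direct free-form optimization of the stage-I objective reaches ~52%,
  which the amortized network approaches (≈50% at median endpoint
  error ≈ 1.2 px).
* **Translation fidelity** is scored on a held-out noise-free phantom:
  white matter darker than gray matter (polarity opposite to SC), rank
  correlation > 0.9 between binned translator luminance and the
  generator's true tone map, and vessel pixels remaining in the top
  luminance quartile (no hallucinated stain in voids).
* **Thickness**: local thickness is the classical largest-inscribed-
  disc diameter, computed by painting discs of radius `dt − ½` (edt to
  the nearest background pixel, offset half a pixel to the boundary) in
  decreasing order; a brute-force disc-fitting oracle guards the
  implementation, and bands of 25/45/40 px at 12 µm/px recover medians
  of 300/540/480 µm within one pixel.

## Numerical conventions and edge cases

* Histogram equalization: 256 bins over the nonzero foreground only,
  monotone mapping applied everywhere, background returned as 0;
  constant images map to 0.5 everywhere.
* Optical density clamps zeros at 1/65535 (the formula is undefined at
  zero transmittance).
* Triangle threshold: bin of maximum perpendicular distance to the
  peak-to-farthest-tail chord; ties break toward the lower index;
  single-bin histograms return that bin.
* `clean_sc` detects defects (difference-of-Gaussians edges above a
  floored 95th percentile; values below half the local maximum) on a
  median-smoothed copy so speckle does not trigger them, and replaces
  flagged pixels with the local maximum of *non-flagged* neighbors,
  never decreasing a pixel — which makes a second pass a near no-op.
* Background blackening only treats near-white pixels (luminance
  > 0.85) as candidate background, so all-tissue images pass through.
* Warping clamps out-of-bounds samples to the border; the TV norm uses
  forward differences with out-of-range terms contributing zero, and
  its gradient at exactly zero difference is taken as zero.
* `split`/`stitch` pad bottom/right with the modality background (0 for
  SC, white for stain) and are exact inverses at stride = patch;
  overlapping stitching averages uniformly.

## Known limitations

* The tiny profile is a scaled-down testbed; nothing here claims the
  full-size architectures reproduce published image quality on real
  S-OCT data.
* The registration network corrects smooth geometric distortion only;
  content mismatch between sections is deliberately out of its reach
  and shows up as a residual floor in the cross-modal data term.
* The adversarial component at tiny scale mostly sharpens tone; with
  larger models and data it would carry more of the perceptual burden.
* Training runs single-device CPU; there is no accelerator path.
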