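# Methods

## Problem and model

The toolkit segments histopathology-style 2-D images into binary
foreground/background masks, with particular care for object boundaries:
in renal pathology the downstream morphometry (glomerular areas,
interstitial fractions) depends on contour accuracy far more than on bulk
overlap. Two mechanisms address this.

**Edge-gated architecture.** The backbone is a U-Net encoder–decoder with
concatenation skip connections. At two scales (1/8 on the encoder side,
1/4 on the decoder side) a fixed Sobel layer computes the channel-averaged
gradient magnitude of the feature map; a learned 1×1 convolution plus
sigmoid converts it into a single-channel attention map `E = σ(conv1×1(‖Sobel(x)‖))`
which multiplies the features and is concatenated with them. This is the
gated-convolution idea `Y = (Wf∗X) ⊙ σ(Wg∗X)` specialized to an edge
prior: the gate is driven by gradient magnitude, so homogeneous regions
are damped and boundary-adjacent features emphasized. The bottleneck uses
dilation-2 convolutions to widen the receptive field without further
pooling. Auxiliary sigmoid heads at 1/4 and 1/8 resolution predict
boundary maps (deep supervision); the two attention maps are exposed as
edge outputs and supervised against mask-derived edge targets.

**Boundary-sensitive optimization (BSO).** The main head trains with

    L_seg = λ1·L_wBCE + λ2·L_bDice,     λ1 = 0.6, λ2 = 0.4

where `L_wBCE` is binary cross-entropy with the positive class weighted
β = 2.5 (foreground pixels are rare), and `L_bDice` is a Dice loss whose
sums run only over a boundary band `Mb`: all pixels within Chebyshev
radius 3 of the mask border (border = mask XOR its 3×3 erosion; the band
is three iterated 3×3 dilations of that border set). ε = 1e-6 smooths the
ratio. Each auxiliary head adds an unweighted BCE term scaled by
α = 0.2; auxiliary targets are already sparse bands, so β-reweighting
there would double-count the imbalance correction.

Ablation variants change exactly one ingredient at a time: `baseline`
(plain U-Net topology, plain BCE+Dice loss), `edge_only` (edge topology,
plain loss), `boundary_only` (plain topology, BSO loss), `full` (both).
The "plain" loss is implemented as the same composite with β = 1 and the
band widened to the whole frame, which reduces `L_bDice` to ordinary Dice
— so the loss ablation is exactly the presence of boundary weighting.

## Numerical substrate

No deep-learning framework is part of the toolkit's dependency set; the
network and trainer run on a small reverse-mode autodiff engine written
on NumPy (`autodiff.py`, `nn.py`): im2col convolutions, 2×2 max pooling,
stride-2 transposed convolutions, batch normalization, and Adam. All
tensors are float32, NHWC. Every vector-Jacobian product is checked
against central finite differences in the test suite. Inference runs
under a `no_grad` context so no graph is retained.

Numerical choices: probabilities are clipped to [1e-7, 1−1e-7] before
logarithms; the in-network Sobel magnitude adds 1e-12 under the square
root for a finite gradient at zero; max-pool backward splits gradient
equally among tied maxima; weight init is He-normal from a per-model RNG,
except the two attention 1×1 convolutions which start near zero
(std 0.05) so the gates open neutrally (E ≈ 0.5) instead of saturating on
the large Sobel magnitudes of randomly initialized deep features.

## Deterministic operators and conventions

Edge/boundary machinery uses replicate (clamped-index) border handling
throughout, so a full-frame mask has no border: erosion treats
out-of-frame pixels as foreground, dilation as background. The edge
ground truth is the morphological gradient (3×3 dilation minus erosion,
clipped to {0,1}). Supervision targets at auxiliary scales are
max-pooled, not interpolated: a low-resolution cell is positive if any
constituent pixel is, which preserves the thin structures the boundary
heads exist for.

Metric conventions: Dice/IoU/volumetric similarity of two empty masks
are 1, HD95 of two empty masks is 0, and HD95 with exactly one empty
mask is the image diagonal √(H²+W²) — a flagged sentinel, not a distance.
HD95 pools the two directed nearest-neighbour border-distance multisets
and takes the 95th percentile of the pooled set, which is symmetric by
construction (directed-percentile-then-max is the other convention in
the literature). Boundary F1 matches border pixels within 2 px Euclidean
tolerance (configurable). Volumetric similarity is 1 − ||Y|−|P||/(|Y|+|P|).
SSIM/PSNR compare the raw probability map to the binary truth with data
range 1 (7×7 SSIM window); PSNR is capped at 100 dB for identical inputs.
The bootstrap CI of a mean enumerates all n^n resamples exactly when that
count does not exceed `n_boot` (so tiny samples give deterministic,
exact percentile bounds) and falls back to seeded Monte Carlo otherwise.
Cohen's d for paired comparisons is mean(Δ)/sd(Δ) with sample SD; all-zero
differences are reported as d = 0, p = 1.

## Synthetic data: what it emulates and what it does not

The generator draws bright elliptical blobs (glomerulus-like) and thin
elliptical annuli (tubule-cross-section-like) on a darker background.
Foreground sits `foreground_contrast` above background before noise, so
mask/intensity correspondence is exact and testable at zero noise. Each
synthetic "patient" carries a global intensity offset (stain shift,
N(0, 0.05)) emulating multi-center staining variability, and a cohort
label cycling through four disease groups; images per patient default to
6, matching the few-images-per-patient regime of biopsy datasets.
Everything is a pure function of (config, seed).

It does **not** emulate nuclear texture, color (images are single-channel
luminance), whole-slide scale, annotation noise, or anatomically
realistic shape statistics. Passing the training tests therefore shows
the architecture, loss, optimizer and evaluation stack are correctly
wired and can recover known structure from realistic nuisances
(stain shift, noise, patient grouping) — not that the model reaches any
particular accuracy on real kidney histology.

## Reference study conditions

Two canned protocols (`experiments.py`) fix the desk-scale conditions:

* **Recovery study**: 30 patients × 6 images at 64×64 (120 train /
  30 val / 30 test after whole-patient apportionment), contrast 0.6,
  noise SD 0.02, full variant with base width 16, Adam lr 1e-4, batch 8,
  15 epochs, seed 42. The model must essentially solve this dataset
  (held-out Dice ≥ 0.85, IoU ≥ 0.75).
* **Ring ablation**: ring-only datasets (20 patients × 6 images, 64×64)
  over seeds {0, 1, 2}; full vs baseline; median held-out HD95 compared
  across seeds. Each run trains 30 epochs: desk-scale cohorts provide
  roughly an order of magnitude fewer optimizer steps per epoch than a
  ~1800-image training set at the full-scale schedule, and comparing
  half-converged models would measure optimization speed, not boundary
  behaviour. Base width 16 is the desk-scale default; the reference
  256×256 architecture uses 64.

Training monitors validation total loss; early stopping patience 10,
plateau LR halving with patience 5 (floor 1e-6), best-epoch weights
restored. Augmentation (rot90/hflip/zoom 0.9–1.1, each with probability
0.5, training set only) is available but off in the reference protocols.

## Known limitations

* Single-channel input is the default; 3-channel input is configurable
  but the reference topology is defined for one channel.
* The λ sensitivity sweep retrains per grid point and is correspondingly
  slow; it is exposed through the CLI rather than run in the test suite.
* The trainer is single-process CPU; batch-level parallelism comes only
  from BLAS.
* An alternative edge-downsampling design, where the predicted edge map
  is repeatedly pooled and fused into every decoder stage, is not built; the
  layer-table topology (encoder-side fusion at 1/8, decoder-side at 1/4)
  is authoritative here.
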