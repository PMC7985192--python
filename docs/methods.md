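# Methods

## Problem and model

A wide-field fluorescence microscope images one focal plane at a time; a
high-NA objective (63x/1.4NA class) has a depth of field (DOF) of roughly
0.4 um, so volumetric imaging conventionally requires dense mechanical
z-scanning (e.g. 91 planes at 0.2 um steps to cover 18 um). This package
reconstructs the whole volume from a handful of sparsely acquired 2D planes:
a convolutional-recurrent generator receives M (image, DPM) pairs, where the
digital propagation matrix (DPM) is a constant matrix encoding the signed
axial distance from that input plane to the requested output plane,
`dz = z_target − z_input`, divided by a fixed 10 um scale constant so the
DPM channel is O(1) next to normalized intensities. Covering a dense output
grid from M = 3 inputs is what yields the ~30-fold reduction in mechanical
scans.

The generator is a U-shaped encoder–decoder with K scales. Encoder block k
applies (2x2 max-pool for k >= 2, none at the stem) then two 3x3
convolutions with batch normalization and ReLU; channel widths follow
`base·2^(k−2)` and `base·2^(k−1)` for k >= 2, and `base` at both stem
convolutions (the width formula would give a fractional/smaller stem; a
clean `base`-wide stem is the simplest consistent choice). At every scale a
convolutional GRU integrates features across the M sequence steps:

    f_t   = sigmoid(W_f * x_t + U_f * h_{t−1} + b_f)
    h_hat = tanh(W_h * x_t + U_h * (f_t ⊙ h_{t−1}) + b_h)
    h_t   = (1 − f_t) ⊙ h_{t−1} + f_t ⊙ h_hat

with the hidden width equal to the scale's feature width, hidden state
initialized to zeros at the start of every sequence, and a 1x1-projected
residual `s_k = x_k + Conv1x1(h_k)`. The decoder mirrors the encoder with
2x2 nearest up-sampling and skip concatenation of the `s_k`; a linear 1x1
head (no ReLU — normalized targets dip below zero after background
subtraction) emits one channel. Because all weights are shared across
sequence steps, the parameter count is independent of M and one weight set
accepts any M >= 1. Batch-norm layers use batch statistics during training
and frozen running statistics (momentum 0.1) at inference, which makes
inference bit-deterministic.

The discriminator is a five-block CNN (two 3x3 convs of width `20·2^k` per
block, 2x2 max-pooling between blocks), global average pooling, a 20-unit
ReLU dense layer and a sigmoid unit.

No deep-learning framework is used: the package ships a compact reverse-mode
autodiff engine over numpy (`refocus.nn`) providing exactly the operations
the model needs (stride-1 same-padded conv via im2col/tensordot, pooling,
nearest up-sampling, batch norm, the pointwise nonlinearities and reductions)
plus an Adam optimizer. This keeps the dependency surface tiny and makes
every gradient numerically checkable; the engine is validated against
central-difference gradients in float64.

## Losses

The generator objective is

    L_V = α·BerHu(ŷ, y) + β·(1 − MSSSIM(ŷ, y)) + γ·(D(ŷ) − 1)²

with α, β, γ = 3, 1, 0.5. The MS-SSIM enters as `1 − MSSSIM`: a printed
form that *adds* the similarity would reward dissimilarity when minimized,
so the standard similarity-to-loss conversion is used. BerHu (reverse
Huber) is `|e|` for `|e| <= c` and `(e² + c²)/(2c)` above, with c = 0.1 on
the normalized intensity scale; `berhu()` defaults to the per-pixel sum
(the literal definition) while the composite loss divides by the pixel
count so α, β, γ stay scale-balanced across crop sizes. MS-SSIM uses 11x11
Gaussian windows (σ = 1.5) on the valid (unpadded) region, 2x2 mean-pool
down-sampling, the canonical five-level exponents
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333) renormalized when fewer levels
fit the crop, C1 = (0.01·L)², C2 = (0.03·L)², C3 = C2/2 with L = 1 on the
normalized scale, and the structure term `(σ_xy + C3)/(σ_x σ_y + C3)` (the
canonical covariance form; a squared covariance in the numerator would be
dimensionally inconsistent with the denominator). Means of the per-level
terms are clamped at zero (with a 1e-8 floor inside the fractional power to
keep the gradient finite) — active only for strongly anticorrelated pairs.
The discriminator minimizes the least-squares objective
`L_D = ½·D(ŷ)² + ½·(D(y) − 1)²`, alternating 1:1 with the generator.

## Synthetic image formation (what the phantom does and does not emulate)

The simulator renders point-like emitters through a separable 2D Gaussian
PSF whose width grows with defocus as `σ(dz) = σ0·sqrt(1 + (dz/z_R)²)` —
the simplest model exhibiting depth-coded blur with an analytic FWHM oracle
(`FWHM = 2·sqrt(2 ln 2)·σ`). Pixel values integrate the Gaussian over the
pixel area (erf differences), so defocus redistributes but conserves energy
exactly up to frame truncation. Defaults: σ0 = 0.1 um, z_R = 0.2 um (PSF
variance doubles at ±0.2 um, emulating the ~0.4 um DOF of the reference
objective), 0.1 um/pixel lateral sampling (63x-class), background 10,
Poisson shot noise at unit photon gain plus Gaussian read noise (SD 2);
real cameras' noise statistics vary by sensor and gain, so these are free
parameters, not a calibration. A filament phantom (random 3D Bézier curves
sampled into emitters) covers worm-like morphologies. Not modelled:
vectorial/Born–Wolf PSFs, aberrations, photobleaching, stage drift —
conclusions from passing tests transfer to real data only insofar as real
defocus is likewise smooth, monotone in |dz| and energy-preserving.

## Preprocessing

The EDF reference image is the per-pixel maximum-intensity projection of
the stack (a monotone, parameter-free substitute for wavelet-based extended
depth-of-field fusion — sufficient as a thresholding reference). Triangle
thresholding on a 256-bin histogram (matching the 8-bit display convention)
separates foreground; the normalization maps `x → (x − shift)/scale` with
shift = mean of EDF background pixels and scale chosen so the 99th
percentile (linear interpolation) of the normalized EDF foreground is
exactly 1, i.e. `scale = p99(foreground) − shift`. The factors are returned
with every normalized stack, making the map invertible to <1e-6 relative.
Stacks are cut into non-overlapping square tiles (256 px at full scale),
discarding remainder margins. Lateral registration must happen upstream;
synthetic data needs none.

## Training and sampling

Each example drawn from a normalized stack: M planes at exact spacing Δz
(random admissible start; Δz must be an integer multiple of the grid step),
a target plane uniform over the full grid — including beyond the outermost
inputs — and one shared random lateral crop. Sequences are ordered by
acquisition depth by default ('by_abs_dz_desc' and 'random' are available).
Adam with initial learning rate 1e-5 at full scale; batch 4; 1:1 G/D
alternation; no augmentation by default; validation loss (the
non-adversarial α·BerHu + β·(1−MSSSIM)) on held-out stacks selects the best
checkpoint — the adversarial term is not a fidelity measure. The learning
rate is cosine-annealed to 10% over the run (disable with
`cosine_decay=False`). Checkpoints are single `.npz` files with the JSON
config embedded; save → load round-trips bit-exactly.

## Desk-scale study conditions

The instrument regime (Δz = 6 um against a 0.4 um DOF, 1024x1024 frames,
days of GPU training) is not reachable on one CPU in minutes, so the
package's self-contained study compresses the axial blur scale while
keeping the experiment's structure: bead phantoms (60 beads,
6.4 x 6.4 x 9 um at 0.1 um/pixel → 64 x 64 frames), σ0 = 0.15 um,
z_R = 1.0 um, M = 3 inputs at Δz = 3 um (z = 1.5, 4.5, 7.5 um), dense
ground truth every 0.25 um (37 planes), K = 3 scales with 8 base channels,
no GAN term, 500 steps at batch 8 with learning rate 1e-3 (cosine-annealed)
on 12 stacks, returning the best-validation weights. Sequences are ordered
by descending |dz| to the target, which routes the input nearest the target
through the decoder's residual path and learns markedly faster than
acquisition-depth ordering at this budget. These constants were fixed as a package-design choice: the blur at
the mid-gap distance (σ(1.5 um) ≈ 1.8·σ0 ≈ 2.7 px) is strong enough that
copying the nearest input is visibly wrong, yet small enough that a
few-hundred-step run can learn the DPM-conditioned correction. The
evaluation metric is
median PSNR over 20 held-out mid-gap planes (within ±0.5 um of the two gap
centres, two fresh test volumes) against the nearest-input-plane baseline.

## Inference

Each requested output plane is an independent sequence (recurrent state is
created fresh per forward pass, so no state leaks between reconstructions);
a volume is the plane-wise map over the requested grid. Images whose sides
are not divisible by 2^(K−1) are reflect-padded to the next multiple and
cropped back. The adaptive acquisition rule reconstructs after each added
input plane and stops at the first M with ‖V_M − V_{M−1}‖_F <= ε, the
Frobenius norm taken on normalized intensities (ε is therefore in
normalized units); with ε = ∞ it stops at the first comparison (M = 2), and
if the bound is never met it returns the stream length.

## Evaluation harness

NRMSE is RMSE normalized by the reference dynamic range, in percent (NRMSE
normalization conventions vary; the range-normalized percent used here is
stated explicitly so results are comparable across runs of this package). PSNR uses the same reference range as
peak; identical images report +inf. ROI-RMSE maps both images to the 0–255
display scale through an affine map in the reference's full range. Bead
FWHM: local maxima above `background + 0.2·(peak − background)`, plateau
ties within 2 px merged (pixel-integrated symmetric beads produce 2x2 tied
maxima), any pair closer than the exclusion radius (10 px) rejected
entirely, then a 1D Gaussian least-squares fit (centroid-seeded, ±7 px
window) along x and y; FWHM = mean of the two axes in um. Histogram KL
divergence uses shared bin edges (30 equal-width bins by default), add-1e-4
smoothing and renormalization; halving the smoothing changes well-populated
histograms by <1%. Permutation statistics enumerate all M! orderings
(capped, default 120), reconstruct each, and report per-plane mean and
population SD of ROI-RMSE plus the pixel-wise SD map; a permutation-blind
reconstruction gives σ_RMSE = 0 to machine epsilon. The DPM-noise stability
sweep draws one N(0, σ²) axial offset per input plane per trial (the whole
DPM shifts uniformly — equivalent to an unknown stage/sample drift), 50
trials per σ by default; σ = 0 reproduces the baseline bit-exactly. The
largest default σ of 1 um is 2.5x the emulated 0.4 um DOF.

## Numerical choices and degenerate inputs

Seeded `numpy.random.Generator` everywhere; identical inputs and seeds give
bit-identical phantoms, renders, draws and training runs (single-threaded
numpy). Ties in 'by_abs_dz_desc' ordering break by ascending z. Constant
images are rejected by the triangle threshold (degenerate histogram), empty
foreground/background by the normalizer, zero dynamic range by NRMSE/PSNR.
Max-pool backward splits gradient between tied maxima. The CLI derives
per-stage seeds as `(seed·1000003 + crc32(tag)) mod 2^31`.

## Known limitations

The Gaussian-defocus phantom cannot show that the network transfers to real
PSFs, aberrated optics or dense extended structures; the desk-scale network
(K = 3, 8 channels) is far below the full-scale capacity (K = 5, 20
channels) and its reconstructions are correspondingly soft; the GAN path is
implemented and tested for mechanics (scores, alternation, isolation) but
desk-scale quality results are reported for the non-adversarial objective;
training on one CPU limits batch and step counts, so reported desk-scale
numbers characterize this configuration, not the method's ceiling.
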