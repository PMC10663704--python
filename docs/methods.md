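# Methods

This note documents the models, parameter choices and numerical conventions
of the package, and what the synthetic experiments do and do not show.

## Synthetic phantoms

A phantom is an axis-aligned breast ellipse (default axes 0.44·size by
0.36·size, tissue intensity 150 with Gaussian texture σ=4, staying within
roughly 120–180) on a dark background (level 10, σ=1.5), 8-bit, default
256×256.  MIAS images are 1024×1024; the desk-scale default keeps every
stage fast while preserving the geometry, and is configurable.  Masses add
a tapered but strictly positive increment (peak contrast 60, falling 30%
toward the rim), so the ground-truth mask is exactly the set of incremented
pixels.  Benign masses are discs (radius default 20 px); malignant masses
are spiculated stars — a 0.75 r core plus cosine-lobe spikes reaching
1.3 r with 8 points, mirroring the circumscribed-vs-spiculated distinction
used in mammographic reporting.  An optional pectoral wedge cuts the
upper-left corner of the ellipse at intensity 185; it is off by default so
the brightest-segment heuristic is not distracted in the standard
experiments.  Each phantom carries nine cytology-style attributes drawn
from label-conditional Gaussians on the 1–10 scale (benign N(2.5, 1.2²),
malignant N(7.0, 1.2²), normal N(1.5, 0.8²), clipped), exercising the
nine-input classifier head.

What the phantoms do *not* emulate: parenchymal texture and vasculature,
calcification clusters, architectural distortion and asymmetry classes,
view geometry (MLO/CC), and scanner artifacts.  Passing results therefore
demonstrate the correctness and internal consistency of each algorithm
under controlled conditions, not clinical performance on real mammograms.

MIAS metadata coordinates use a bottom-left origin; the parser converts to
top-left rows via `y_internal = image_height − 1 − y` (default height 1024)
and the writer converts back, so a parse→format round trip is exact.

## Noise model and profiling

Salt-and-pepper noise replaces a `density` fraction of pixels by 0 or 255
with equal probability; Gaussian noise adds N(mean, σ²) and clips; Poisson
noise draws each pixel from a Poisson with the clean value as mean (direct
gray-level parameterization, no gain factor).

The profiler works from the 3×3 median-filter residual.  Its impulse
statistic counts pixels at exactly 0/255 that also deviate from their local
median by more than 50 gray levels — a raw extreme-value count is useless
on images with a true black background, where clipped additive noise also
produces exact zeros.  Decision order: salt-and-pepper when that fraction
exceeds 0.01; *none* when the residual variance is below 25 (σ=5 gray
levels — fluctuation weaker than restoration can improve); otherwise
Poisson when the bright-region residual power exceeds the dark-region one
by more than 4× (the signal-dependent, quantum-mottle signature), else
Gaussian.  A tile-correlation test for signal dependence was rejected:
breast texture lives only in the bright region, so local mean and local
variance correlate even on noise-free images.

## Denoising

Default: Haar wavelet, 2 levels, universal threshold
t = σ̂·sqrt(2 ln N) with σ̂ = median|d|/0.6745 from the finest diagonal
band; BayesShrink and fixed thresholds are available.  The energy

E(I) = Σ (1 + α²|∇I|² + γ²(I−I₀)²),  α = γ = 1

uses forward differences with replicate boundary (last row/column gradient
zero), making its values bit-stable.  The greedy search proposes one
operator per iteration with probability 0.9 (the local-search rate), for at
most 40 iterations, stopping after 10 consecutive rejections; acceptance
requires a strict decrease, ties reject.  The directional median operator
replaces pixels flagged by the four-level quantization rule (a pixel whose
64-wide brightness bin differs from ≥ 6 of its 8 neighbours) with the
median of the four neighbours at ±1, ±2 along a randomly chosen scan
direction (row, column, diagonal, anti-diagonal).

When the profiler reports *none*, denoising is an identity: the energy
objective always rewards lower total variation, so an unguarded search
erases fine spiculation from already-clean images.  Restoration is
therefore gated on detected noise.

Active-contour behaviour is realized only through the energy's
total-variation and fidelity terms; there is no explicit evolving-contour
solver.  The four-level quantization stands in for the 2-qubit
position/color encoding of the quantum formulation; everything is simulated
classically.

## Segmentation

Features are per-pixel (brightness/255, Sobel magnitude/max), after a 3×3
median despeckle.  Centers initialize at the K mid-quantiles of the
*distinct* brightness values (edge coordinate at the global mean):
quantiles of the brightness scale, not the pixel mass, because the heavily
bimodal mammogram histogram otherwise collapses several initial centers
into the tissue mode and Lloyd never separates a mass that covers ~2% of
the frame.  The procedure is deterministic; the fitness (summed squared
Euclidean distance) is non-increasing per iteration and the final
assignment is a nearest-center fixpoint.

Default K=5: background, tissue, mass interior, and two edge/texture
segments.  With only K=3 or 4, the high-Sobel halo of a spiculated mass
(and residual grain on restored images) absorbs the center the small mass
interior needs, and the "brightest segment" degenerates to the whole
breast.  ROI extraction opens the brightest segment with a disc of radius
2, keeps the largest 8-connected component, and reports *no mass* when
nothing survives opening **or** when the component covers more than 20% of
the frame (that is breast tissue, not a localized lesion).

Morphology lives on a finite frame: translations leaving the frame fail
the containment test, so erosion shrinks at borders; the erosion/dilation
duality therefore holds exactly on the interior (pixels whose translated
element stays inside) and is tested there.

## Classifier

The fixed feature stack uses 4 filters per bank (zero-mean 9×9 kernels,
scale 1/(k·√C)), sigmoid activation, non-overlapping pooling windows
(stride = window), and atrous rates {1, 2, 3, 4, 6, 9, 12} — fine to
coarse, including the identity rate so the dilated implementation can be
checked against plain convolution.  Stochastic pooling samples one
activation per 7×7 window with probability proportional to magnitude at
training time and uses the magnitude-weighted expectation at inference.
High dilation rates on the small post-pooling grid fall back to the few
in-bounds taps (replicate boundary); they contribute coarse-context
averages.

The head standardizes features, propagates them through two frozen random
dense layers of 10 and 2 units (weights N(0, 1/√d), biases U(−0.5, 0.5)),
and collects *both* layers' activations plus a bias column into the hidden
matrix G — a stacked-ELM formulation chosen because the 2-unit final layer
alone is rank-3 and cannot reliably separate the classes.  Training is the
single solve β = G⁺z (SVD pseudoinverse, cutoff 1e-10·σ_max; an all-zero
column warns and falls back to a ridge solve, λ=1e-6).  Scores are
softmax(Gβ); the three-way rule labels a case *suspicious* when the best
score is below τ (default 0.6).  The suspicious rate is monotone
non-decreasing in τ by construction.

## Dense CRF

Pairwise kernels follow the form k⁽¹⁾ = exp(−|Δs|²/θ_α² − |Δe|²/θ_β²),
k⁽²⁾ = exp(−|Δs|²/θ_γ²) — note the θ² (not 2θ²) denominators — with Potts
compatibility η = [yᵢ ≠ yⱼ] and weights w⁽¹⁾=1, w⁽²⁾=0.3; bandwidths
θ_α=5 px, θ_β=20 gray levels, θ_γ=3 px; 5 mean-field iterations.  Pairwise
sums are evaluated exactly (dense N×N kernel matrix, float32, spatial parts
cached per crop shape) for images up to 96×96; the pipeline refines a
64×64 crop centered on the ROI and pastes the result back.  Mean-field
iteration does not guarantee monotone MAP energy, so the refinement
returns the best-energy labeling among the unary argmax and every
iteration's argmax — it can never end above the initial energy.  The
energy is E(Y) = Σ −log P(yᵢ|I) + Σ_{i≠j} K_ij[yᵢ≠yⱼ] over ordered pairs.

Unary probabilities for refinement come from the clustering geometry: a
two-class softmax over squared feature distances to the mass center versus
the nearest other center, scale 0.08 feature units.

## Particle filter

Bootstrap filter with N=200 particles by default: initialization samples
pixel locations from the first score map (uniform fallback when it is all
zero), dynamics are a Gaussian random walk (σ=2 px, clipped to the frame),
the observation model is the score map smoothed by a two-dimensional
Gaussian (σ₁=σ₂=2 px) interpolated at each particle, weights are
normalized every frame, and systematic resampling follows each estimate
(the weighted particle mean).  Degenerate point-mass observations with
zero process noise recover the source pixel exactly because all particles
initialize on it.

## Evaluation conventions

PSNR uses peak 255; identical images report +inf, serialized as null.
Dice of two empty masks is 1.0 (an absent mass correctly found absent).
ROC curves come from a threshold sweep over unique scores (ties enter
together) with trapezoidal AUC; this equals the Mann–Whitney
concordant-pair statistic and is tested against that oracle.  Reports emit
both accuracy and positive predictive value under distinct names, and the
full 3-way confusion matrix alongside the binary one; for binary
sensitivity/specificity bookkeeping a predicted *suspicious* counts as a
positive prediction (the case is recalled, not cleared).  The splitter
stratifies by label (70/30 by default) and assigns 5 folds round-robin per
class; a class smaller than k warns and falls back to unstratified.

## Problem sizes

The packaged experiments use 256×256 phantoms; the end-to-end study uses a
200-phantom cohort (100 benign / 100 malignant), the denoising study 20
phantoms per noise family, and the particle-filter study 20 seeds at 50
versus 500 particles.  These sizes make the full pipeline run in a few
minutes on a single CPU while keeping every statistical check
well-powered.

## Known limitations

- Clustering is a deterministic single-init Lloyd descent: it reaches a
  valid local optimum of the K-means objective, typically within 2× of a
  multi-init solution, which suffices for mass recovery but is not a
  global optimizer.
- The dense CRF is exact but quadratic in pixels; crops beyond 96×96 are
  rejected rather than approximated.
- Segmentation of restored (previously noisy) images recovers masses
  reliably at the default noise levels, but heavier corruption degrades
  the brightest-segment heuristic before it degrades classification,
  since classification also uses the tabular attributes.
- Poisson-noise PSNR gains are modest (fractions of a dB): at tissue
  intensities near 150 the noise σ is ~12 and wavelet shrinkage removes
  only part of it without oversmoothing.
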