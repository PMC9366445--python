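# Methods

This note documents the models, parameter choices and numerical decisions
behind `pupanet`, and what the synthetic benchmark does and does not show
about real specimen data.

## Synthetic image model

Real *B. tabaci* puparia are elongate-oval larval cases whose taxonomic
signal is a subtle joint shift of outline shape and interior structure.
The generator emulates that statistical situation, not the anatomy, with a
closed-form shape family rendered on a white 8-bit field (128×128 by
default):

- **Body**: a superellipse |x/b|ᵉ + |y/a|ᵉ = 1 (long semi-axis a ≈ 0.40,
  short b ≈ 0.26 of the half-frame, exponent e ≈ 2.2), with a sinusoidal
  margin crenulation of amplitude ~0.02 and frequency ~12 lobes.
- **Interior**: radial shading, faint transverse striations, and a dark
  posterior Gaussian blob standing in for the vasiform orifice. The
  marginal rim (~4.5 px) and the orifice core are rendered fully black:
  real slide mounts have strongly sclerotized dark margins, and these
  pure-black anchors pin the image's low percentile at 0, which in turn
  makes the exposure-normalization step exactly idempotent on prepared
  images (see below).
- **Group effect**: each of the g groups shifts the 8-vector of shape
  parameters along a unit-norm direction drawn once per group from a
  seeded stream, scaled by a single effect size δ and a fixed per-parameter
  sensitivity vector. δ = 0 therefore makes images exchangeable across
  group labels; δ is a single interpretable knob for parameter-recovery
  tests.
- **Specimen jitter**: rotation (σ = 4°), scale (σ = 4%), brightness
  (σ = 4%) and additive interior pixel noise (σ = 3 gray levels). These
  defaults are calibrated so that δ ≈ 1 yields near-perfect separability
  and δ = 0 chance performance; they are not estimates of biological
  variation.
- **Substrate**: a deterministic ecophenotypic shift applied to all groups
  (glabrous leaves: 10% broader bodies, 40% weaker crenulation), mirroring
  the known dependence of puparial form on host-leaf hairiness.

Randomness uses one root `SeedSequence` spawned into independent substreams
for group directions and per-specimen jitter, so identical configs are
bit-identical and per-stage reproducibility holds.

What passing tests on this generator show: the pipeline's machinery —
preparation, pair enumeration, contrastive optimization, centroid
classification, jackknife, MANOVA — behaves correctly under controlled
group structure, recovers chance at δ = 0 and perfect discrimination at
large δ. What they do not show: that real puparial photomicrographs carry
a comparable signal; focus-stacking artifacts, staining variation,
mounting distortion and genuine biological shape distributions are not
modelled.

## Image preparation

The order-fixed chain is grayscale → exposure normalization → crop/frame →
step-down:

- **Von Kries grayscale** (colour sources only): sRGB linearization, the
  sRGB→XYZ matrix, Bradford cone responses, cone scaling from the source
  white (D65) to the adopted white point (D65 default, so the scaling is
  the identity), luminance extraction, gamma re-encoding. Achromatic
  pixels are fixed points up to the linearization round trip.
- **Exposure normalization**: a linear stretch mapping the 1st/99th
  percentiles to 0/1 (clipped), the automated surrogate for the manual
  brightness/contrast editing applied to the source photomicrographs.
  Constant images are returned unchanged with a warning.
- **Crop and frame**: tight bounding box of pixels below 0.98 of full
  white, centred on a square pure-white frame whose side is the larger box
  dimension. When the content already spans a square frame and is centred
  to within 1 px, recentring is skipped: the bounding box of a resampled
  image is only defined to the rasterization limit, and recentring inside
  that limit would jitter the raster by a pixel on re-runs.
- **Step-down**: exact area-average resampling to 28×28 via per-axis
  overlap-weight matrices; this preserves the image mean to float
  precision. Bilinear resampling is config-selectable. The published
  description of the resolution reduction is read as plain downsampling
  (deterministic and parameter-free), not a learned autoencoder.
- **Idempotence**: running the chain on an already-prepared image is an
  exact no-op provided its low/high percentiles already sit at 0/1 —
  guaranteed for the synthetic sets by the black rim/orifice and the white
  frame, and verified by test.

## Contrast engine

All n(n−1)/2 unordered pairs are enumerated (ordered enumeration is
available for bookkeeping, reproducing the published n(n−1) totals of
148,610 and 133,590). The published count of "unique contrasts" for one
training round is not reconstructible from any of n(n−1), n(n−1)/2 or
1863·64; the engine therefore defaults to all unordered pairs and exposes
a seeded, optionally class-balanced per-round subsample instead. Because
same-group pairs are a small minority of all pairs, balanced draws
(half same / half different per round) are the default for training.
Batch plans are seeded permutations cut into batches of 64; each round is
reshuffled.

## Network and training

The LeNet-5 variant follows the published layer table; the 4×4 kernel is
forced by the shape algebra (28−25+1 and 12−9+1). Pooling is max pooling
(the standard partner of rectifier ramps in modern LeNet variants);
average pooling is selectable. The parameter count for the 2-D embedding
head is 4,032.

Choices the source leaves open, fixed here:

- **Loss**: margin contrastive loss on embedding distance (m_c = 1.0) —
  the canonical realization of "maximize between-group, minimize
  within-group distances". Both pair members pass through one
  shared-weight network.
- **Optimizer**: Adam with η = 10⁻³ by default (plain SGD selectable);
  weights initialized uniformly at ±1/√fan_in from a seeded stream.
- **Precision**: training runs in float32 (the objective is insensitive to
  the trailing float64 digits and single precision roughly halves the
  time); gradient correctness is verified in float64 against central
  differences at 10⁻⁴ relative tolerance.
- **Error metric**: the training log records per-batch loss and periodic
  nearest-centroid training-set misassignment rate (the published "error"
  curve is not defined precisely; nearest-centroid error matches the
  stated decision criterion).
- **No early stopping**: the budget (rounds × pairs per round) is entirely
  config-driven.

Desk-scale problem sizes: the headline reproduction uses 15 groups × 20
specimens, δ = 2, and a budget of 4 rounds × 100 balanced batches of 64
pairs (25,600 presentations) — about a hundredth of the published budget —
which suffices for MCC = 1.0 on this synthetic set across seeds. The
jackknife retrains from scratch per holdout with the same budget, with
per-iteration seed offsets so iterations are independent but reproducible.

Degenerate inputs: training requires at least two groups and at least one
group with two or more specimens; singleton groups are tolerated (they
supply different-group pairs and a centroid) so that jackknife iterations
that empty a group remain well-defined — such iterations are flagged in
the report. Nearest-centroid ties are broken toward the lexicographically
first group label and flagged.

## Evaluation

The multiclass MCC uses the covariance (Gorodkin) form on the g×g count
table; on 2×2 tables it equals the classic binary formula (tested against
an independent implementation). A degenerate marginal (all predictions in
one class) yields MCC = 0 with a warning.

## Feature-space statistics

Wilks' λ = |E|/|E+H| and Pillai's V = tr H(H+E)⁻¹ are computed from
scatter matrices via `slogdet`/`solve`; a singular within-group scatter
falls back to a pseudo-inverse eigenvalue form with a warning (possible
with tiny groups in 2-D). An independent eigenvalue-based oracle
(θ = eig(E⁻¹H); λ = Π 1/(1+θ), V = Σ θ/(1+θ)) guards the implementation at
10⁻¹⁰. Rao's F approximation is used for λ and the standard Pillai F for
V; for p = 2 these force hypothesis dof 2(g−1) and error dof 2(N−g−1)
(Wilks) and 2(N−g) (Pillai), reproducing the published 28/740 and 28/742
for g = 15, N = 386.

The published "bootstrap" significance tests are implemented as
label-permutation tests — the natural nonparametric test of group
separation, with exact-level type-I control — using the add-one estimator
p = (1 + hits)/(n_perm + 1) so p is never 0. A within-group residual
resampling bootstrap is available behind a flag. t-SNE ordination
(perplexity × iteration grid, exact gradient, seeded) is delegated to
scikit-learn and applied both to raw flattened images (untrained space)
and to trained feature scores.

## Known limitations

- The synthetic shape family is stylized; results on it bound nothing
  about real image sets beyond pipeline correctness.
- The published real-data λ and F magnitudes depend on the original images
  and trained weights and are not reproduced here; only the degrees of
  freedom and the Pillai bound are analytically forced.
- The CNN is CPU-bound numpy; it is sized for hundreds of specimens, not
  thousands.
- Training determinism holds for fixed BLAS/numpy versions; bit-identical
  logs across different BLAS builds are not guaranteed.
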