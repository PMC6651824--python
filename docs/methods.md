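# Methods

## The problem

Mid-infrared (FTIR) absorbance spectra of plant tissue fingerprint the
underlying chemistry — O–H and C–H stretches above 2800 cm⁻¹, the crowded
fingerprint region below 1800 cm⁻¹, the dominant carbohydrate C–O band near
1023 cm⁻¹ — and closely related varieties differ only through subtle,
distributed amplitude changes in a few of those bands.  Two tasks follow:
classify a spectrum into one of C varieties, and find the small set of
wavenumbers that actually carries the discriminative signal, so that a
cheap filter instrument could measure only those.

The package implements a stacked sparse auto-encoder (SSAE) classifier for
the first task and a gradient-saliency selector (SSAE-GB, "guided
backward") for the second, together with the baselines both are
conventionally compared against: k-nearest neighbours and RBF-kernel SVM
classifiers, and PCA-loading and CARS variable selectors.

## Models

### Sparse auto-encoder layer

One layer is the sigmoid encoder/decoder pair `h = σ(W₁x + b₁)`,
`z = σ(W₂h + b₂)` trained to minimize

    L = ½ Σᵢ ‖zᵢ − xᵢ‖² + β Σⱼ KL(ρ ‖ ρ̂ⱼ),

where `ρ̂ⱼ` is the mean activation of hidden unit j over the training set
and KL is the Bernoulli divergence `ρ ln(ρ/ρ̂) + (1−ρ) ln((1−ρ)/(1−ρ̂))`
(natural log).  Defaults: target sparsity ρ = 0.05, penalty weight β = 3 —
conventional values for sigmoid sparse coders; both exposed.  Because the
decoder is a sigmoid, inputs must live in (0, 1): absorbance is mapped
per-wavenumber into [0.05, 0.95] by an invertible affine record fitted on
the calibration rows only (constant columns map to the midpoint).  Raw
absorbance is used for KNN/SVM/PCA/CARS, which have no such constraint.

### Stack, softmax, fine-tuning

Layers are pretrained greedily (each SAE reconstructs the previous hidden
code), decoders are dropped, and a softmax read-out
`P(y=j|x) ∝ exp(θⱼᵀf)` is attached to the deepest code `f` (bias via an
appended constant-1 feature).  Fine-tuning minimizes the multinomial
cross-entropy plus `(λ/2)‖θ‖²` (λ = 1e-4, applied to θ only — the decay
term in the objective penalizes the classifier parameters, not the encoder
weights; the sparsity penalty is not part of the supervised objective) and
backpropagates through every encoder layer, so the whole network moves.

### Optimization

Full-batch first-order gradient descent with classical momentum
(default 0.9) on analytic gradients; the step is scaled by 1/m so the
default learning rate (0.1) has the same meaning at any training-set size.
Momentum matters: on the noisier fixtures plain descent needs several
thousand epochs to leave the `ln C` plateau, momentum cuts that by roughly
an order of magnitude without changing the objective.  Gradients of every
block are verified against central finite differences (relative error
≤ 1e-5) in the test suite.  Mini-batch mode exists but approximates `ρ̂ⱼ`
by an exponential moving average (decay 0.99) and is flagged as such;
full batch is the default because the sparsity term is defined through the
full-training-set mean activation.

Divergence (non-finite loss) raises an error naming the epoch and learning
rate.  With sigmoid activations and the clamped KL term the reconstruction
objective is bounded, so in practice only supervised fine-tuning can reach
non-finite territory (mixed-sign overflow in the softmax scores).

### Guided-backward saliency (SSAE-GB)

For sample i with true class yᵢ the gradient of the cross-entropy w.r.t.
the softmax input collapses to `p − e_{yᵢ}` (predicted probabilities minus
the one-hot target); chaining through θ and every sigmoid encoder layer
yields `∂loss/∂x`, a per-wavenumber score of how strongly a small
absorbance change would move the classifier's loss.  The fused form is
exact and needs no clamping of small probabilities.  The softmax-input
Jacobian itself is implemented in the stable product form
`Pⱼ(θⱼ − Σₗ Pₗθₗ)` and cross-checked against finite differences and
against the expanded quadratic-normalizer expression (with the exponent
read as `(θⱼ+θₗ)ᵀx`, which is what makes the expansion a correct
derivative of the softmax).

Aggregation across samples is a genuinely open choice; the default is
**per-class signed mean, then the elementwise maximum over class
magnitudes** (sign of the winning class kept).  Rationale: with 13 classes
the global signed mean cancels class-opposite gradients, collapsing the
curve onto one or two bands and starving the selection; the per-class
aggregation keeps every class's salient wavenumbers.  Global signed mean
and mean-absolute remain selectable.  A softmax-only mode
(`softmax_feature_saliency`) stops the backward pass at the deepest code,
for comparing "what the classifier weights say" with the full chain.

Selection: normalize the curve to max |value| = 1 (all-zero stays zero;
normalization is idempotent), then keep indices that are local maxima of
the magnitude curve (plateaus keep their leftmost point) with
|value| > threshold (default 0.5) — the "strong peaks and valleys" rule.
Raising the threshold can only remove indices.

### Baselines

- **KNN**: Euclidean, k searched over 3..20 by mean held-out accuracy
  across the three folds.  The vote is hand-rolled for deterministic
  tie-breaking: tied classes resolve to the one whose nearest
  representative is closest, then to the smaller class index.
- **RBF-SVM**: one-vs-one SVC over the 17×17 grid c, g ∈ {2⁻⁸..2⁸}
  (integer exponents; ties toward smaller c then g).
- **PCA-loading**: score each wavenumber by its largest |loading| over the
  first 6 mean-centered principal components (no variance scaling —
  absorbance shares units across the axis); keep the top-n local maxima of
  the score curve, ties toward the higher wavenumber; if fewer local
  maxima exist than requested the restriction is dropped and the result
  carries a note.
- **CARS** over a from-scratch SIMPLS PLS core, classification cast as
  one-hot multi-response regression.  Per Monte-Carlo run: fit PLS on a
  random 80% row subsample of the surviving variables; weight each
  variable by the **standardized** coefficient magnitude |bⱼ|·sd(xⱼ) (raw
  |bⱼ| is scale-dependent and lets near-constant noise-floor columns win);
  retain the top `rᵢ·P` by weight, where `rᵢ = (P/2)^(−(i−1)/(N−1))`
  decays from 1 (run 1) to 2/P (run N); the retained set is drawn without
  replacement in proportion to the weights (an exhaustive draw — the
  competition between variables comes from each run's row subsample
  re-ranking the weights); score each run's set by pooled RMSECV (5-fold
  PLS cross validation); return the minimum-RMSECV run's set.  Defaults
  n_runs = 50, max 10 latent components.
- **t-SNE** is wrapped (scikit-learn), perplexity capped below N/3 —
  visualization only.

### Reporting

The three-fold protocol: per fold, the two training folds are the
*calibration set* and the held-out fold the *prediction set*; accuracies
are reported per fold and as the fold mean, in percent.  `knn_cv` and
`svm_grid` choose one hyperparameter setting from the mean held-out
accuracy over the outer folds — the single-k / single-(c, g) reporting
style of classical chemometric tables.  `table_report` is the
leakage-free variant: within each fold the hyperparameter is searched by
an inner 3-fold cross validation on calibration rows only (a
poisoned-held-out-labels test asserts the chosen settings cannot depend on
prediction rows).  Folds are stratified (per-class counts differ by ≤ 1)
and deterministic in (labels, K, seed).

## Synthetic data

No public spectra accompany the study design this package mirrors, so the
generator is a first-class module.  Each spectrum is a sum of Gaussian
bands on a per-sample linear baseline plus i.i.d. noise:

    x(ν) = Σ_b A_b · exp(−(ν−c_b)²/2σ_b²) + offset + slope·(ν−ν_min) + ε

with the eight canonical leaf-tissue band centers
{3322, 2924, 2849, 1620, 1417, 1369, 1237, 1023} cm⁻¹, a broad O–H stretch
(σ = 120 cm⁻¹) and narrow fingerprint bands (σ = 15–30 cm⁻¹), and the
largest base amplitude at 1023 cm⁻¹.  Five bands (3322, 1620, 1417, 1237,
1023) are class-informative: `A_b = base_b(1 + e·δ[class, b])` with a fixed
per-class pattern δ ~ U(−1, 1) drawn once from the seed and effect size
e = 0.5.  Every band also gets per-sample multiplicative jitter
(sd 0.05, biological/preparation variability), and the non-informative
bands get extra jitter (sd 0.2) emulating specimen chemistry — moisture,
surface wax — that varies without separating classes.  Defaults:
13 classes × 30 samples, 7157 axis points spanning 4000→550 cm⁻¹
(descending), noise sd 0.01 absorbance units, baseline offset U(0, 0.05)
and slope ±6e-6 per cm⁻¹.  Ground truth for selection scoring is every
axis index within ±2σ of an informative band center (saliency spreads over
a band, not a grid point); generation is bit-deterministic in the seed.

What the generator does **not** emulate: Lorentzian/Voigt line shapes,
multiplicative scatter, instrument apodization and interferogram effects,
atmospheric CO₂/H₂O lines, wavelength-dependent noise.  Passing tests
therefore demonstrate that the algorithms behave as designed on
band-structured, class-modulated signals — not that any particular
accuracy will transfer to real tissue spectra.

## Test fixtures and problem sizes

Desk-scale sizes keep the full suite tractable: reduced axes of 400–1000
points (the methods are dimension-agnostic; the saliency and selection
rules operate per grid point), stacks of (64, 13) hidden units, 13 × 30
samples, pretraining 150 epochs at rate 0.2 and fine-tuning 1000 epochs at
rate 0.1 with momentum 0.95.  Two deliberately "noisy" fixtures probe the
classical failure modes:

- **Baseline-drift fixture** (ordering): offsets U(0, 0.25), slopes
  ±4e-5/cm⁻¹, noise 0.02, amplitude jitter off so that drift is the only
  structured nuisance.  Uncorrected baseline drift is a 2-D nuisance
  subspace: margin-based and fine-tuned models project it out, raw
  Euclidean KNN cannot — reproducing the canonical SSAE ≥ SVM > KNN
  ordering.  Each fixture isolates one nuisance mechanism; stacking both
  mechanisms at once mainly probes the optimizer's budget rather than
  either phenomenon.
- **Nuisance-chemistry fixture** (selection gain): five extra
  non-informative minor bands (1731, 1550, 1150, 895, 815 cm⁻¹) with
  strong per-sample jitter (sd 0.6) on a 1000-point axis, noise 0.05.
  The structured nuisance variance drowns full-spectrum KNN distances;
  restricting to the guided-backward selection excises it, so
  selection-restricted KNN beats full-spectrum KNN.  Plain i.i.d. noise
  does not reproduce this effect (removing noise columns also removes
  band-support redundancy that KNN averages over), which is why the
  fixture carries structured nuisance instead.

The CARS recovery fixture follows the regression framing of the method:
200 standard-normal variables, 10 planted with 10× coefficients, labels by
terciles of the latent response; recovery is the fraction of planted
variables retained in the minimum-RMSECV set.  (A precision reading is
unattainable by construction: the RMSECV minimum legitimately sits at sets
larger than the planted support, since pruning below it discards real
signal.)

## Numerical choices

- Sigmoid evaluated in the two-branch stable form; softmax with
  max-subtraction; `ρ̂` clamped to [1e-10, 1−1e-10] inside the KL term.
- Weight init U(−r, r), r = init_scale·√(6/(fan_in+fan_out)); biases zero;
  softmax θ initialized to zeros (uniform initial probabilities).
- Argmax ties at prediction go to the smallest class index; plateau ties
  in extremum detection to the leftmost grid point; equal PCA-loading
  scores to the higher wavenumber; equal CV accuracies to the smaller
  hyperparameter.
- CSV round-trips are written at %.17g, reproducing float64 exactly;
  the wavenumber axis is stored descending and re-ordered on read.
- Models serialize to a single JSON container (arrays as nested lists) —
  adequate at these model sizes and keeps every artifact text.

## Known limitations

- Batch gradient descent with momentum is sensitive to the learning rate
  on hard fixtures; there is no line search or adaptive scheme, by design
  (the training procedure itself is part of what is being specified).
- The guided-backward curve is computed on training data; selections are
  not themselves cross-validated (matching how such selectors are used in
  the source protocol).
- PCA-loading on raw spectra with baseline drift legitimately spends
  loadings on the drift ramp; no baseline correction is applied anywhere
  because the modeled protocol states none.
- CARS results depend on the Monte-Carlo seed; only the seeded form is
  reproducible.
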