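# Methods

## Scope and model

`immunonet` implements a multi-class diagnostic classifier for tabular
clinical data together with the full experimental protocol around it. The
classifier composes four stages — 1-D convolution over the feature vector, a
gated recurrence over ordered segments of the convolutional map, a
feature-topology refinement, and a softmax head — and six ablation variants
that toggle the convolutional, recurrent and topology stages.

Because the feature vector of a patient record has no natural spatial order,
the convolutional stage is a modelling convention, not a claim about
locality: the preprocessed vector (scaled continuous features followed by
one-hot blocks, in a fixed documented order) is treated as a length-F,
single-channel signal. The recurrent stage consumes the conv map chunked
into `n_segments` ordered slices (default 5); when longitudinal data from
`make_visits` are supplied, visits form the sequence instead. The final
dense layer produces the feature vector `x_L` (dimension D = `feat_dim`,
default 32, matching the recurrent hidden size).

### Topology refinement

The learned adjacency assigns one weight vector `w_ij ∈ R^D` to every ordered
feature pair and computes `a_ij = ReLU(w_ij · x_L)`; the head consumes
`concat(A·x_L / D, x_L)`. Two numerical choices matter:

- **1/D normalization of the refined features.** Row sums of a non-negative
  D×D adjacency grow linearly with D, so the raw product `A·x_L` is roughly D
  times larger than `x_L`; with a shared learning rate this imbalance
  dominated the head and slowed convergence. Dividing by D puts both halves
  of the concatenation on the same scale (the same reasoning as degree
  normalization in graph convolutions).
- **Which layer feeds the adjacency.** The adjacency is computed from the
  final feature layer `x_L` — the representation the head actually consumes —
  rather than from an intermediate conv map.

The correlation-mode adjacency (`a_ij = |Pearson(x_i, x_j)|` across the
batch, diagonal 1) is provided as the non-learned alternative; it is treated
as a constant during backpropagation (gradients flow through `x_L` only).

### Dropout placement

Dropout at the configured rate p (default 0.5) is applied to the classifier
head's input (after the topology concatenation) and to MLP hidden
activations — the conventional dense-layer placement. Applying p = 0.5 to
convolutional feature maps and to the topology input was tried and rejected:
the adjacency is quadratic in `x_L`, so inverted dropout no longer unbiases
the inference-time forward pass, and validation loss plateaued early with
held-out accuracy several points below variants trained without it.

### Training

The objective is mean cross-entropy plus `λ·Σw²` over weights (biases
exempt); its gradient contributes `2λw`. Defaults follow the experimental
configuration the protocol fixes: learning rate 0.001, batch 64, up to 100
epochs, dropout 0.5, λ = 1e-4, Adam (β₁, β₂, ε) = (0.9, 0.999, 1e-8), Xavier
uniform initialization with bound √(6/(fan_in+fan_out)) and zero biases.
SGD with momentum 0.9 is the selectable alternative. Early stopping watches
validation loss with patience 10 and restores the best epoch's weights. The
last incomplete mini-batch is kept. A non-finite loss aborts with the
epoch/batch in the message. All gradients are computed by a small tape-based
reverse-mode engine over numpy arrays; every layer's gradient is checked
against central finite differences in the test suite.

## Synthetic cohorts

The generator emulates a cross-sectional autoimmune-disorder registry: 13
predictors (demographics, vitals, blood counts, inflammation markers) and a
disease label drawn i.i.d. from the documented mix (RA 25%, SLE 18%, MS 15%,
T1D 12%, psoriasis 10%, IBD 8%, Sjögren 7%, other 5%), 52% women, ages
uniform on 18–80. Continuous biomarkers come from truncated normals with
physiological baselines (e.g. CRP mean 8 ± 6 mg/L on [0, 200]); symptom
count is Poisson (base rate 4).

Learnable signal has two components, both scaled by one `effect_size` knob:

- **Mean shifts.** Each class shifts the means of (CRP, ESR, WBC, symptom
  count) by `effect_size × signature × sd`, with fixed documented per-class
  signatures; inflammation markers carry the largest shifts, consistent with
  their known role in disease activity.
- **Correlation structure.** Each class imposes a pairwise correlation
  pattern on the latent normals behind (CRP, ESR, WBC) — e.g. tightly
  coupled CRP/ESR in RA, anti-coupled CRP/WBC in IBD — applied through a
  Gaussian copula so the truncated-normal marginals (and hence the mean-shift
  contract) are exact. The pattern strength is `min(effect_size / 3.5, 1)`,
  so `effect_size = 0` leaves every predictor independent of the label
  (verified by contingency-table chi-square in the tests). This component
  exists because the topology stage is explicitly a model of inter-feature
  relationships; a generator with only mean shifts would leave it nothing to
  detect, and any dense network would already be near Bayes-optimal.

`effect_size = 1` (default) is a deliberately hard, overlapping mixture;
`HIGH_EFFECT_SIZE = 3.5` is the documented high-signal regime where the
linear-model ceiling is ≈93% and correlation contrasts are at full strength.
Missingness is MCAR, injected per predictor cell at a configurable rate; the
label is never masked. Visit expansion adds a Gaussian random walk (step =
`drift` × sd per visit) to continuous biomarkers with the label held fixed —
a modelling device for exercising the recurrent stage, since the emulated
data are cross-sectional.

What passing tests on these cohorts shows: the pipeline recovers planted
class-conditional structure of the stated kind and size. What it does not
show: performance on real registries, whose missingness is informative,
whose features are not truncated-normal, and whose class boundaries are not
captured by mean shifts plus pairwise correlations.

## Preprocessing

Statistics are fitted on the training partition only: mean (or median or
k-NN) imputation for continuous features, mode for categorical; winsorization
at |z| > 3 (configurable) using training mean/sd; min-max scaling to [0, 1]
with out-of-range values clipped; lexicographically ordered one-hot levels,
unseen categories encoding to an all-zero block with a warning. A constant
training feature maps to 0. The stratified 80/10/10 split allocates within
each class by largest-remainder rounding (ties toward the earlier partition),
so per-class counts are within one sample of exact proportionality; classes
with fewer than 3 members fall back to training with a warning. SMOTE runs
after the split on training data only (resampling before splitting would
leak synthetic copies of test points): each minority class is oversampled to
the majority count with `x + λ(x_nn − x)`, λ ~ U[0,1], x_nn among the k = 5
nearest same-class neighbours (k is reduced when a class is smaller than
k + 1).

## Evaluation protocol

Per-class precision, recall and F1 derive from the confusion matrix with the
harmonic-mean formula; macro averages (unweighted class means) are the
default so rare diseases count equally; weighted averaging is available. In
rendered comparison/ablation tables the F1 cell is the harmonic mean of the
row's printed precision and recall — the convention the published table
format implies — whereas `MetricsReport.f1` is the standard macro-F1.
AUC-ROC is one-vs-rest per class with midrank tie handling; AUC-PR uses the
conservative step-curve (no linear interpolation); both are macro-averaged,
skipping classes without the required positives/negatives with a warning.
Multi-run comparison reports mean accuracy ± t-based 95% CI per model and a
two-sided paired t-test against the reference over run-wise differences;
zero-variance differences use the degenerate conventions p = 1 (zero mean)
or p = 0 with a flag (nonzero mean). Feature attribution is permutation
importance — drop in accuracy when a source feature's columns (one-hot
blocks jointly) are permuted, averaged over seeded repeats — with a hook
point for plugging in SHAP/LIME-style explainers. Baseline comparators (SVM,
random forest, k-NN, logistic regression, MLP) are scikit-learn estimators
behind a uniform adapter: they are comparators, not contributions.

## Problem sizes in the tests

The end-to-end recovery test trains the full and MLP-only variants on an
n = 10,000 high-signal cohort for up to 60 epochs (patience 20) over five
paired seeds; unit and property tests use cohorts of 200–2,000 rows and
100,000 rows for marginal checks. All randomness is seeded; the slow
end-to-end fixture is deterministic given its fixed seeds.

## Known limitations

- The tabular-CNN and segment-LSTM conventions are modelling devices; the
  architecture's relative merits on real clinical tables are not established
  by the synthetic benchmarks.
- Learned-mode adjacency costs O(D²·D) parameters (D³ = 32,768 at the
  default D = 32); much larger D would need a factorized parameterization.
- Correlation-mode topology requires batches of ≥ 2 rows and treats the
  adjacency as constant in the backward pass.
- The k-NN imputation path queries only rows complete in the remaining
  continuous features and falls back to the mean value otherwise.
- No learning-rate schedules, no GPU path, no federated or distributed
  training.
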