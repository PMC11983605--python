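# immunonet

A hybrid deep-learning classifier for tabular clinical data, built around the
diagnosis of autoimmune disorders (rheumatoid arthritis, lupus, multiple
sclerosis, type-1 diabetes, psoriasis, IBD, Sjögren's syndrome) from routine
clinical and laboratory features. The package bundles the complete
experimental protocol — synthetic cohort generation, leak-free preprocessing,
training, multi-model statistical comparison, ablation, and feature
attribution — so the whole pipeline runs end to end with no external data.

## The model

A patient record of F preprocessed features is treated as a single-channel
1-D signal. The network stacks:

1. **Convolutional layers** `Z^l = W^l * X^{l-1} + b^l` (stride 1, same
   padding) extracting local feature patterns, with element-wise activation
   `X^l = f(Z^l)` (ReLU by default).
2. **A recurrent stage** (LSTM, GRU selectable) over ordered segments of the
   convolutional feature map — or over per-patient visit sequences when
   longitudinal data are supplied — returning the last hidden state.
3. **Topology refinement**: a learnable feature-by-feature adjacency
   `a_ij = ReLU(w_ij · x_L)` over the final feature vector `x_L`; the refined
   features `A·x_L/D` are concatenated with `x_L`. A correlation-based
   adjacency (`a_ij = |corr(x_i, x_j)|`) is available as an alternative.
4. **Softmax head** `y = softmax(W_out · concat(A x_L, x_L) + b_out)` over
   the K disease classes.

Training minimizes cross-entropy plus an L2 penalty (λ·Σw²) with Adam (or
SGD + momentum), Xavier initialization, seeded mini-batches, and early
stopping on validation loss. Six ablation variants toggle the three stages
(full, CNN-only, CNN+LSTM, CNN+topology, LSTM-only, MLP-only).

The network, including reverse-mode gradients for every layer, is implemented
in numpy and gradient-checked against finite differences in the test suite.

## Worked example

```python
from immunonet import (
    CohortSpec, generate_cohort, prepare_datasets, build_variant,
    Hyperparams, initialize, train, evaluate, permutation_importance,
)
from immunonet.cohort import HIGH_EFFECT_SIZE

spec = CohortSpec(n=4000, seed=0, effect_size=HIGH_EFFECT_SIZE)
cohort = generate_cohort(spec)                      # 4,000 synthetic patients
train_fm, val_fm, test_fm, state = prepare_datasets(cohort, seed=0)

cfg = build_variant("full", train_fm.X.shape[1], len(train_fm.class_names), seed=0)
ts = train(cfg, initialize(cfg, 0), (train_fm, val_fm),
           Hyperparams(epochs=40, patience=10, seed=0))
report = evaluate(ts.model, test_fm)
print(f"held-out accuracy: {report.accuracy:.1f}%")
imp = permutation_importance(ts.model, test_fm, n_repeats=5, seed=0)
print(imp.table.head(4).round(4).to_string(index=False))
```

Output:

```
held-out accuracy: 88.4%
      feature  importance    std
          wbc      0.3241 0.0147
          crp      0.3141 0.0045
          esr      0.2854 0.0194
symptom_count      0.1472 0.0148
```

The classifier recovers the signal planted by the generator: the four
biomarkers that carry class-conditional structure (white blood cell count,
C-reactive protein, erythrocyte sedimentation rate, symptom count) rank first
in permutation importance, and held-out accuracy is far above the 25% majority
class. Larger cohorts (n = 10,000) with the same settings reach ~94%.

## Command line

```bash
immunonet --seed 0 --outdir out simulate           # write a cohort CSV
immunonet --outdir out train    --cohort out/cohort.csv --variant full
immunonet --outdir out evaluate --cohort out/cohort.csv --model out/model
immunonet --outdir out ablate   --cohort out/cohort.csv --runs 5
immunonet --outdir out compare  --cohort out/cohort.csv --runs 5
immunonet --outdir out explain  --cohort out/cohort.csv --model out/model
```

`compare` trains the full model against scikit-learn baselines (SVM, random
forest, k-NN, logistic regression, MLP) over repeated seeded runs and reports
mean accuracy ± 95% CI with paired t-tests. `ablate` produces the six-variant
ablation table. Every command accepts `--config config.yaml` and writes a JSON
manifest for reproducibility.

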