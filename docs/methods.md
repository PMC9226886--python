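# Methods

## Model

Respondents `T` and questionnaire items `Q` (k = 106 in the default
bank) form an undirected bipartite graph. Raw answers are integer codes
(binary items 0/1; ordinal items 0..L−1 in increasing severity /
decreasing agreement). Each item's codes are standardized on the
**training respondents only** — z-score with the population SD by
default, min-max with clipping to [0, 1] as an alternative — and the
standardized matrix `A*` supplies the edge weights: one weighted edge
per (respondent, item) pair. Degenerate training columns (constant
answers) get scale 1 and therefore contribute zero-weight edges;
uninformative items vanish from the graph rather than producing
divisions by zero.

Node features are `P = [I_k; 0]`: items carry one-hot identities,
respondents carry nothing. All respondent information therefore enters
through propagation, which is why the convolution depth must be even:
layer 1 moves respondent-side information into item embeddings, layer 2
returns it to respondent nodes. The classifier is

    H1 = ReLU(Â P Θ0)        Θ0: k×80
    H2 = ReLU(Â H1 Θ1)       Θ1: 80×30, dropout p=0.5 on H1 (train only)
    logits = H2[respondents] W + b,   log-softmax → NLL loss

trained full-batch with Adam (lr 1e-2, β = 0.9/0.999, ε = 1e-8) for 200
epochs by default. Dropout is inverted (activations rescaled by
1/(1−p) at train time) so evaluation needs no correction. Gradients are
derived by hand in numpy and verified against central finite differences
(1e-5 relative) in the test suite. Glorot-uniform initialization, seeded;
every train/predict path is deterministic given the config seed.

### Adjacency normalization

`Â = D̃^{-1/2}(W + I)D̃^{-1/2}` with self-loop weight 1. Degrees use
absolute edge weights (z-scored weights can be negative; degrees must
stay positive). The degree convention is the package's own design and
matters more than it looks:

- **mean (default)**: `d̃_v = 1 + mean_u |W[v,u]|`, the mean over the
  opposite node set. Item degrees are then independent of how many
  respondents are in the graph.
- **sum**: `d̃_v = 1 + Σ_u |W[v,u]|`, the classic renormalization.
  Item degrees grow linearly with the respondent count, so hidden
  activations scale like n^(−3/2).

The sum convention couples the network's activation scale to the
training-graph size: a model trained on ~1000 respondents is badly
mis-scaled on a 253-respondent test-only graph, which is exactly the
situation inductive prediction creates. The mean convention makes the
propagation operator scale-stable across batch sizes, and with it the
inductive test accuracy matches transductive evaluation of the same
model. Both conventions are exposed (`normalize_adjacency(..., degree=)`).

### Inductive prediction

`predict()` builds a fresh bipartite graph from the test respondents
alone, reusing the training standardizer and frozen parameters, and
resolves exact probability ties to "healthy" (label 0) so the
conservative default is explicit. Item-node degrees still depend weakly
on the composition of the prediction batch (the mean absolute weight of
the batch), so predictions for a respondent can differ marginally across
batches; a regression test pins behavior for a fixed batch.

## Baselines

LR (SGD, L2, constant lr 1e-3), RBF-SVM (C = 1, γ = 0.007), a dense
(80, 30) network under Adam ("ANN") and the same architecture under SGD
lr 1e-3 ("CNN" — the comparison literature's label for what is, by its
stated layer sizes, a dense net; no convolution geometry exists to
implement), and a transductive GCN on a respondent-only cosine k-NN
similarity graph (k = 10 by default, weights clipped at 0, union
symmetrization). All consume standardized answer rows fitted on training
data only.

## Synthetic cohorts

The generator emulates a screening survey with a latent crisis class:
labels are primitive (not a score threshold), severities
`θ ~ N(μ_y, 1)` with μ₀ = 0 and μ₁ = 1.5 by default, cohort sizes
265 positive / 1000 negative. Ordinal items follow the graded response
model, binary items the 2PL, with discriminations `a_j ~ U(0.8, 2.0)`
and thresholds evenly spaced inside [−1, 2]; 25% of the binary items are
lie-scale-like nulls (a_j = 0, answers independent of θ). A sum-score
over the informative items reaches AUC > 0.8 under the defaults, so the
benchmark is learnable.

**Class overlap bounds attainable accuracy.** Responses depend on the
label only through θ, so no classifier can beat the Bayes rule on θ.
At μ₁ = 1.5 with the 265:1000 prior the Bayes decision is θ > 1.635 and
the optimal accuracy ≈ 0.843 — the default cohort is a *moderate*,
realistic screening problem, not a separable one. Benchmarks that ask
"does the classifier work when the items discriminate strongly" use
`strong_discrimination_config()` (μ₁ = 3.0, Bayes accuracy ≈ 0.95);
that condition is what the acceptance benchmark and the model-quality
tests run, at the default 1265 × 106 size with three to five seeds —
sizes chosen so the whole suite trains dozens of models in about a
minute.

What the generator does **not** model: multiple correlated latent
traits, item wording/order effects, response styles, missing answers.
Passing benchmarks show the pipeline recovers a single well-specified
latent signal under class imbalance; they do not certify performance on
real survey data.

**Null cohorts** (μ₁ = μ₀) provide a leakage guard: no classifier's
median test accuracy may exceed the majority-class floor (200/253 ≈
0.7905) by more than 3 points. The guard is one-sided by design:
classifiers that overfit pure noise land *below* the floor at test time
(their test positive-rate approaches the prior while predictions are
uninformative — the BGCN and the dense nets lose 5–12 points this way),
which is the expected behavior of unregularized models on noise, not a
defect the guard is meant to catch.

## Numerical and design choices

- Positive class is "crisis" everywhere; precision/recall/F1 refer to it.
- Zero-denominator metrics are 0, not NaN, so all-negative predictors
  tabulate.
- Split counts round half-up per class (20% of 265 → 53, of 1000 → 200);
  tables print 4 decimals.
- Epoch count (200), ReLU activations, Glorot initialization and the
  absence of weight decay are explicit package defaults — the
  architecture literature this follows typically leaves them unstated.
- Class weighting is off by default despite the 265:1000 imbalance;
  inverse-frequency weights are available behind `class_weight="balanced"`.
- Likert tokens map agreement-descending ("strongly agree" = 0); the
  orientation is stored per item in the schema so either direction can
  be declared.
- Missing answers are rejected, never imputed: the graph construction
  requires exactly one edge per (respondent, item) pair.
- EPQ-like subscale tags default to blocks E = 21, N = 24, P = 20,
  L = 20 (an 85-item split consistent with the instrument's structure);
  tags are metadata only and do not affect the model.

## Known limitations

- The bipartite convolution is depth-2 only in practice; deeper even
  stacks are supported but untested beyond unit level.
- Full-batch dense linear algebra: memory grows as (k+n)², fine for
  thousands of respondents, not for hundreds of thousands.
- Inductive predictions depend weakly on prediction-batch composition
  (see above).
- Synthetic benchmarks cannot reproduce any published survey's exact
  metric values; comparisons on them measure relative, not absolute,
  performance.
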