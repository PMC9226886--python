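# bgcn-screen

Recognizing questionnaire respondents in psychological crisis with a
**bipartite graph convolutional network (BGCN)**.

Mental-health screening instruments (a depression inventory plus a
personality questionnaire — 106 items in the default bank) produce an
answer matrix `A` (respondents × items, integer codes). Classical
practice scores the scale and thresholds it; this package instead treats
items and respondents as the two node sets of an undirected bipartite
graph `G(Q, T, E, W)` whose edge weights are the per-item standardized
answers `A*`, and classifies respondent nodes with a graph convolutional
network:

- node features `P = [Q ∥ T]` with item features `Q = I_k` and
  respondent features `T = 0`;
- an **even** number of convolutions `H' = σ(Â H Θ)` (default two, hidden
  widths 80 and 30) so respondent information travels to item nodes and
  back — with zero respondent features an odd depth leaves respondents
  unrepresented;
- `Â = D̃^{-1/2}(W + I)D̃^{-1/2}` with degrees built from mean absolute
  edge weights so the propagation scale does not depend on cohort size;
- dropout 0.5 between the convolutions, a softmax head on respondent
  rows, full-batch Adam (lr 1e-2) minimizing the negative
  log-likelihood.

Because item nodes and their learned filters are fixed, **unseen
respondents are classified inductively**: their answers form a fresh
bipartite graph over the same items and the frozen parameters are
applied — no retraining, unlike a transductive GCN on a
respondent-similarity graph.

The package also ships the comparison baselines (logistic regression,
RBF-SVM, two dense networks, a transductive similarity-graph GCN),
stratified splitting and imbalance-aware metrics, and an item-response
-theory cohort simulator (graded response model for ordinal items, 2PL
for binary, lie-scale-like null items) that stands in for survey data
that cannot be shared.

## Worked example

Simulate a 1265-respondent cohort (265 crisis / 1000 healthy, strongly
discriminating items), train the BGCN and every baseline on the 80%
stratified training split, and evaluate on the held-out 53 + 200
respondents:

```sh
cat > benchmark.yaml <<'YAML'
synthetic:
  mu_positive: 3.0
YAML
bgcn-screen benchmark --config benchmark.yaml --seed 0 --out bench/
```

which prints (seed 0):

```
Method  Accuracy  Precision  Recall  F1
BGCN    0.8933    0.6857     0.9057  0.7805
LR      0.8933    0.7241     0.7925  0.7568
SVM     0.9289    0.8182     0.8491  0.8333
ANN     0.8972    0.7368     0.7925  0.7636
CNN     0.9170    0.7759     0.8491  0.8108
GCN     0.9328    0.8000     0.9057  0.8496
```

All metrics refer to the positive (crisis) class on the 253-respondent
test set; the majority-class floor here is 200/253 ≈ 0.7905. On
synthetic cohorts the methods are closely matched — the BGCN's
distinguishing property is the highest recall alongside inductive
prediction (the transductive GCN row requires test respondents inside
the training graph). Relative improvements in the style of published
comparisons come from
`evaluation.relative_improvement(new, reference)`; e.g.
`relative_improvement(0.9047, 0.7869) == 14.97` (percent).

The same workflow is available step-by-step (`bgcn-screen simulate`,
`train`, `predict`) or as library calls
(`bgcn_screen.cli.run_experiment`); trained models round-trip through a
single-file JSON checkpoint.

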