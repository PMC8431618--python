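# diagrank

Multi-criteria benchmarking of competing binary diagnostic classifiers.

When several models are evaluated for the same diagnostic task — e.g. a set
of convolutional neural networks classifying dermoscopic images as melanoma
vs non-melanoma — no single model usually wins on every axis: one has the
best sensitivity, another the best specificity, a third is a fraction of the
size. `diagrank` treats model selection as a multi-criteria decision problem:
it computes ten confusion-matrix-derived criteria per cross-validation fold,
assembles a direction-aware decision matrix, weights the criteria (by the
entropy method or an externally supplied vector), and produces a complete
ranking with PROMETHEE II outranking flows, cross-validated by the VIKOR
compromise ranking. It is aimed at researchers and engineers choosing a
classifier for deployment under conflicting performance and complexity
constraints.

## The methods

**Criteria.** For each classifier and fold, from the confusion counts
(tp, tn, fp, fn): accuracy, classification error (1 − Acc), precision
tp/(tp+fp), sensitivity tp/(tp+fn), F1 = 2·Pre·Sen/(Pre+Sen), specificity
tn/(tn+fp), FPR = 1 − Spe, FNR = 1 − Sen, Matthews correlation coefficient

```
MCC = (tp·tn − fp·fn) / √((tp+fp)(tp+fn)(tn+fp)(tn+fn)),
```

plus the parameter count in millions as a complexity criterion. Folds are
aggregated to mean ± sample (n−1) standard deviation.

**Decision matrix and normalization.** With m alternatives and k criteria,
beneficial columns (Acc, Sen, Spe, F1, Pre, MCC) are scaled x̄ᵢⱼ = xᵢⱼ/maxᵢ xᵢⱼ
and non-beneficial columns (Err, FPR, FNR, #params) x̄ᵢⱼ = minᵢ xᵢⱼ/xᵢⱼ, so
every column is max-oriented with optimum 1.

**Entropy weights.** pᵢⱼ = xᵢⱼ/Σᵢ xᵢⱼ, eⱼ = −(1/ln m)·Σᵢ pᵢⱼ ln pᵢⱼ,
dⱼ = 1 − eⱼ, wⱼ = dⱼ/Σⱼ dⱼ: a criterion's weight grows with the contrast of
its column.

**PROMETHEE II.** For each ordered pair (a, b), dⱼ(a,b) = x̄ₐⱼ − x̄ᵦⱼ is mapped
through the usual (threshold) preference function Pⱼ = 1 iff dⱼ > 0, the
global index π(a,b) = Σⱼ wⱼPⱼ(a,b) is accumulated into positive and negative
outranking flows ϕ⁺, ϕ⁻, and alternatives are ranked by the net flow
ϕ = ϕ⁺ − ϕ⁻ (averaged over m−1 opponents, or summed — both conventions are
supported).

**VIKOR.** Per-criterion best/worst values x*ⱼ, x⁻ⱼ give the group utility
Sᵢ = Σⱼ wⱼ(x*ⱼ−xᵢⱼ)/(x*ⱼ−x⁻ⱼ) and the worst single regret Rᵢ = maxⱼ of the
same terms; the compromise index Q mixes the two with weight v (default 0.5)
and ranks ascending.

## Worked example

The package bundles the decision data of a published benchmark of 19
ImageNet-pretrained CNNs fine-tuned for binary melanoma diagnosis on 991
dermoscopic images over five stratified folds. Reproducing it end to end:

```python
>>> from diagrank import reproduce_case_study
>>> rep = reproduce_case_study()
>>> rep.benchmark.ranking_table().round(4).head()
                  phi  rank_promethee       Q  rank_vikor
alternative
ResNet101    150.8418               1  0.0000           1
DenseNet201  133.2356               2  0.1937           2
Inceptionv3  132.2051               3  0.2858           4
ResNet50     115.1633               4  0.2854           3
NasnetLarge   73.3193               5  0.4510           5
```

ResNet101 attains the highest net outranking flow (ϕ = 150.84, summed
convention) and simultaneously the minimum VIKOR S and R, hence Q = 0 — both
methods select it as the best compromise between accuracy-type criteria and
model complexity; SqueezeNet (smallest model, weakest discrimination) is
last under both with Q = 1. `rep.summary` reports the diff against the
bundled reference tables: all 190 normalized-matrix cells match at 4 decimal
places and the entire PROMETHEE ranking column is reproduced.

Running your own comparison from simulated (or real) per-fold predictions:

```python
from diagrank import (FoldPlan, SyntheticModelSpec, simulate_predictions,
                      summarize_predictions, build_decision_matrix,
                      normalize, entropy_weights, promethee_rank)

specs = [
    SyntheticModelSpec("resnet-ish",  0.93, 0.95, n_params=44.6),
    SyntheticModelSpec("mobile-ish",  0.86, 0.96, n_params=3.5),
    SyntheticModelSpec("squeeze-ish", 0.87, 0.83, n_params=1.24),
]
preds = simulate_predictions(specs, FoldPlan(n_pos=491, n_neg=500, seed=42))
summaries = summarize_predictions(preds, {s.model_id: s.n_params for s in specs},
                                  positive_label="positive")
norm = normalize(build_decision_matrix(summaries))
ranker = promethee_rank(norm, weights=entropy_weights(norm.data))
print(ranker.report().round(4))
```

```
             phi_plus  phi_minus     phi  rank
alternative
squeeze-ish    0.6519     0.3481  0.3038     1
mobile-ish     0.4341     0.5647 -0.1307     2
resnet-ish     0.4128     0.5859 -0.1731     3
```

Here entropy weighting puts most of the weight (0.59) on the parameter-count
column — it is by far the most dispersed criterion — so the smallest model
wins despite middling accuracy. This is the expected behaviour of objective
entropy weights, and the reason the ranking estimators also accept
user-supplied weight vectors when the analyst wants a different emphasis.

The same pipeline is scriptable: `diagrank simulate`, `diagrank metrics`,
`diagrank rank` and `diagrank reproduce` (see `diagrank --help`).

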