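# seqentropy

Differential-entropy separability analysis for sequence-embedding
classifiers.

When a pretrained DNA language model is fine-tuned and its per-sequence
embeddings are fed to a downstream classifier (e.g. an SVM distinguishing
enhancers from non-enhancers), a practical question arises: **after how many
fine-tuning epochs are the embeddings most discriminative?** Validation
metrics alone fluctuate within a narrow band and do not point to a single
epoch. `seqentropy` answers the question geometrically: it estimates the
differential entropy of the positive-class and negative-class embedding
clouds at every epoch and selects the epoch where the two class entropy
distributions are furthest apart — the point of peak separability before
over-fitting drives them back together ("coincidence – separation –
coincidence").

## The estimator

For a cloud of N points in R^d, the Kozachenko–Leonenko (k = 1)
nearest-neighbor estimate of differential entropy is

    H_N = d·ln(ρ̄) + ln(V_d) + γ + ln(N − 1)        [nats]

where ρ̄ is the geometric mean of each point's distance ρ_i to its nearest
other point, V_d = π^(d/2) / Γ(1 + d/2) is the d-dimensional unit-ball
volume (always handled in log space — at d = 768 the linear volume
underflows to zero), and γ ≈ 0.5772 is the Euler–Mascheroni constant.
Because ρ̄ is a geometric mean, H_N is identically the arithmetic mean of
per-sample contributions h_i = d·ln ρ_i + ln V_d + γ + ln(N − 1); the
class-wise means and medians of these contributions give, per epoch, the
separability gaps

    Δmean   = |mean(h_i | y = 1) − mean(h_i | y = 0)|
    Δmedian = |median(h_i | y = 1) − median(h_i | y = 0)|

and the optimal epoch is the argmax of Δmean (ties → larger Δmedian, then
the smaller epoch).

Around the selector, the package provides the full classifier-evaluation
protocol: a stratified 7:3 train/test split, label-stratified 5-fold CV
plus independent testing, a five-family classifier roster (RBF-kernel SVM,
histogram and exact gradient-boosted trees, L2 logistic regression, k-NN),
and eight metrics (ACC, MCC, Sn, Sp, NPV, P, auROC, auPRC) computed from
first principles (midrank Mann–Whitney auROC; average-precision auPRC).
A seeded synthetic generator produces epoch-indexed Gaussian embedding
snapshots with an exactly known, planted entropy-gap trajectory, so every
estimate in the pipeline is checkable against closed forms.

## Worked example

Simulate 11 embedding snapshots (epoch 0 = un-fine-tuned baseline; a 4-nat
separability peak planted at epoch 6; 400 positives vs 972 negatives,
the 1:2.43 class imbalance), estimate the trajectory, select the epoch:

```sh
seqentropy simulate --seed 1 --outdir snaps
seqentropy trajectory snaps/epoch*.tsv --out traj.json
seqentropy select-epoch traj.json
```

which prints (abridged):

```json
{
  "optimal_epoch": 6,
  "criterion": "delta_mean",
  "agreement_with_median": true
}
```

with the estimated per-epoch gaps behind it (Δmean, Δmedian in nats):

```
epoch   0      1      2      3      4      5      6      7      8      9      10
Δmean   0.245  0.030  0.606  1.026  0.797  1.409  4.143  1.392  1.102  0.574  0.044
Δmedian 0.098  0.071  0.455  0.987  0.842  1.515  4.174  1.547  1.162  0.575  0.076
```

The gap rises from near-coincidence, peaks at the planted epoch 6 (the
estimate 4.14 nats vs the planted 4.0), and collapses again — so
`select-epoch` recovers the epoch of maximal class separability, and the
mean- and median-based criteria agree.

Library use mirrors the CLI:

```python
from seqentropy import (TrajectoryConfig, simulate_trajectory,
                        entropy_trajectory, select_optimal_epoch)

sets = simulate_trajectory(TrajectoryConfig(seed=1))
result = select_optimal_epoch(entropy_trajectory(sets))
print(result.optimal_epoch)   # 6
```

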