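# Methods

## Model and procedure

The package treats per-sequence embedding vectors as draws from two
class-conditional distributions in R^d (positives = enhancers, negatives =
non-enhancers) and quantifies how distinguishable those distributions are
at each fine-tuning epoch by the gap between their differential entropies.

Differential entropy h(X) = −∫ f ln f is estimated nonparametrically with
the Kozachenko–Leonenko nearest-neighbor estimator at neighbor order k = 1:

    H_N = d·ln(ρ̄) + ln(V_d) + γ + ln(N − 1)   (nats),

ρ̄ the geometric mean of nearest-neighbor distances, V_d the unit-ball
volume, γ the Euler–Mascheroni constant. The implementation computes the
algebraically identical arithmetic mean of per-sample contributions
h_i = d·ln ρ_i + ln V_d + γ + ln(N − 1). This decomposition is load-bearing:
the per-epoch statistics are the class-wise mean and median of the h_i, and
the mean reproduces H_N exactly while the median gives a robust companion
criterion. The estimator avoids density estimation entirely (no binning
artifacts, no KDE bandwidth choice) and behaves well in the
high-dimensional regimes language-model embeddings live in.

Epoch selection maximizes Δmean = |pos mean − neg mean| over the epoch
trajectory; ties break toward the larger Δmedian and then the smaller
epoch (earlier epoch = less fine-tuning = cheaper and less over-fit). The
result records whether the Δmedian criterion independently lands on the
same epoch — agreement is evidence the separability peak is real and not a
tail artifact.

### Assumptions

- Embeddings are treated as i.i.d. draws within a class; no account is
  taken of sequence relatedness or spatial structure.
- Entropy gaps are compared across epochs computed on clouds of the same
  size and dimension, so the estimator's finite-sample bias (which depends
  on N and d) cancels in the comparison. Comparing gaps across different
  sample sizes is not supported by this cancellation and should be read
  with care.
- By default each class's neighbor search runs within its own cloud
  (class-conditional entropy); a pooled mode searches the union instead.
  Pooled search couples the two estimates and is offered only as a
  sensitivity check (`--pooled`).

## Tunable parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `k` (neighbor order) | 1 | — | The defining k = 1 formula; k > 1 replaces γ + ln(N−1) with ψ(N) − ψ(k) (digamma generalization) and is an extension, reducing variance at the cost of bias. |
| `epsilon` (distance floor) | 1e-12 | same as features | Duplicate points give ρ_i = 0; flooring keeps the estimator total. Every floored distance is counted and a warning fires above 10% clamped. |
| `metric` | Euclidean | — | The only metric with the stated V_d normalization. |
| `test_fraction` | 0.3 | — | The 7:3 split protocol; per-class counts rounded half-up, remainder in training. |
| `folds` | 5 | — | The 5-fold CV + independent-test protocol. |

Classifier defaults (none are tuned): RBF SVM with C = 1 and kernel width
1/(d·feature variance); L2 logistic regression C = 1; k-NN with k = 5;
both boosted-tree families at 100 trees, depth 6, learning rate 0.1. SVM
ranking scores are signed margins, not calibrated probabilities —
threshold-free metrics only need the ordering. Class imbalance (1:2.43) is
left unweighted.

## Metrics

ACC, MCC, Sn, Sp, NPV and P come directly from the 2×2 confusion counts;
any metric with a zero denominator is reported as 0 and flagged degenerate
rather than raising, so a degenerate CV fold cannot abort a run. auROC is
the Mann–Whitney statistic computed with midranks (exactly
P(score_pos > score_neg) + ½·P(tie)); auPRC is the average-precision step
sum Σ (R_i − R_{i−1})·P_i with tied scores entering as one block. Both are
cross-checked in the test suite against exhaustive pairwise enumeration and
scikit-learn. Note the trapezoidal PR area is a different (more
optimistic) quantity; this package reports average precision.

## Synthetic generator

The trajectory simulator emulates the study setting the package is built
for: two classes of d-dimensional spherical Gaussian feature clouds whose
separability rises and falls over fine-tuning epochs. The negative class
is a fixed reference N(0, σ_neg²·I_d); at epoch e the positive class is
N(μ_e, σ_pos,e²·I_d) with

    σ_pos,e = σ_neg · exp(gap_profile[e] / d),

so the *true* class entropy gap is exactly gap_profile[e] nats (Gaussian
entropy is (d/2)·ln(2πeσ²)), and |μ_e| follows a mean-separation profile
coupled to the gap (default 0.5 × gap) so classifier quality tracks the
planted separability. Defaults: d = 16, 400 positives vs 972 negatives
(preserving the 1:2.43 imbalance), 11 epochs (0–10), and a unimodal gap
profile that is 0 at both ends and peaks at 4 nats at epoch 6 with
shoulders ≤ 1 nat — the coincidence–separation–coincidence shape. d = 16
rather than the native 768 keeps the default suite fast; correctness at
d = 768 is exercised through the log-space unit-ball volume, which is the
only dimension-fragile term.

What the generator does *not* emulate: real embedding clouds are neither
Gaussian nor isotropic, class-conditional distributions can be multimodal,
and fine-tuning moves both classes at once. Passing tests therefore
demonstrate estimator and selector correctness under a known ground truth,
not that any particular real dataset has a clean epoch-6 peak.

## Numerical choices

- ln V_d is computed as (d/2)·ln π − lnΓ(1 + d/2) via log-gamma; V_d
  itself underflows at d ≈ 350 and is never formed.
- Natural log throughout; the additive γ is only consistent with nats.
- Nearest neighbors are exact (k-d tree), never approximate: estimates
  must be bit-stable for a fixed input.
- All randomness flows from explicit integer seeds through NumPy
  `default_rng`; the same seed reproduces splits, folds, simulations and
  classifier scores bit-for-bit on any platform.
- Split counts round half-up per class (floor(x + 0.5)); the remainder
  stays in training.
- Per-draw noise of the gap estimate at the default generator size
  (n ≈ 10³, d = 16) is roughly 0.1 nats, so null-gap checks average the
  signed gap over seeds rather than bounding single draws.

## Known limitations

- The k = 1 estimator carries a positive finite-sample bias that grows
  with d (≈ 0.4 nats at d = 16, N = 1000 for a Gaussian); the pipeline
  relies on this bias cancelling between equal-dimension, similar-size
  class clouds, not on absolute entropy accuracy in high d.
- Group-key (e.g. chromosome) stratification preserves per-group class
  proportions by per-cell rounding; it does not solve constrained
  optimization for exact global counts.
- The CLI reads whole snapshots into memory; matrices far beyond ~10⁵ × 768
  would need chunked I/O that is out of scope here.
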