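"""Kozachenko–Leonenko nearest-neighbor differential entropy.

For a cloud of N points in R^d the k = 1 estimator is

    H_N = d * ln(rho_bar) + ln(V_d) + gamma + ln(N - 1)

where rho_bar is the geometric mean of each point's distance to its nearest
other point, V_d = pi^(d/2) / Gamma(1 + d/2) is the volume of the
d-dimensional unit ball, and gamma is the Euler–Mascheroni constant.
Because rho_bar is a geometric mean, H_N is identically the arithmetic mean
of the per-sample contributions

    h_i = d * ln(rho_i) + ln(V_d) + gamma + ln(N - 1),

which is how the estimate is computed here: the contributions double as the
per-sample entropy values whose class-wise means and medians drive the
epoch-gap analysis.  For k > 1 the additive constant gamma + ln(N - 1) is
replaced by the digamma form psi(N) - psi(k); this is an extension beyond
the k = 1 definition above and is off by default.

Entropies are in nats (natural log) throughout: the additive gamma term is
only consistent with the natural logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .exceptions import InputError, SampleSizeError
from .io import EmbeddingSet

__all__ = [
    "KLParams",
    "EntropyEstimate",
    "EpochGapRecord",
    "SelectionResult",
    "EULER_GAMMA",
    "log_unit_ball_volume",
    "kl_entropy",
    "class_entropy",
    "entropy_trajectory",
    "select_optimal_epoch",
]

#: Euler–Mascheroni constant (np.euler_gamma), ~0.5772.
EULER_GAMMA: float = float(np.euler_gamma)

CLAMP_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class KLParams:
    """Estimator knobs.

    k is the neighbor order (1 reproduces the defining formula; larger k is
    the digamma generalization).  epsilon floors neighbor distances so
    duplicate points cannot produce -inf contributions; every floored
    distance is counted and a warning is emitted above 10% clamped.
    """

    k: int = 1
    metric: Literal["euclidean"] = "euclidean"
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("neighbor order k must be >= 1")
        if self.epsilon <= 0:
            raise InputError("epsilon must be positive")
        if self.metric != "euclidean":
            raise InputError(f"unsupported metric: {self.metric}")


@dataclass(frozen=True)
class EntropyEstimate:
    """K-L estimate for one point cloud with per-sample contributions."""

    H: float
    contributions: np.ndarray
    d: int
    N: int
    n_clamped: int

    @property
    def median_contribution(self) -> float:
        return float(np.median(self.contributions))

    @property
    def mean_contribution(self) -> float:
        return float(np.mean(self.contributions))


@dataclass(frozen=True)
class EpochGapRecord:
    """Per-epoch class entropy summaries and the Δmean/Δmedian gaps."""

    epoch: int
    pos_mean: float
    pos_median: float
    neg_mean: float
    neg_median: float
    n_pos: int
    n_neg: int
    n_clamped: int

    @property
    def delta_mean(self) -> float:
        return abs(self.pos_mean - self.neg_mean)

    @property
    def delta_median(self) -> float:
        return abs(self.pos_median - self.neg_median)

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "pos_mean": self.pos_mean,
            "pos_median": self.pos_median,
            "neg_mean": self.neg_mean,
            "neg_median": self.neg_median,
            "delta_mean": self.delta_mean,
            "delta_median": self.delta_median,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_clamped": self.n_clamped,
        }


@dataclass(frozen=True)
class SelectionResult:
    """Gap-maximizing epoch choice over a trajectory."""

    optimal_epoch: int
    criterion: str
    agreement_with_median: bool
    trajectory: tuple[EpochGapRecord, ...]

    def to_dict(self) -> dict:
        return {
            "optimal_epoch": self.optimal_epoch,
            "criterion": self.criterion,
            "agreement_with_median": self.agreement_with_median,
            "trajectory": [r.to_dict() for r in self.trajectory],
        }


def log_unit_ball_volume(d: int) -> float:
    """ln of the d-dimensional unit-ball volume, pi^(d/2)/Gamma(1 + d/2).

    Computed entirely in log space via log-gamma so it stays finite at
    d = 768 and beyond, where the linear-space volume underflows to zero.
    """
    if d <= 0:
        raise InputError(f"dimension must be positive, got {d}")
    return 0.5 * d * np.log(np.pi) - gammaln(1.0 + 0.5 * d)


def kl_entropy(points: np.ndarray, params: KLParams = KLParams()) -> EntropyEstimate:
    """K-L differential entropy of one point cloud (nats).

    Nearest neighbors are exact (k-d tree).  Duplicate points yield zero
    neighbor distances; these are floored at ``params.epsilon`` and counted
    in ``n_clamped``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if not np.all(np.isfinite(pts)):
        raise InputError("non-finite input points")
    n, d = pts.shape
    if n <= params.k:
        raise SampleSizeError(
            f"need at least k+1 = {params.k + 1} samples, got {n}"
        )
    tree = cKDTree(pts)
    # query returns each point itself at distance 0 first
    dist, _ = tree.query(pts, k=params.k + 1)
    rho = dist[:, params.k]
    n_clamped = int(np.sum(rho < params.epsilon))
    if n_clamped > CLAMP_WARN_FRACTION * n:
        warnings.warn(
            f"{n_clamped}/{n} nearest-neighbor distances floored at "
            f"epsilon={params.epsilon}; the estimate is dominated by "
            "duplicate or near-duplicate points",
            RuntimeWarning,
            stacklevel=2,
        )
    rho = np.maximum(rho, params.epsilon)
    if params.k == 1:
        const = EULER_GAMMA + np.log(n - 1)
    else:
        const = digamma(n) - digamma(params.k)
    contributions = d * np.log(rho) + log_unit_ball_volume(d) + const
    return EntropyEstimate(
        H=float(np.mean(contributions)),
        contributions=contributions,
        d=d,
        N=n,
        n_clamped=n_clamped,
    )


def class_entropy(
    es: EmbeddingSet, params: KLParams = KLParams(), pooled: bool = False
) -> tuple[EntropyEstimate, EntropyEstimate]:
    """Per-class K-L estimates (positive first, then negative).

    By default each class's neighbor search runs within its own cloud, so
    the two class-conditional estimates are independent.  ``pooled=True``
    instead searches neighbors over the union of both classes and splits
    the contributions by label afterwards.
    """
    out: dict[int, EntropyEstimate] = {}
    if pooled:
        full = kl_entropy(es.features, params)
        for lab in (1, 0):
            mask = es.labels == lab
            if mask.sum() <= params.k:
                raise SampleSizeError(
                    f"class {lab} has {int(mask.sum())} samples; "
                    f"need > k = {params.k}"
                )
            contrib = full.contributions[mask]
            out[lab] = EntropyEstimate(
                H=float(np.mean(contrib)),
                contributions=contrib,
                d=full.d,
                N=int(mask.sum()),
                n_clamped=full.n_clamped,
            )
    else:
        for lab in (1, 0):
            pts = es.class_features(lab)
            if pts.shape[0] <= params.k:
                raise SampleSizeError(
                    f"class {lab} has {pts.shape[0]} samples; "
                    f"need > k = {params.k}"
                )
            out[lab] = kl_entropy(pts, params)
    return out[1], out[0]


def entropy_trajectory(
    sets: Sequence[EmbeddingSet],
    params: KLParams = KLParams(),
    pooled: bool = False,
) -> list[EpochGapRecord]:
    """Class entropy summaries and gaps for an epoch-ordered snapshot list."""
    if not sets:
        raise InputError("empty snapshot list")
    epochs = [es.epoch for es in sets]
    if len(set(epochs)) != len(epochs):
        raise InputError(f"duplicate epoch indices: {epochs}")
    if epochs != sorted(epochs):
        raise InputError(f"epochs must be strictly increasing: {epochs}")
    records = []
    for es in sets:
        pos, neg = class_entropy(es, params, pooled=pooled)
        records.append(
            EpochGapRecord(
                epoch=es.epoch,
                pos_mean=pos.mean_contribution,
                pos_median=pos.median_contribution,
                neg_mean=neg.mean_contribution,
                neg_median=neg.median_contribution,
                n_pos=pos.N,
                n_neg=neg.N,
                n_clamped=pos.n_clamped + neg.n_clamped,
            )
        )
    return records


def _argmax_epoch(
    records: Sequence[EpochGapRecord], primary: str, secondary: str
) -> int:
    # max primary gap; ties -> larger secondary gap, then smaller epoch
    best = max(
        records,
        key=lambda r: (getattr(r, primary), getattr(r, secondary), -r.epoch),
    )
    return best.epoch


def select_optimal_epoch(records: Sequence[EpochGapRecord]) -> SelectionResult:
    """Pick the epoch maximizing Δmean entropy between the classes.

    Ties break toward the larger Δmedian, then the smaller epoch.
    ``agreement_with_median`` reports whether maximizing Δmedian (with the
    mirrored tie-breaking) lands on the same epoch — agreement is the
    signature of a robust separability peak.
    """
    if not records:
        raise InputError("empty trajectory")
    by_mean = _argmax_epoch(records, "delta_mean", "delta_median")
    by_median = _argmax_epoch(records, "delta_median", "delta_mean")
    return SelectionResult(
        optimal_epoch=by_mean,
        criterion="delta_mean",
        agreement_with_median=(by_mean == by_median),
        trajectory=tuple(records),
    )
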