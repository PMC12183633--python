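"""Seeded generators of embedding snapshots with planted entropy dynamics.

The trajectory generator emulates a fine-tuned feature extractor whose
class-conditional embedding distributions first coincide, then separate,
then re-coincide as training over-fits.  Both classes are spherical
Gaussians in R^d; the negative class keeps a fixed scale sigma_neg while
the positive class's scale is sigma_pos = sigma_neg * exp(gap / d) at each
epoch, so the true class differential-entropy gap is exactly ``gap`` nats
(the Gaussian entropy (d/2) ln(2 pi e sigma^2) shifts by d ln(sigma ratio)).
A separate mean-separation profile moves the positive class's centroid so
classifier quality tracks the planted separability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .exceptions import ConfigError
from .io import EmbeddingSet, write_embedding_table

__all__ = [
    "TrajectoryConfig",
    "DEFAULT_GAP_PROFILE",
    "simulate_trajectory",
    "simulate_classification_set",
    "write_trajectory",
]

# Unimodal gap profile over epochs 0..10: zero at both ends (coincidence),
# a 4-nat peak at epoch 6 (separation), shoulders at or below 1 nat.
DEFAULT_GAP_PROFILE = (0.0, 0.3, 0.5, 0.7, 0.9, 1.0, 4.0, 1.0, 0.8, 0.4, 0.0)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Full parameterization of the epoch-trajectory simulator.

    Defaults mirror the study setting scaled to test size: 11 snapshots
    (epoch 0 = un-fine-tuned baseline), a 1:2.43 class imbalance, and a
    separability peak planted at epoch 6.
    """

    d: int = 16
    n_pos: int = 400
    n_neg: int = 972
    epochs: int = 11
    sigma_neg: float = 1.0
    gap_profile: tuple[float, ...] = DEFAULT_GAP_PROFILE
    planted_epoch: int = 6
    mean_separation_profile: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        gp = tuple(float(g) for g in self.gap_profile)
        object.__setattr__(self, "gap_profile", gp)
        if len(gp) != self.epochs:
            raise ConfigError(
                f"gap_profile length {len(gp)} != epochs {self.epochs}"
            )
        if any(g < 0 for g in gp):
            raise ConfigError("gap_profile must be non-negative")
        argmaxes = [i for i, g in enumerate(gp) if g == max(gp)]
        if argmaxes != [self.planted_epoch]:
            raise ConfigError(
                f"planted_epoch {self.planted_epoch} must be the unique "
                f"argmax of gap_profile (argmax at {argmaxes})"
            )
        if self.mean_separation_profile is None:
            # couple centroid distance to the gap so classifier quality
            # tracks the planted separability
            object.__setattr__(
                self, "mean_separation_profile", tuple(0.5 * g for g in gp)
            )
        else:
            msp = tuple(float(m) for m in self.mean_separation_profile)
            if len(msp) != self.epochs:
                raise ConfigError("mean_separation_profile length mismatch")
            object.__setattr__(self, "mean_separation_profile", msp)
        if self.d < 1 or self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("d, n_pos, n_neg must be positive")
        if self.sigma_neg <= 0:
            raise ConfigError("sigma_neg must be positive")


def simulate_trajectory(config: TrajectoryConfig) -> list[EmbeddingSet]:
    """Draw one embedding snapshot per epoch with the planted entropy gaps.

    Sample IDs are stable across epochs — the same virtual sequence gets a
    new representation at each snapshot, as a fine-tuned extractor would
    produce.  Fully deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    ids = tuple(
        [f"pos{i:05d}" for i in range(config.n_pos)]
        + [f"neg{i:05d}" for i in range(config.n_neg)]
    )
    labels = np.r_[np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    sets = []
    for epoch in range(config.epochs):
        gap = config.gap_profile[epoch]
        sep = config.mean_separation_profile[epoch]
        sigma_pos = config.sigma_neg * np.exp(gap / config.d)
        mu = np.zeros(config.d)
        mu[0] = sep
        pos = mu + sigma_pos * rng.standard_normal((config.n_pos, config.d))
        neg = config.sigma_neg * rng.standard_normal((config.n_neg, config.d))
        sets.append(
            EmbeddingSet(
                epoch=epoch,
                sample_ids=ids,
                labels=labels,
                features=np.vstack([pos, neg]),
            )
        )
    return sets


def simulate_classification_set(
    d: int, n_pos: int, n_neg: int, mean_gap: float, seed: int = 0
) -> EmbeddingSet:
    """Two unit-variance spherical Gaussians separated along the first axis.

    The raw first coordinate has theoretical auROC Phi(mean_gap / sqrt(2)),
    which makes the set a checkable fixture for ranking metrics and
    classifiers.
    """
    if d < 1 or n_pos < 1 or n_neg < 1:
        raise ConfigError("d, n_pos, n_neg must be positive")
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n_pos, d))
    pos[:, 0] += mean_gap
    neg = rng.standard_normal((n_neg, d))
    return EmbeddingSet(
        epoch=0,
        sample_ids=tuple(
            [f"pos{i:05d}" for i in range(n_pos)]
            + [f"neg{i:05d}" for i in range(n_neg)]
        ),
        labels=np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)],
        features=np.vstack([pos, neg]),
    )


def theoretical_auroc(mean_gap: float) -> float:
    """auROC of the raw separating coordinate for unit-variance classes."""
    return float(norm.cdf(mean_gap / np.sqrt(2.0)))


def write_trajectory(
    sets: Sequence[EmbeddingSet], config: TrajectoryConfig, outdir: str | Path
) -> list[Path]:
    """Write ``epoch<k>.tsv`` snapshots plus a ``truth.json`` manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for es in sets:
        p = outdir / f"epoch{es.epoch}.tsv"
        write_embedding_table(es, p)
        paths.append(p)
    truth = {
        "seed": config.seed,
        "d": config.d,
        "n_pos": config.n_pos,
        "n_neg": config.n_neg,
        "sigma_neg": config.sigma_neg,
        "gap_profile": list(config.gap_profile),
        "mean_separation_profile": list(config.mean_separation_profile),
        "planted_epoch": config.planted_epoch,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return paths
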