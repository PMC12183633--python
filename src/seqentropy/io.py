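"""Embedding-snapshot data model, file I/O, and dataset splitting.

The on-disk snapshot format is delimited text (TSV by default, comma
auto-detected): mandatory columns ``id`` and ``label`` followed by one
column per feature dimension (``f1`` .. ``fd``).  Each file holds one
fine-tuning epoch's embedding matrix; the epoch index is carried in the
``epoch<k>.tsv`` file-name convention or passed explicitly (an explicit
epoch always wins).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from math import floor
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import (
    FormatError,
    InputError,
    LabelError,
    StratificationError,
)

__all__ = [
    "EmbeddingSet",
    "SplitSpec",
    "DatasetSummary",
    "read_embedding_table",
    "write_embedding_table",
    "read_fasta_ids",
    "stratified_split",
    "summarize_dataset",
    "epoch_from_filename",
]

_EPOCH_RE = re.compile(r"epoch[_-]?(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class EmbeddingSet:
    """An epoch-tagged matrix of per-sample feature vectors with binary labels.

    Parameters
    ----------
    epoch
        Non-negative fine-tuning epoch index; 0 denotes the un-fine-tuned
        baseline representation.
    sample_ids
        Unique string identifier per sample (row).
    labels
        Binary vector; 1 = enhancer/positive, 0 = non-enhancer/negative.
    features
        Real matrix of shape (N, d) with finite entries.
    group_keys
        Optional per-sample grouping key (e.g. chromosome) for grouped
        stratification.
    """

    epoch: int
    sample_ids: tuple[str, ...]
    labels: np.ndarray
    features: np.ndarray
    group_keys: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        features = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "features", features)
        if self.epoch < 0:
            raise InputError(f"epoch must be non-negative, got {self.epoch}")
        if features.ndim != 2 or features.shape[1] < 1:
            raise InputError("features must be a 2-d matrix with d >= 1")
        n = features.shape[0]
        if len(self.sample_ids) != n or labels.shape != (n,):
            raise InputError(
                "sample_ids, labels and features must agree on the sample count"
            )
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample IDs")
        if not np.all(np.isin(labels, (0, 1))):
            bad = sorted(set(labels.tolist()) - {0, 1})
            raise LabelError(f"labels must be 0/1, found {bad}")
        if not np.all(np.isfinite(features)):
            raise InputError("non-finite feature values")
        if self.group_keys is not None:
            gk = tuple(str(g) for g in self.group_keys)
            if len(gk) != n:
                raise InputError("group_keys length must match sample count")
            object.__setattr__(self, "group_keys", gk)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: Sequence[int]) -> "EmbeddingSet":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return EmbeddingSet(
            epoch=self.epoch,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            labels=self.labels[idx],
            features=self.features[idx],
            group_keys=None
            if self.group_keys is None
            else tuple(self.group_keys[i] for i in idx),
        )

    def class_features(self, label: int) -> np.ndarray:
        return self.features[self.labels == label]


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of a train/test split; defaults follow the 7:3 protocol."""

    test_fraction: float = 0.3
    stratify_by_label: bool = True
    group_key_stratify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise InputError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class DatasetSummary:
    n_pos: int
    n_neg: int
    ratio_neg_to_pos: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_pos": self.n_pos,
                "n_neg": self.n_neg,
                "ratio_neg_to_pos": round(self.ratio_neg_to_pos, 2),
            }
        )


def epoch_from_filename(path: str | Path) -> Optional[int]:
    """Extract the epoch index from an ``epoch<k>`` file-name convention."""
    m = _EPOCH_RE.search(Path(path).stem)
    return int(m.group(1)) if m else None


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def read_embedding_table(path: str | Path, epoch: Optional[int] = None) -> EmbeddingSet:
    """Read one embedding snapshot from delimited text.

    ``epoch``, when given, overrides the index inferred from the file name;
    if neither is available the snapshot is tagged epoch 0.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"malformed table {path}: {exc}") from exc
    for col in ("id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{col}'")
    feature_cols = [c for c in df.columns if c not in ("id", "label", "group")]
    if not feature_cols:
        raise FormatError(f"{path}: no feature columns")
    if df["id"].isna().any() or df["id"].duplicated().any():
        raise FormatError(f"{path}: missing or duplicate sample IDs")
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or not labels.isin((0, 1)).all():
        raise LabelError(f"{path}: label column must contain only 0/1")
    features = df[feature_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(features)):
        raise FormatError(f"{path}: non-finite feature values")
    if epoch is None:
        epoch = epoch_from_filename(path) or 0
    group = tuple(df["group"].astype(str)) if "group" in df.columns else None
    return EmbeddingSet(
        epoch=epoch,
        sample_ids=tuple(df["id"]),
        labels=labels.to_numpy(dtype=int),
        features=features,
        group_keys=group,
    )


def write_embedding_table(
    es: EmbeddingSet, path: str | Path, sep: str = "\t", float_fmt: str = "%.17g"
) -> None:
    """Write a snapshot in the ``id, label, f1..fd`` delimited-text format."""
    path = Path(path)
    cols: dict[str, object] = {"id": list(es.sample_ids), "label": es.labels}
    if es.group_keys is not None:
        cols["group"] = list(es.group_keys)
    for j in range(es.d):
        cols[f"f{j + 1}"] = es.features[:, j]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=sep, index=False, float_format=float_fmt, lineterminator="\n")


def read_fasta_ids(path: str | Path) -> list[tuple[str, int]]:
    """Return (id, sequence length) for each FASTA record.

    Only sequence metadata is used here; embedding computation is external.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for rec in records:
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record '{rec.id}' has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record ID '{rec.id}'")
        seen.add(rec.id)
        out.append((rec.id, len(rec.seq)))
    return out


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def stratified_split(
    es: EmbeddingSet, spec: SplitSpec
) -> tuple[EmbeddingSet, EmbeddingSet]:
    """Split into (train, test) with per-class test counts round(f * n_c).

    Per-class counts use round-half-up; the remainder stays in training.
    With ``group_key_stratify`` the rounding is applied per (class, group)
    cell so each group's class proportions carry over as closely as integer
    rounding permits.  Deterministic given ``spec.seed``.
    """
    labels = es.labels
    if es.n < 4 or len(np.unique(labels)) < 2:
        raise StratificationError("need >= 4 samples with both classes present")
    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    if spec.group_key_stratify and es.group_keys is not None:
        cells = sorted(
            {(int(l), g) for l, g in zip(labels, es.group_keys)},
            key=lambda t: (t[0], t[1]),
        )
        for lab, grp in cells:
            idx = np.flatnonzero(
                (labels == lab) & (np.asarray(es.group_keys) == grp)
            )
            n_test = _round_half_up(spec.test_fraction * idx.size)
            test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    elif spec.stratify_by_label:
        for lab in (0, 1):
            idx = np.flatnonzero(labels == lab)
            n_test = _round_half_up(spec.test_fraction * idx.size)
            if n_test == 0 or n_test == idx.size:
                raise StratificationError(
                    f"class {lab} would be empty in one part"
                )
            test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    else:
        idx = np.arange(es.n)
        n_test = _round_half_up(spec.test_fraction * es.n)
        test_idx = rng.permutation(idx)[:n_test].tolist()
    test_mask = np.zeros(es.n, dtype=bool)
    test_mask[test_idx] = True
    train = es.subset(np.flatnonzero(~test_mask))
    test = es.subset(np.flatnonzero(test_mask))
    return train, test


def summarize_dataset(es: EmbeddingSet) -> DatasetSummary:
    """Class counts and the negative-to-positive ratio (reported to 2 dp)."""
    n_pos = int(np.sum(es.labels == 1))
    n_neg = int(np.sum(es.labels == 0))
    if n_pos == 0:
        raise StratificationError("no positive samples: ratio undefined")
    return DatasetSummary(n_pos=n_pos, n_neg=n_neg, ratio_neg_to_pos=n_neg / n_pos)
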