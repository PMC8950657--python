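"""Train/test partitioning and two-pass probabilistic positive oversampling.

The oversampling rule duplicates each positive *training* record with an
independent probability p (default 0.5) in each of a fixed number of passes
(default 2).  Duplicates keep the original sequence and carry a provenance
suffix in their id ("orig#dupK"), so leakage checks downstream are mechanical:
stripping the suffix recovers the ancestral id.  Negatives are never
duplicated, and the rule runs strictly after partitioning, on the training
side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqio import Dataset, SequenceRecord, PROVENANCE_SEP, base_id

__all__ = [
    "SplitSpec",
    "DataSplit",
    "OversampleSpec",
    "partition",
    "oversample_positives",
    "oversample_indices",
    "assert_no_leakage",
    "LeakageError",
]


class LeakageError(AssertionError):
    """A test id (or its duplicate ancestor) appeared in a training set."""


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: test fraction, seed, optional stratification."""

    test_rate: float
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_rate < 1.0:
            raise ValueError(f"test_rate must be in (0, 1), got {self.test_rate}")

    def to_dict(self) -> dict:
        return {
            "test_rate": self.test_rate,
            "seed": self.seed,
            "stratified": self.stratified,
        }


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/test id sets whose union covers the dataset."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as out:
            out.write("id\tpartition\n")
            for i in self.train_ids:
                out.write(f"{i}\ttrain\n")
            for i in self.test_ids:
                out.write(f"{i}\ttest\n")
        return path


@dataclass(frozen=True)
class OversampleSpec:
    """Two-pass probabilistic duplication of positive training records."""

    passes: int = 2
    p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.passes < 0:
            raise ValueError("passes must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")

    def to_dict(self) -> dict:
        return {"passes": self.passes, "p": self.p, "seed": self.seed}


def partition(d: Dataset, spec: SplitSpec) -> DataSplit:
    """Randomly split a dataset into train/test id sets.

    The test set holds floor(test_rate * n) records.  In stratified mode the
    per-class test counts are allocated by largest remainder, keeping the
    class ratio within one sample per class while preserving the exact total.
    """
    n = len(d)
    if n == 0:
        raise ValueError("cannot partition an empty dataset")
    n_test = int(np.floor(spec.test_rate * n))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test_rate {spec.test_rate} leaves an empty partition for n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    ids = np.array(d.ids)
    if not spec.stratified:
        test_idx = rng.choice(n, size=n_test, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
    else:
        labels = np.array(d.labels)
        mask = np.zeros(n, dtype=bool)
        # largest-remainder allocation of the exact n_test across classes
        classes = np.unique(labels)
        exact = {c: spec.test_rate * int((labels == c).sum()) for c in classes}
        alloc = {c: int(np.floor(v)) for c, v in exact.items()}
        short = n_test - sum(alloc.values())
        for c in sorted(classes, key=lambda c: exact[c] - alloc[c], reverse=True):
            if short <= 0:
                break
            alloc[c] += 1
            short -= 1
        for c in classes:
            cls_idx = np.flatnonzero(labels == c)
            take = rng.choice(len(cls_idx), size=alloc[c], replace=False)
            mask[cls_idx[take]] = True
    return DataSplit(tuple(ids[~mask]), tuple(ids[mask]))


def oversample_positives(train: Dataset, spec: OversampleSpec) -> Dataset:
    """Apply the two-pass probabilistic duplication rule to a training set.

    Every input record appears once in the output; each positive record is
    additionally duplicated, independently with probability ``spec.p``, in
    each of ``spec.passes`` passes.  Duplicate ids are suffixed
    "#dup<pass>" so the original set is recoverable.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[SequenceRecord] = list(train.records)
    for k in range(1, spec.passes + 1):
        for r in train.records:
            if r.is_positive and rng.random() < spec.p:
                out.append(replace(r, id=f"{r.id}{PROVENANCE_SEP}{k}"))
    return Dataset(tuple(out), train.length)


def oversample_indices(
    y: np.ndarray, spec: OversampleSpec, positive_label: int = 1
) -> np.ndarray:
    """Row-index form of the oversampling rule, for matrix-level pipelines.

    Returns the indices 0..n-1 followed by the duplicated positive indices of
    each pass, suitable for fancy-indexing a feature matrix and label vector.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(spec.seed)
    idx = list(range(len(y)))
    pos = np.flatnonzero(y == positive_label)
    for _ in range(spec.passes):
        keep = rng.random(len(pos)) < spec.p
        idx.extend(pos[keep].tolist())
    return np.array(idx, dtype=int)


def assert_no_leakage(train_ids, test_ids) -> None:
    """Raise if any test id shares an ancestral id with the training set.

    Oversampling provenance suffixes are stripped before comparison, so a
    duplicate of a test record hiding in the training set is caught.
    """
    train_base = {base_id(i) for i in train_ids}
    leaked = sorted({base_id(i) for i in test_ids} & train_base)
    if leaked:
        raise LeakageError(
            f"{len(leaked)} test record(s) present in training set: {leaked[:5]}"
        )
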