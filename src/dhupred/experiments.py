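"""Experiment designs: encoder x classifier grids, partition-rate study, and
three cross-species generalization experiments.

All designs share one pipeline ordering: partition first, oversample the
training side only (when requested), encode the two sides separately, fit,
then evaluate on the untouched test side.  The encoders are all sample-local
(no training-set statistics), so encoding after splitting is not required
for correctness — it is kept so the no-leakage argument is structural, and
every run asserts mechanically that no test id (or duplicate-provenance
ancestor) appears in the training set.

The cross-species designs are:

* experiment I  — train on one species (default S. cerevisiae), CV within
  it, independent test on the pooled other species;
* experiment II — leave-one-species-out: each species in turn is the test
  set, the rest train;
* experiment III — every ordered species pair: the 5x5 accuracy matrix with
  within-species CV accuracy on the diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoders import EncoderSpec, encode_dataset
from .evaluation import (
    CVResult,
    MetricSet,
    cross_validate,
    independent_test,
)
from .models import ModelSpec, fit
from .resample import (
    DataSplit,
    OversampleSpec,
    SplitSpec,
    assert_no_leakage,
    oversample_positives,
    partition,
)
from .seqio import Dataset

__all__ = [
    "GridResult",
    "CrossSpeciesMatrix",
    "run_single",
    "grid_benchmark",
    "partition_rate_study",
    "experiment_one",
    "experiment_two",
    "experiment_three",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridResult:
    """Metrics per (encoder, algorithm) cell plus the full run configuration."""

    rows: dict  # (encoder_name, algorithm) -> MetricSet
    config: dict

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (enc, alg), m in self.rows.items():
            records.append({"encoder": enc, "algorithm": alg, **m.to_dict()})
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class CrossSpeciesMatrix:
    """5x5 accuracy table: rows train, columns test, CV accuracy on the diagonal."""

    accuracy: pd.DataFrame
    config: dict

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.accuracy.index)


def _train_test_datasets(
    d: Dataset, split: DataSplit, oversample: OversampleSpec | None
) -> tuple[Dataset, Dataset]:
    train = d.subset(split.train_ids)
    test = d.subset(split.test_ids)
    if oversample is not None:
        train = oversample_positives(train, oversample)
    assert_no_leakage(train.ids, test.ids)
    return train, test


def run_single(
    d: Dataset,
    encoder: EncoderSpec,
    model: ModelSpec,
    split: DataSplit,
    oversample: OversampleSpec | None = None,
) -> MetricSet:
    """One partition -> oversample -> encode -> fit -> independent test run."""
    train, test = _train_test_datasets(d, split, oversample)
    X_train = encode_dataset(train, encoder)
    X_test = encode_dataset(test, encoder)
    trained = fit(model, X_train, train.labels)
    return independent_test(trained, X_test, test.labels)


def grid_benchmark(
    d: Dataset,
    encoders: list[EncoderSpec],
    algorithms: list[ModelSpec],
    split: SplitSpec,
    oversample: OversampleSpec | None = None,
) -> GridResult:
    """Independent-test metrics for every encoder x algorithm pair.

    A single partition (from ``split``) is reused across all pairs so cells
    are comparable; oversampling, when enabled, is re-drawn per cell from
    its own seeded stream but always on the training side only.
    """
    data_split = partition(d, split)
    rows = {}
    for enc in encoders:
        for model in algorithms:
            rows[(enc.name, model.algorithm)] = run_single(
                d, enc, model, data_split, oversample
            )
    config = {
        "split": split.to_dict(),
        "oversample": oversample.to_dict() if oversample else None,
        "encoders": [e.to_dict() for e in encoders],
        "models": [m.to_dict() for m in algorithms],
        "n_train": len(data_split.train_ids),
        "n_test": len(data_split.test_ids),
    }
    return GridResult(rows, config)


def partition_rate_study(
    d: Dataset,
    encoders: list[EncoderSpec],
    model: ModelSpec,
    rates: tuple[float, ...] = (0.30, 0.20, 0.10),
    seed: int = 0,
    oversample: OversampleSpec | None = None,
) -> dict[float, GridResult]:
    """One single-algorithm grid per test-partition rate, common seed policy.

    No monotonicity in the rate is asserted anywhere: whether smaller test
    fractions help is an empirical observation, not a law.
    """
    out = {}
    for rate in rates:
        out[rate] = grid_benchmark(
            d,
            encoders,
            [model],
            SplitSpec(test_rate=rate, seed=seed),
            oversample,
        )
    return out


def _species_sides(d: Dataset, test_species: str) -> tuple[Dataset, Dataset]:
    test = d.by_species(test_species)
    train = Dataset(
        tuple(r for r in d if r.species != test_species), d.length
    )
    return train, test


def _check_two_classes(sub: Dataset, what: str) -> None:
    if sub.n_positive == 0 or sub.n_negative == 0:
        raise ValueError(f"{what} must contain both classes")


def experiment_one(
    d: Dataset,
    holdout_species: str = "S.cerevisiae",
    model: ModelSpec = ModelSpec("RF"),
    encoder: EncoderSpec = EncoderSpec("NCP"),
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    oversample: OversampleSpec | None = None,
) -> tuple[CVResult, MetricSet]:
    """Train on one species; test on the pooled remaining species."""
    if holdout_species not in d.species_present():
        raise ValueError(f"species {holdout_species!r} absent from dataset")
    train = d.by_species(holdout_species)
    test = Dataset(tuple(r for r in d if r.species != holdout_species), d.length)
    _check_two_classes(train, f"training species {holdout_species}")
    _check_two_classes(test, "pooled test species")
    assert_no_leakage(train.ids, test.ids)
    X_train = encode_dataset(train, encoder)
    X_test = encode_dataset(test, encoder)
    cv = cross_validate(
        X_train, train.labels, model, k=k, repeats=repeats, seed=seed,
        oversample=oversample,
    )
    if oversample is not None:
        fit_data = oversample_positives(train, oversample)
        assert_no_leakage(fit_data.ids, test.ids)
        X_fit = encode_dataset(fit_data, encoder)
        trained = fit(model, X_fit, fit_data.labels)
    else:
        trained = fit(model, X_train, train.labels)
    metrics = independent_test(trained, X_test, test.labels)
    return cv, metrics


def experiment_two(
    d: Dataset,
    model: ModelSpec = ModelSpec("RF"),
    encoder: EncoderSpec = EncoderSpec("NCP"),
    oversample: OversampleSpec | None = None,
) -> dict[str, MetricSet]:
    """Leave-one-species-out: each species tested against the rest."""
    species = d.species_present()
    if len(species) < 2:
        raise ValueError("leave-one-species-out needs at least two species")
    out = {}
    for sp in species:
        train, test = _species_sides(d, sp)
        _check_two_classes(train, f"training pool excluding {sp}")
        _check_two_classes(test, f"test species {sp}")
        if oversample is not None:
            train = oversample_positives(train, oversample)
        assert_no_leakage(train.ids, test.ids)
        X_train = encode_dataset(train, encoder)
        X_test = encode_dataset(test, encoder)
        trained = fit(model, X_train, train.labels)
        out[sp] = independent_test(trained, X_test, test.labels)
    return out


def experiment_three(
    d: Dataset,
    model: ModelSpec = ModelSpec("RF"),
    encoder: EncoderSpec = EncoderSpec("NCP"),
    k: int = 5,
    seed: int = 0,
) -> CrossSpeciesMatrix:
    """Every ordered species pair: train on the row, test on the column.

    Off-diagonal (r, c) is the independent-test accuracy of a model trained
    on all of species r and tested on all of species c; the diagonal is the
    within-species stratified k-fold CV mean accuracy.  A species whose
    smallest class has fewer than k members gets k reduced to that count
    (with a logged warning) rather than failing.
    """
    species = d.species_present()
    for sp in species:
        sub = d.by_species(sp)
        if sub.n_positive == 0 or sub.n_negative == 0:
            raise ValueError(f"species {sp!r} has a single class; cannot evaluate")
    acc = pd.DataFrame(
        np.zeros((len(species), len(species))), index=species, columns=species
    )
    for train_sp in species:
        train = d.by_species(train_sp)
        X_train = encode_dataset(train, encoder)
        trained = fit(model, X_train, train.labels)
        for test_sp in species:
            if test_sp == train_sp:
                k_eff = min(k, train.n_positive, train.n_negative)
                if k_eff < k:
                    log.warning(
                        "species %s: smallest class supports only %d folds "
                        "(requested %d)", train_sp, k_eff, k,
                    )
                cv = cross_validate(
                    X_train, train.labels, model, k=k_eff, repeats=1, seed=seed
                )
                acc.loc[train_sp, train_sp] = cv.mean("Acc")
            else:
                test = d.by_species(test_sp)
                assert_no_leakage(train.ids, test.ids)
                X_test = encode_dataset(test, encoder)
                m = independent_test(trained, X_test, test.labels)
                acc.loc[train_sp, test_sp] = m.Acc
    config = {
        "model": model.to_dict(),
        "encoder": encoder.to_dict(),
        "k": k,
        "seed": seed,
        "species": list(species),
    }
    return CrossSpeciesMatrix(acc, config)
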