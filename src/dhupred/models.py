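"""A uniform train/score interface over five classifier families.

The menu is RF (random forest), SVM (RBF kernel), KNN (neighbour count chosen
by inner cross-validation on the training data), LR (L2 logistic regression)
and MLP (one sigmoid hidden layer).  All are scikit-learn estimators behind a
small spec/handle/trained-model surface that fixes seeds, validates shapes,
and records training sample ids so downstream leakage checks are possible.

Scores are positive-class probabilities in [0, 1]; hard labels come from
thresholding at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .encoders import FeatureMatrix

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "ModelHandle",
    "TrainedModel",
    "make_model",
    "fit",
    "predict_scores",
    "predict_labels",
    "save_model",
    "load_model",
]

ALGORITHMS = ("RF", "SVM", "KNN", "LR", "MLP")

#: Candidate neighbour counts for KNN inner cross-validation.
KNN_GRID = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm name, hyperparameter overrides, and seed."""

    algorithm: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {', '.join(ALGORITHMS)}"
            )
        object.__setattr__(self, "hyperparams", dict(self.hyperparams))

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "hyperparams": dict(self.hyperparams),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(d["algorithm"], dict(d.get("hyperparams", {})), d.get("seed", 0))


def _build_estimator(spec: ModelSpec):
    hp = spec.hyperparams
    if spec.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            criterion=hp.get("criterion", "gini"),
            max_features=hp.get("max_features", "sqrt"),
            random_state=spec.seed,
        )
    if spec.algorithm == "SVM":
        # RBF kernel, library-default C and gamma; probability calibration
        # (internally cross-validated Platt scaling) gives [0,1] scores.
        return SVC(
            kernel=hp.get("kernel", "rbf"),
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            probability=True,
            random_state=spec.seed,
        )
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    if spec.algorithm == "LR":
        return LogisticRegression(
            C=hp.get("C", 1.0), max_iter=hp.get("max_iter", 2000)
        )
    if spec.algorithm == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (100,)),
            activation=hp.get("activation", "logistic"),
            max_iter=hp.get("max_iter", 300),
            random_state=spec.seed,
        )
    raise AssertionError(spec.algorithm)


@dataclass(frozen=True)
class ModelHandle:
    """An untrained, fully configured estimator plus its spec."""

    spec: ModelSpec
    estimator: object

    def describe(self) -> dict:
        """Echo the effective configuration (resolved defaults included)."""
        params = self.estimator.get_params()
        keep = {
            "RF": ("n_estimators", "criterion", "max_features"),
            "SVM": ("kernel", "C", "gamma"),
            "KNN": ("n_neighbors",),
            "LR": ("C", "penalty"),
            "MLP": ("hidden_layer_sizes", "activation"),
        }[self.spec.algorithm]
        desc = {k: params[k] for k in keep if k in params}
        if self.spec.algorithm == "KNN" and "n_neighbors" not in self.spec.hyperparams:
            desc["k_selection_grid"] = list(KNN_GRID)
        return desc


@dataclass
class TrainedModel:
    """A fitted classifier with its spec and training metadata."""

    spec: ModelSpec
    estimator: object
    n_features: int
    n_samples: int
    class_counts: dict
    train_ids: tuple[str, ...] | None = None

    def _check_dim(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_features}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X


def make_model(spec: ModelSpec) -> ModelHandle:
    """Configure an untrained model handle for the given spec."""
    return ModelHandle(spec, _build_estimator(spec))


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.sample_ids
    return np.asarray(X, dtype=float), None


def fit(model: ModelHandle | ModelSpec, X, y) -> TrainedModel:
    """Fit a model on a feature matrix; deterministic given the spec seed.

    KNN selects its neighbour count from {1,3,5,7,9} by stratified inner
    cross-validation on the training data only (skipped when the user pins
    ``n_neighbors`` or the data are too small to fold).
    """
    if isinstance(model, ModelSpec):
        model = make_model(model)
    Xv, sample_ids = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if Xv.shape[0] != len(y):
        raise ValueError(f"X has {Xv.shape[0]} rows but y has {len(y)} labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class; two are required")
    est = _build_estimator(model.spec)  # fresh estimator: refits are independent
    if (
        model.spec.algorithm == "KNN"
        and "n_neighbors" not in model.spec.hyperparams
        and counts.min() >= 3
    ):
        grid = [k for k in KNN_GRID if k <= len(y) - 1]
        inner = StratifiedKFold(
            n_splits=min(3, int(counts.min())), shuffle=True,
            random_state=model.spec.seed,
        )
        search = GridSearchCV(est, {"n_neighbors": grid}, cv=inner)
        search.fit(Xv, y)
        est = search.best_estimator_
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # sklearn >= 1.9 deprecates SVC(probability=True); retained until
            # the replacement calibration wrapper is the settled API
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(Xv, y)
    return TrainedModel(
        spec=model.spec,
        estimator=est,
        n_features=Xv.shape[1],
        n_samples=len(y),
        class_counts={int(c): int(n) for c, n in zip(classes, counts)},
        train_ids=sample_ids,
    )


def predict_scores(m: TrainedModel, X) -> np.ndarray:
    """Positive-class scores in [0, 1], one per row of X."""
    Xv, _ = _as_matrix(X)
    Xv = m._check_dim(Xv)
    proba = m.estimator.predict_proba(Xv)
    pos_col = list(m.estimator.classes_).index(1)
    return proba[:, pos_col]


def predict_labels(m: TrainedModel, X, threshold: float = 0.5) -> np.ndarray:
    """Hard labels by thresholding the positive-class score at 0.5."""
    return (predict_scores(m, X) >= threshold).astype(int)


def save_model(m: TrainedModel, path: str | Path) -> Path:
    """Persist a trained model (spec + estimator + metadata) to one file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {
            "spec": m.spec.to_dict(),
            "estimator": m.estimator,
            "n_features": m.n_features,
            "n_samples": m.n_samples,
            "class_counts": m.class_counts,
            "train_ids": m.train_ids,
        },
        path,
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(
        spec=ModelSpec.from_dict(blob["spec"]),
        estimator=blob["estimator"],
        n_features=blob["n_features"],
        n_samples=blob["n_samples"],
        class_counts=blob["class_counts"],
        train_ids=tuple(blob["train_ids"]) if blob["train_ids"] else None,
    )
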