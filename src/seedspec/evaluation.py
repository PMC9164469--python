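"""Classifier training and evaluation.

Two classifier families, both with library-default hyperparameters:
LDA (scikit-learn ``LinearDiscriminantAnalysis``) and a linear-kernel
SVM (``SVC(kernel="linear")``).  Accuracy is reported as the pooled
fraction of correctly classified held-out objects over stratified
k-fold cross-validation (k = 10 by default), times 100.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._rng import derive_int
from .spectra_core import SpectralDataset

__all__ = [
    "ModelSpec",
    "CVResult",
    "FittedModel",
    "ValidationRow",
    "ValidationReport",
    "ParsimonyWarning",
    "cross_validated_accuracy",
    "train_full",
    "predict_germination_pct",
    "rmse",
    "validate",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("LDA", "SVM_linear")


class ParsimonyWarning(UserWarning):
    """Raised when a model is trained with more bands than the
    (objects - classes)/3 parsimony rule permits."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Classifier family; hyperparameters stay at library defaults.

    ``scale_features=None`` picks the family's library-default
    preprocessing: none for LDA (affine-invariant anyway), internal
    standardization for the linear SVM — mirroring e1071's ``svm``
    whose default is ``scale=TRUE`` (and without which libsvm does not
    converge in reasonable time on raw reflectance magnitudes).
    """

    family: str = "LDA"
    scale_features: bool | None = None

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")

    @property
    def scales_features(self) -> bool:
        if self.scale_features is None:
            return self.family == "SVM_linear"
        return self.scale_features

    def build(self):
        base = LinearDiscriminantAnalysis() if self.family == "LDA" else SVC(kernel="linear")
        if self.scales_features:
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler

            return make_pipeline(StandardScaler(), base)
        return base

    def default_hyperparameters(self) -> dict:
        """The library defaults actually in force, for the run record."""
        return self.build().get_params()


@dataclasses.dataclass(frozen=True)
class CVResult:
    accuracy_pct: float
    per_fold_accuracy: tuple[float, ...]
    fold_sizes: tuple[int, ...]
    k: int
    model_spec: ModelSpec
    rng_seed: int


@dataclasses.dataclass(frozen=True)
class ValidationRow:
    subsample_id: str
    n_seeds: int
    predicted_germination_pct: float
    known_germination_pct: float
    is_training_subsample: bool


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    rows: tuple[ValidationRow, ...]
    rmse: float
    model_spec: ModelSpec
    restrict_independent: bool = False
    variety: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])


def _check_parsimony(n_objects: int, n_classes: int, n_bands: int) -> None:
    max_bands = (n_objects - n_classes) // 3
    if n_bands > max_bands:
        warnings.warn(
            f"training with {n_bands} bands exceeds the parsimony bound "
            f"({n_objects} objects, {n_classes} classes -> max {max_bands} bands); "
            "over-fitting risk",
            ParsimonyWarning,
            stacklevel=3,
        )


def _fit(model: ModelSpec, X: np.ndarray, y: np.ndarray):
    _check_parsimony(len(y), len(np.unique(y)), X.shape[1])
    est = model.build()
    est.fit(X, y)
    return est


def cross_validated_accuracy(
    dataset: SpectralDataset,
    model: ModelSpec,
    k: int = 10,
    rng_seed: int = 0,
) -> CVResult:
    """Pooled accuracy over stratified k-fold cross-validation.

    Objects are partitioned into k stratified folds (shuffled with a
    seed derived from ``rng_seed``); each fold is scored by a model
    trained on the other k-1 folds.  ``accuracy_pct`` pools all held-out
    predictions; per-fold accuracies are retained.  Deterministic given
    (dataset, model, k, rng_seed).
    """
    counts = dataset.class_counts()
    if counts.n_class0 == 0 or counts.n_class1 == 0:
        raise ValueError("cross-validation requires both classes present")
    if min(counts.n_class0, counts.n_class1) < k:
        raise ValueError(
            f"each class needs >= k={k} members "
            f"(have {counts.n_class0} and {counts.n_class1})"
        )

    X, y = dataset.reflectance, dataset.labels
    splitter = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=derive_int(rng_seed, "cv-folds") % (2**32)
    )
    per_fold: list[float] = []
    fold_sizes: list[int] = []
    n_correct = 0
    for train_idx, test_idx in splitter.split(X, y):
        est = _fit(model, X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        hits = int(np.sum(pred == y[test_idx]))
        n_correct += hits
        per_fold.append(100.0 * hits / len(test_idx))
        fold_sizes.append(len(test_idx))
    return CVResult(
        accuracy_pct=100.0 * n_correct / len(y),
        per_fold_accuracy=tuple(per_fold),
        fold_sizes=tuple(fold_sizes),
        k=k,
        model_spec=model,
        rng_seed=rng_seed,
    )


@dataclasses.dataclass
class FittedModel:
    """Opaque handle over a fitted classifier, bound to a band grid."""

    model_spec: ModelSpec
    band_grid: "object"
    _estimator: object

    def predict(self, dataset: SpectralDataset) -> np.ndarray:
        if dataset.band_grid != self.band_grid:
            raise ValueError(
                f"band-grid mismatch: model has {self.band_grid.n_bands} bands, "
                f"data has {dataset.n_bands}"
            )
        return np.asarray(self._estimator.predict(dataset.reflectance))


def train_full(dataset: SpectralDataset, model: ModelSpec) -> FittedModel:
    """Fit on the full dataset; returns a predict-capable handle."""
    counts = dataset.class_counts()
    if counts.n_class0 == 0 or counts.n_class1 == 0:
        raise ValueError("training requires both classes present")
    est = _fit(model, dataset.reflectance, dataset.labels)
    return FittedModel(model_spec=model, band_grid=dataset.band_grid, _estimator=est)


def predict_germination_pct(model_handle: FittedModel, subsample: SpectralDataset) -> float:
    """100 x (profiles predicted germinating) / n_profiles."""
    if subsample.n_profiles == 0:
        raise ValueError("subsample must be non-empty")
    pred = model_handle.predict(subsample)
    return 100.0 * float(np.sum(pred == 1)) / subsample.n_profiles


def rmse(predicted: Sequence[float], known: Sequence[float]) -> float:
    """sqrt(mean squared difference) of two equal-length percent lists."""
    p = np.asarray(predicted, dtype=float)
    q = np.asarray(known, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("predicted and known must be equal-length 1-D sequences")
    if p.size == 0:
        raise ValueError("rmse of empty lists is undefined")
    return float(np.sqrt(np.mean((p - q) ** 2)))


def validate(
    model_handle: FittedModel,
    subsamples: Sequence[tuple[SpectralDataset, float, bool]],
    restrict_independent: bool = False,
    variety: str = "",
) -> ValidationReport:
    """Per-subsample predicted vs known germination percentage + RMSE.

    ``subsamples`` are (dataset, known_pct, is_training_subsample)
    triples.  RMSE covers all rows by default; with
    ``restrict_independent`` only non-training subsamples enter.
    """
    if not subsamples:
        raise ValueError("at least one validation subsample is required")
    rows = []
    for ds, known_pct, is_training in subsamples:
        sid = str(ds.subsample_ids[0]) if ds.n_profiles else ""
        rows.append(
            ValidationRow(
                subsample_id=sid,
                n_seeds=ds.n_profiles,
                predicted_germination_pct=predict_germination_pct(model_handle, ds),
                known_germination_pct=float(known_pct),
                is_training_subsample=bool(is_training),
            )
        )
    included = [r for r in rows if not (restrict_independent and r.is_training_subsample)]
    if not included:
        raise ValueError("restrict_independent excluded every subsample")
    value = rmse(
        [r.predicted_germination_pct for r in included],
        [r.known_germination_pct for r in included],
    )
    return ValidationReport(
        rows=tuple(rows),
        rmse=value,
        model_spec=model_handle.model_spec,
        restrict_independent=restrict_independent,
        variety=variety,
    )
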