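"""Manipulation sweeps, accuracy-vs-level regression, paired family
comparisons, and the parsimony (over-fitting) guard.

A sweep applies one manipulation at each grid level to a fresh copy of
the training set (held-out folds are perturbed too), runs ten-fold
cross-validation, and records one accuracy point per level.  Per-level
perturbation seeds derive from (plan seed, kind, level, replicate), so
two classifier families swept under the same plan see bit-identical
perturbed data — the premise of the paired t-test comparison.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_int, derive_rng
from .evaluation import CVResult, ModelSpec, cross_validated_accuracy
from .perturbations import ManipulationPlan, apply_manipulation
from .spectra_core import SpectralDataset

__all__ = [
    "AccuracyCurve",
    "RegressionSummary",
    "PairedTestResult",
    "ParsimonyGuard",
    "run_sweep",
    "fit_linear",
    "paired_t_test",
    "parsimony_guard",
    "compare_families",
    "DegenerateVarianceError",
]


class DegenerateVarianceError(ValueError):
    """Paired differences have zero variance; t is undefined."""


@dataclasses.dataclass(frozen=True)
class AccuracyCurve:
    """(level %, accuracy %) points for one family under one manipulation.

    ``points`` hold replicate-averaged accuracies; ``replicate_points``
    keeps the raw (level %, replicate, accuracy %) triples.
    """

    kind: str
    points: tuple[tuple[float, float], ...]
    model_spec: ModelSpec
    rng_seed: int
    replicate_points: tuple[tuple[float, int, float], ...] = ()

    def __post_init__(self) -> None:
        levels = [p[0] for p in self.points]
        if list(levels) != sorted(set(levels)):
            raise ValueError("curve levels must be strictly increasing")

    @property
    def levels_pct(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    @property
    def accuracies_pct(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        rows = self.replicate_points or tuple(
            (lvl, 0, acc) for lvl, acc in self.points
        )
        return pd.DataFrame(
            [
                (self.kind, lvl, rep, self.model_spec.family, acc)
                for lvl, rep, acc in rows
            ],
            columns=["kind", "level_pct", "replicate", "family", "accuracy_pct"],
        )


@dataclasses.dataclass(frozen=True)
class RegressionSummary:
    """OLS of accuracy (%) on manipulation level (%)."""

    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    n_points: int


@dataclasses.dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float


@dataclasses.dataclass(frozen=True)
class ParsimonyGuard:
    """Maximum explanatory bands = floor((objects - classes)/3)."""

    objects: int
    classes: int
    max_bands: int


def cv_seed_for_plan(plan: ManipulationPlan) -> int:
    """The fold seed shared by every level of a sweep (level 0 therefore
    reproduces the unmanipulated baseline bit-identically)."""
    return derive_int(plan.rng_seed, "cv")


def _level_rng(plan: ManipulationPlan, level: float, replicate: int):
    return derive_rng(plan.rng_seed, plan.kind, float(level), int(replicate))


def _sweep(
    dataset: SpectralDataset,
    plan: ManipulationPlan,
    models: tuple[ModelSpec, ...],
    k: int,
) -> dict[str, AccuracyCurve]:
    cv_seed = cv_seed_for_plan(plan)
    mean_points: dict[str, list[tuple[float, float]]] = {m.family: [] for m in models}
    rep_points: dict[str, list[tuple[float, int, float]]] = {m.family: [] for m in models}
    for level in plan.levels:
        accs: dict[str, list[float]] = {m.family: [] for m in models}
        for rep in range(plan.replicates):
            perturbed = apply_manipulation(
                dataset, plan.kind, level, _level_rng(plan, level, rep)
            )
            for model in models:
                result: CVResult = cross_validated_accuracy(
                    perturbed, model, k=k, rng_seed=cv_seed
                )
                accs[model.family].append(result.accuracy_pct)
                rep_points[model.family].append((100.0 * level, rep, result.accuracy_pct))
        for model in models:
            mean_points[model.family].append(
                (100.0 * level, float(np.mean(accs[model.family])))
            )
    return {
        m.family: AccuracyCurve(
            kind=plan.kind,
            points=tuple(mean_points[m.family]),
            model_spec=m,
            rng_seed=plan.rng_seed,
            replicate_points=tuple(rep_points[m.family]),
        )
        for m in models
    }


def run_sweep(
    dataset: SpectralDataset,
    plan: ManipulationPlan,
    model: ModelSpec,
    k: int = 10,
) -> AccuracyCurve:
    """One accuracy curve: plan levels x replicates, replicate-averaged."""
    return _sweep(dataset, plan, (model,), k)[model.family]


def compare_families(
    dataset: SpectralDataset,
    plan: ManipulationPlan,
    k: int = 10,
) -> tuple[AccuracyCurve, AccuracyCurve, PairedTestResult]:
    """Sweep LDA and linear SVM over identical perturbed datasets per
    level, then paired t-test on the two level-averaged accuracy vectors."""
    curves = _sweep(dataset, plan, (ModelSpec("LDA"), ModelSpec("SVM_linear")), k)
    lda, svm = curves["LDA"], curves["SVM_linear"]
    test = paired_t_test(lda.accuracies_pct, svm.accuracies_pct)
    return lda, svm, test


def fit_linear(curve: AccuracyCurve) -> RegressionSummary:
    """Ordinary least squares of accuracy on level over all curve points."""
    x = np.asarray(curve.levels_pct, dtype=float)
    y = np.asarray(curve.accuracies_pct, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("levels have zero variance; regression undefined")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adjusted = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionSummary(
        slope=slope, intercept=intercept, r2=r2, adjusted_r2=adjusted, n_points=n
    )


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("paired differences have zero variance")
    mean_d = float(np.mean(d))
    t = mean_d / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(t_statistic=t, df=df, p_value=p, mean_difference=mean_d)


def parsimony_guard(objects: int, classes: int) -> ParsimonyGuard:
    """Maximum explanatory spectral bands: floor((objects - classes)/3)."""
    if classes < 2:
        raise ValueError("at least 2 classes are required")
    if objects <= classes:
        raise ValueError("objects must exceed classes")
    return ParsimonyGuard(
        objects=int(objects),
        classes=int(classes),
        max_bands=(int(objects) - int(classes)) // 3,
    )
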