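"""The three controlled training-data manipulations.

Each manipulation is a pure, seeded transform of a SpectralDataset:

* ``flip_labels`` — class-assignment error: an equal fraction of each
  class is drawn at random and its labels are inverted.
* ``add_spectral_noise`` — repeatability degradation: every reflectance
  value v becomes v*(1+u) with u ~ Uniform(-r, +r), i.i.d. per value.
* ``reduce_training`` — ablation: an equal fraction of each class is
  removed at random.

Counts use round-half-away-from-zero on ``rate * n_class``, fixed here
for reproducibility (the worked grid values are exact integers under any
rounding rule).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra_core import SpectralDataset

__all__ = [
    "FlipRecord",
    "ManipulationPlan",
    "flip_labels",
    "undo_flips",
    "add_spectral_noise",
    "add_spectral_noise_directional",
    "reduce_training",
    "apply_manipulation",
    "FLIP_LEVELS",
    "NOISE_LEVELS",
    "REDUCTION_LEVELS",
    "DEFAULT_LEVELS",
]

#: Default level grids (fractions) for the three manipulation kinds.
FLIP_LEVELS = (0.0, 0.01, 0.02, 0.04, 0.06, 0.08, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)
NOISE_LEVELS = (0.0, 0.005, 0.01, 0.02, 0.04, 0.06, 0.08, 0.10)
REDUCTION_LEVELS = (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.75, 0.90)

DEFAULT_LEVELS = {
    "assignment_error": FLIP_LEVELS,
    "spectral_noise": NOISE_LEVELS,
    "size_reduction": REDUCTION_LEVELS,
}

_LEVEL_DOMAIN = {
    "assignment_error": (0.0, 0.5),
    "spectral_noise": (0.0, 0.10),
    "size_reduction": (0.0, 0.90),
}


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero for non-negative x."""
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class FlipRecord:
    """One label inversion in a flip log."""

    object_id: str
    original_label: int
    new_label: int

    def __post_init__(self) -> None:
        if self.original_label == self.new_label:
            raise ValueError("original_label must differ from new_label")


@dataclasses.dataclass(frozen=True)
class ManipulationPlan:
    """One manipulation sweep: kind, level grid, replicates, seed."""

    kind: str
    levels: tuple[float, ...]
    replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _LEVEL_DOMAIN:
            raise ValueError(
                f"kind must be one of {sorted(_LEVEL_DOMAIN)}, got {self.kind!r}"
            )
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        lo, hi = _LEVEL_DOMAIN[self.kind]
        for v in levels:
            if not lo <= v <= hi:
                raise ValueError(f"{self.kind} level {v} outside [{lo}, {hi}]")
        if list(levels) != sorted(set(levels)):
            raise ValueError("levels must be strictly ascending")
        if not levels or levels[0] != 0.0:
            raise ValueError("level grid must include 0 (the unmanipulated baseline)")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")

    @classmethod
    def default(cls, kind: str, replicates: int = 1, rng_seed: int = 0) -> "ManipulationPlan":
        return cls(kind=kind, levels=DEFAULT_LEVELS[kind], replicates=replicates, rng_seed=rng_seed)


def _per_class_draw(
    labels: np.ndarray, rate: float, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Per class, draw round(rate * n_c) row indices without replacement."""
    out: dict[int, np.ndarray] = {}
    for cls in (0, 1):
        rows = np.flatnonzero(labels == cls)
        k = _round_half_away(rate * len(rows))
        chosen = rng.choice(rows, size=k, replace=False) if k else np.empty(0, dtype=int)
        out[cls] = np.sort(chosen)
    return out


def flip_labels(
    dataset: SpectralDataset, rate: float, rng: np.random.Generator
) -> tuple[SpectralDataset, list[FlipRecord]]:
    """Invert the labels of a random ``rate`` fraction of each class.

    The same count round(rate * n_c) is drawn separately from each class,
    so balanced inputs stay balanced exactly.  Reflectance is untouched.
    Returns the perturbed dataset and the flip log.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"flip rate must be in [0, 0.5], got {rate}")
    counts = dataset.class_counts()
    if counts.n_class0 == 0 or counts.n_class1 == 0:
        raise ValueError("flip_labels requires both classes to be non-empty")

    out = dataset.copy()
    records: list[FlipRecord] = []
    for cls, rows in _per_class_draw(dataset.labels, rate, rng).items():
        out.labels[rows] = 1 - cls
        records.extend(
            FlipRecord(object_id=str(dataset.object_ids[i]), original_label=cls, new_label=1 - cls)
            for i in rows
        )
    return out, records


def undo_flips(dataset: SpectralDataset, records: list[FlipRecord]) -> SpectralDataset:
    """Invert the logged flips again; an involution on the flipped set."""
    out = dataset.copy()
    index = {str(oid): i for i, oid in enumerate(out.object_ids)}
    for rec in records:
        i = index[rec.object_id]
        if out.labels[i] != rec.new_label:
            raise ValueError(f"object {rec.object_id!r} does not carry the logged label")
        out.labels[i] = rec.original_label
    return out


def flip_log_frame(records: list[FlipRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.object_id, r.original_label, r.new_label) for r in records],
        columns=["object_id", "original_label", "new_label"],
    )


def write_flip_log(records: list[FlipRecord], path: str | Path) -> Path:
    path = Path(path)
    flip_log_frame(records).to_csv(path, index=False)
    return path


def add_spectral_noise_directional(
    dataset: SpectralDataset,
    noise_range: float,
    sign: str = "both",
    band_window_nm: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> SpectralDataset:
    """Multiplicative uniform noise, optionally one-sided and windowed.

    ``u`` is drawn per (profile, band) and mapped to Uniform(-r, +r) for
    ``sign="both"``, Uniform(0, +r) for ``"positive"`` and Uniform(-r, 0)
    for ``"negative"``; it is applied only to bands inside
    ``band_window_nm`` (all bands when absent).  With ``sign="both"`` and
    no window this consumes the RNG stream identically to
    :func:`add_spectral_noise`.
    """
    if noise_range < 0:
        raise ValueError(f"noise range must be >= 0, got {noise_range}")
    if sign not in ("both", "positive", "negative"):
        raise ValueError(f"sign must be 'both', 'positive' or 'negative', got {sign!r}")
    if rng is None:
        raise ValueError("a seeded rng is required")

    if band_window_nm is None:
        mask = np.ones(dataset.n_bands, dtype=bool)
    else:
        mask = dataset.band_grid.window_mask(*band_window_nm)
        if not mask.any():
            raise ValueError(f"band window {band_window_nm} contains no bands")

    # one base draw per value regardless of sign/window keeps substreams
    # comparable across variants
    base = rng.uniform(0.0, 1.0, size=dataset.reflectance.shape)
    if sign == "both":
        u = (2.0 * base - 1.0) * noise_range
    elif sign == "positive":
        u = base * noise_range
    else:
        u = -base * noise_range

    out = dataset.copy()
    out.reflectance[:, mask] = dataset.reflectance[:, mask] * (1.0 + u[:, mask])
    return out


def add_spectral_noise(
    dataset: SpectralDataset, noise_range: float, rng: np.random.Generator
) -> SpectralDataset:
    """Replace every value v by v*(1+u), u ~ Uniform(-r, +r) i.i.d.

    A value of 1000 under r = 0.02 therefore lands in [980, 1020].
    Labels and the value count are untouched.
    """
    return add_spectral_noise_directional(dataset, noise_range, sign="both", rng=rng)


def reduce_training(
    dataset: SpectralDataset, fraction: float, rng: np.random.Generator
) -> SpectralDataset:
    """Remove a random ``fraction`` of each class, preserving balance.

    round(fraction * n_c) profiles are removed per class; the remaining
    profiles are untouched and keep their original order.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"reduction fraction must be in [0, 1), got {fraction}")
    counts = dataset.class_counts()
    for cls, n in ((0, counts.n_class0), (1, counts.n_class1)):
        if n and n - _round_half_away(fraction * n) < 1:
            raise ValueError(f"fraction {fraction} would empty class {cls}")

    drop = np.zeros(dataset.n_profiles, dtype=bool)
    for rows in _per_class_draw(dataset.labels, fraction, rng).values():
        drop[rows] = True
    return dataset.subset(~drop)


def apply_manipulation(
    dataset: SpectralDataset, kind: str, level: float, rng: np.random.Generator
) -> SpectralDataset:
    """Dispatch one manipulation by kind (flip logs discarded)."""
    if kind == "assignment_error":
        return flip_labels(dataset, level, rng)[0]
    if kind == "spectral_noise":
        return add_spectral_noise(dataset, level, rng)
    if kind == "size_reduction":
        return reduce_training(dataset, level, rng)
    raise ValueError(f"unknown manipulation kind {kind!r}")
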