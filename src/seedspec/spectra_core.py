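"""Data model for labeled reflectance profiles and lossless tabular I/O.

A dataset is a table of per-object average reflectance profiles: one row
per seed with an object id, a subsample (seed lot) id, a binary
germination label (non-germination = 0, germination = 1) and one column
per spectral band.  Reflectance is kept in arbitrary relative units; no
normalization is imposed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BandGrid",
    "SpectralProfile",
    "SpectralDataset",
    "ClassBalance",
    "read_profiles_csv",
    "write_profiles_csv",
    "class_counts",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("object_id", "subsample_id", "label")


@dataclasses.dataclass(frozen=True)
class BandGrid:
    """An ordered grid of spectral-band center wavelengths in nm."""

    wavelengths_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", wl)
        if len(wl) < 2:
            raise ValueError("band grid needs at least 2 bands")
        arr = np.asarray(wl, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("wavelengths must be finite")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths_nm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)

    @classmethod
    def uniform(cls, start_nm: float, stop_nm: float, n_bands: int) -> "BandGrid":
        """Evenly spaced grid of ``n_bands`` covering [start_nm, stop_nm]."""
        return cls(tuple(np.linspace(start_nm, stop_nm, n_bands)))

    def window_mask(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Boolean mask of bands with low_nm <= wavelength <= high_nm."""
        arr = self.as_array()
        return (arr >= low_nm) & (arr <= high_nm)


@dataclasses.dataclass(frozen=True)
class ClassBalance:
    """Per-class object counts (class 0 = non-germinating)."""

    n_class0: int
    n_class1: int

    def __post_init__(self) -> None:
        if self.n_class0 < 0 or self.n_class1 < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_class0 + self.n_class1


@dataclasses.dataclass(frozen=True)
class SpectralProfile:
    """One object's average reflectance profile with its label."""

    object_id: str
    subsample_id: str
    label: int
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", refl)
        if int(self.label) not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        object.__setattr__(self, "label", int(self.label))
        if refl.ndim != 1:
            raise ValueError("reflectance must be a 1-D vector")
        if not np.all(np.isfinite(refl)) or np.any(refl < 0):
            raise ValueError("reflectance values must be finite and >= 0")


class SpectralDataset:
    """Profiles x bands with labels and subsample metadata.

    Internally columnar (object_ids, subsample_ids, labels, and an
    (n_profiles, n_bands) reflectance matrix) for vectorized transforms.
    """

    def __init__(
        self,
        band_grid: BandGrid,
        object_ids: Iterable[str],
        subsample_ids: Iterable[str],
        labels: Iterable[int],
        reflectance: np.ndarray,
        provenance: str = "",
    ) -> None:
        self.band_grid = band_grid
        self.object_ids = np.asarray(list(object_ids), dtype=object)
        self.subsample_ids = np.asarray(list(subsample_ids), dtype=object)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.reflectance = np.asarray(reflectance, dtype=float)
        if self.reflectance.size == 0:
            self.reflectance = self.reflectance.reshape(0, band_grid.n_bands)
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        n = len(self.object_ids)
        if len(self.subsample_ids) != n or len(self.labels) != n:
            raise ValueError("metadata columns have inconsistent lengths")
        if self.reflectance.ndim != 2 or self.reflectance.shape != (n, self.band_grid.n_bands):
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{n} profiles x {self.band_grid.n_bands} bands"
            )
        if n and len(set(self.object_ids)) != n:
            raise ValueError("object_ids must be unique")
        bad = ~np.isin(self.labels, (0, 1))
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"label must be 0 or 1; object {self.object_ids[i]!r} has {self.labels[i]}"
            )
        finite = np.isfinite(self.reflectance)
        if not finite.all():
            i, j = (int(x[0]) for x in np.nonzero(~finite))
            raise ValueError(
                f"non-finite reflectance at object {self.object_ids[i]!r}, "
                f"band {self.band_grid.wavelengths_nm[j]} nm"
            )
        neg = self.reflectance < 0
        if neg.any():
            i, j = (int(x[0]) for x in np.nonzero(neg))
            raise ValueError(
                f"negative reflectance at object {self.object_ids[i]!r}, "
                f"band {self.band_grid.wavelengths_nm[j]} nm"
            )

    # -- basic views ---------------------------------------------------

    @property
    def n_profiles(self) -> int:
        return len(self.object_ids)

    @property
    def n_bands(self) -> int:
        return self.band_grid.n_bands

    @property
    def n_values(self) -> int:
        """Number of scalar reflectance values (profiles x bands)."""
        return self.n_profiles * self.n_bands

    def profiles(self) -> Iterator[SpectralProfile]:
        for i in range(self.n_profiles):
            yield SpectralProfile(
                object_id=str(self.object_ids[i]),
                subsample_id=str(self.subsample_ids[i]),
                label=int(self.labels[i]),
                reflectance=self.reflectance[i].copy(),
            )

    @classmethod
    def from_profiles(
        cls,
        band_grid: BandGrid,
        profiles: Iterable[SpectralProfile],
        provenance: str = "",
    ) -> "SpectralDataset":
        profiles = list(profiles)
        refl = (
            np.vstack([p.reflectance for p in profiles])
            if profiles
            else np.empty((0, band_grid.n_bands))
        )
        return cls(
            band_grid=band_grid,
            object_ids=[p.object_id for p in profiles],
            subsample_ids=[p.subsample_id for p in profiles],
            labels=[p.label for p in profiles],
            reflectance=refl,
            provenance=provenance,
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            band_grid=self.band_grid,
            object_ids=self.object_ids.copy(),
            subsample_ids=self.subsample_ids.copy(),
            labels=self.labels.copy(),
            reflectance=self.reflectance.copy(),
            provenance=self.provenance,
        )

    def subset(self, index: np.ndarray) -> "SpectralDataset":
        """Row subset (positional index array or boolean mask), order kept."""
        return SpectralDataset(
            band_grid=self.band_grid,
            object_ids=self.object_ids[index],
            subsample_ids=self.subsample_ids[index],
            labels=self.labels[index],
            reflectance=self.reflectance[index],
            provenance=self.provenance,
        )

    def class_counts(self) -> ClassBalance:
        return ClassBalance(
            n_class0=int(np.sum(self.labels == 0)),
            n_class1=int(np.sum(self.labels == 1)),
        )

    def equals(self, other: "SpectralDataset") -> bool:
        """Field-by-field exact equality (used by round-trip checks)."""
        return (
            self.band_grid == other.band_grid
            and np.array_equal(self.object_ids, other.object_ids)
            and np.array_equal(self.subsample_ids, other.subsample_ids)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.reflectance, other.reflectance)
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"SpectralDataset(n_profiles={self.n_profiles}, n_bands={self.n_bands}, "
            f"class_counts={self.class_counts()})"
        )


def class_counts(dataset: SpectralDataset) -> ClassBalance:
    """Exact per-class profile counts."""
    return dataset.class_counts()


def _parse_band_columns(columns: list[str]) -> tuple[BandGrid, list[str]]:
    band_cols = [c for c in columns if c not in METADATA_COLUMNS]
    wavelengths = []
    for c in band_cols:
        try:
            wavelengths.append(float(c))
        except ValueError as exc:
            raise ValueError(f"band column {c!r} is not a wavelength") from exc
    return BandGrid(tuple(wavelengths)), band_cols


def read_profiles_csv(path: str | Path) -> SpectralDataset:
    """Read a profiles table written by :func:`write_profiles_csv`.

    Expected header: ``object_id, subsample_id, label`` followed by one
    column per band named by its wavelength in nm (e.g. ``"432.0"``);
    band order is taken from header order.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={"object_id": str, "subsample_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    band_grid, band_cols = _parse_band_columns(list(frame.columns))

    labels = frame["label"].to_numpy()
    for i, lab in enumerate(labels):
        if lab not in (0, 1, "0", "1"):
            raise ValueError(
                f"{path}: row {i} (object_id={frame['object_id'].iloc[i]!r}) "
                f"has non-binary label {lab!r}"
            )
    refl = np.empty((len(frame), len(band_cols)), dtype=float)
    for j, col in enumerate(band_cols):
        values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any() and len(frame):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric reflectance in row {i} "
                f"(object_id={frame['object_id'].iloc[i]!r}), column {col!r}"
            )
        refl[:, j] = values
    return SpectralDataset(
        band_grid=band_grid,
        object_ids=frame["object_id"].astype(str).tolist(),
        subsample_ids=frame["subsample_id"].astype(str).tolist(),
        labels=np.asarray(labels, dtype=np.int64),
        reflectance=refl,
        provenance=f"read from {path.name}",
    )


def write_profiles_csv(dataset: SpectralDataset, path: str | Path) -> Path:
    """Write the dataset as CSV; exact numeric round-trip guaranteed.

    Floats are serialized with Python's shortest round-trip repr, so
    ``read_profiles_csv(write_profiles_csv(ds))`` reproduces ``ds``
    field-by-field.
    """
    path = Path(path)
    band_names = [repr(w) for w in dataset.band_grid.wavelengths_nm]
    frame = pd.DataFrame(
        {
            "object_id": dataset.object_ids,
            "subsample_id": dataset.subsample_ids,
            "label": dataset.labels,
        }
    )
    refl = pd.DataFrame(dataset.reflectance, columns=band_names, index=frame.index)
    pd.concat([frame, refl], axis=1).to_csv(path, index=False)
    return path
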