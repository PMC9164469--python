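"""Synthetic labeled seed spectra with controllable class separability.

The generator produces datasets with the statistical structure the
downstream assessment protocol needs to exercise: several subsamples
(seed lots) with visibly shifted mean profiles, a small multiplicative
class effect concentrated around 650 nm (germinating seeds slightly more
reflective), per-seed scale variation and independent band-wise noise.

Model, per profile:

    reflectance = base_level * base_curve(lambda)
                  * g(lambda)^label            (Gaussian bump, see class_effect)
                  * subsample scale * subsample tilt
                  * seed scale * (1 + band noise)

All randomness flows from one integer seed through four named
substreams (subsample effects, labels, per-seed scale, band noise), so
equal seeds give byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np

from ._rng import derive_seed_sequence
from .spectra_core import BandGrid, SpectralDataset

__all__ = [
    "GeneratorConfig",
    "CalibrationError",
    "base_curve",
    "class_effect",
    "generate",
    "calibrate_separability",
    "preset",
    "PRESET_NAMES",
]

#: Default band grid: 221 bands spanning 432-1025 nm.
DEFAULT_BAND_GRID = BandGrid.uniform(432.0, 1025.0, 221)

#: (subsample_id, n_seeds, germination_rate) triples per preset.  Sizes
#: are the two training seed lots of each variety; rates are the lots'
#: germination percentages.
_PRESETS: dict[str, dict] = {
    "variety1": {
        "subsamples": (("1a", 496, 0.97), ("1e", 1751, 0.56)),
        "subsample_scale_sd": 0.05,
    },
    "variety2": {
        "subsamples": (("2f", 513, 0.97), ("2j", 886, 0.73)),
        # lot-to-lot spread is visibly larger for this variety
        "subsample_scale_sd": 0.10,
    },
}

PRESET_NAMES = tuple(_PRESETS)


class CalibrationError(RuntimeError):
    """Separability calibration failed to bracket the target accuracy."""


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-spectra generator."""

    subsamples: tuple[tuple[str, int, float], ...]
    band_grid: BandGrid = DEFAULT_BAND_GRID
    class_effect_amplitude: float = 0.05
    class_effect_center_nm: float = 650.0
    class_effect_width_nm: float = 60.0
    subsample_scale_sd: float = 0.05
    subsample_tilt_sd: float = 0.02
    seed_scale_sd: float = 0.08
    band_noise_sd: float = 0.01
    base_level: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        subs = tuple((str(s), int(n), float(r)) for s, n, r in self.subsamples)
        object.__setattr__(self, "subsamples", subs)
        if not subs:
            raise ValueError("at least one subsample is required")
        for sid, n, rate in subs:
            if n <= 0:
                raise ValueError(f"subsample {sid!r}: n_seeds must be positive")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"subsample {sid!r}: germination_rate must be in [0, 1]")
        for name in ("subsample_scale_sd", "subsample_tilt_sd", "seed_scale_sd", "band_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.class_effect_amplitude < 0:
            raise ValueError("class_effect_amplitude must be >= 0")
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_grid"] = {
            "start_nm": self.band_grid.wavelengths_nm[0],
            "stop_nm": self.band_grid.wavelengths_nm[-1],
            "n_bands": self.band_grid.n_bands,
        }
        d["subsamples"] = [list(s) for s in self.subsamples]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        bg = d.get("band_grid")
        if isinstance(bg, dict):
            d["band_grid"] = BandGrid.uniform(bg["start_nm"], bg["stop_nm"], bg["n_bands"])
        elif isinstance(bg, (list, tuple)):
            d["band_grid"] = BandGrid(tuple(bg))
        d["subsamples"] = tuple(tuple(s) for s in d["subsamples"])
        return cls(**d)


def preset(name: str, rng_seed: int = 0, **overrides) -> GeneratorConfig:
    """A ready-made GeneratorConfig for one of the two variety presets."""
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    kwargs = dict(spec)
    kwargs.update(overrides)
    return GeneratorConfig(rng_seed=rng_seed, **kwargs)


def base_curve(band_grid: BandGrid) -> np.ndarray:
    """Smooth vegetation-like baseline with a red-edge rise.

    Deterministic in the wavelengths; strictly positive; monotone
    non-decreasing through 680-760 nm (the logistic red-edge term
    dominates there).
    """
    wl = band_grid.as_array()
    green_bump = 0.04 * np.exp(-0.5 * ((wl - 550.0) / 40.0) ** 2)
    red_edge = 0.45 / (1.0 + np.exp(-(wl - 715.0) / 20.0))
    return 0.35 + green_bump + red_edge


def class_effect(
    band_grid: BandGrid,
    amplitude: float,
    center_nm: float = 650.0,
    width_nm: float = 60.0,
) -> np.ndarray:
    """Multiplicative germination effect g(lambda) >= 1.

    g(lambda) = 1 + amplitude * exp(-(lambda - center)^2 / (2 width^2)),
    peaking at the band nearest ``center_nm``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    wl = band_grid.as_array()
    return 1.0 + amplitude * np.exp(-0.5 * ((wl - center_nm) / width_nm) ** 2)


def generate(config: GeneratorConfig) -> SpectralDataset:
    """Draw a full labeled dataset; reproducible from ``config.rng_seed``."""
    grid = config.band_grid
    wl = grid.as_array()
    ss = derive_seed_sequence(config.rng_seed, "generate")
    sub_rng, label_rng, scale_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    base = base_curve(grid)
    g = class_effect(
        grid,
        config.class_effect_amplitude,
        config.class_effect_center_nm,
        config.class_effect_width_nm,
    )
    # tilt coordinate centered on the grid, spanning [-0.5, 0.5]
    x = (wl - wl.mean()) / (wl[-1] - wl[0])

    object_ids: list[str] = []
    subsample_ids: list[str] = []
    labels: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    for sid, n, rate in config.subsamples:
        sub_scale = float(np.exp(sub_rng.normal(0.0, config.subsample_scale_sd)))
        tilt_slope = float(sub_rng.normal(0.0, config.subsample_tilt_sd))
        tilt = np.exp(tilt_slope * x)

        lab = label_rng.binomial(1, rate, size=n)
        seed_scale = np.exp(scale_rng.normal(0.0, config.seed_scale_sd, size=n))
        band_noise = 1.0 + noise_rng.normal(0.0, config.band_noise_sd, size=(n, grid.n_bands))

        class_factor = np.where(lab[:, None] == 1, g[None, :], 1.0)
        block = (
            config.base_level
            * base[None, :]
            * class_factor
            * sub_scale
            * tilt[None, :]
            * seed_scale[:, None]
            * band_noise
        )
        object_ids.extend(f"{sid}-{i:05d}" for i in range(n))
        subsample_ids.extend([sid] * n)
        labels.append(lab)
        blocks.append(block)

    return SpectralDataset(
        band_grid=grid,
        object_ids=object_ids,
        subsample_ids=subsample_ids,
        labels=np.concatenate(labels),
        reflectance=np.vstack(blocks),
        provenance=f"synthetic(seed={config.rng_seed})",
    )


def _baseline_accuracy(config: GeneratorConfig, amplitude: float, k: int) -> float:
    # local import: evaluation depends on spectra_core only, no cycle
    from .evaluation import ModelSpec, cross_validated_accuracy

    dataset = generate(replace(config, class_effect_amplitude=amplitude))
    result = cross_validated_accuracy(
        dataset, ModelSpec("LDA"), k=k, rng_seed=config.rng_seed
    )
    return result.accuracy_pct


def calibrate_separability(
    config: GeneratorConfig,
    target_accuracy: float = 70.0,
    tolerance: float = 3.0,
    k: int = 10,
    max_iter: int = 40,
) -> GeneratorConfig:
    """Adjust the class-effect amplitude by bisection until baseline
    ten-fold LDA accuracy on a generated dataset is within
    ``target_accuracy +/- tolerance`` percent.

    The config is returned unchanged if it already meets the target.
    Raises :class:`CalibrationError` with the achieved bracket if the
    target cannot be reached within ``max_iter`` evaluations.
    """
    if not 50.0 < target_accuracy < 100.0:
        raise ValueError("target_accuracy must be in the open interval (50, 100)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    current = _baseline_accuracy(config, config.class_effect_amplitude, k)
    if abs(current - target_accuracy) <= tolerance:
        return config

    lo, acc_lo = 0.0, None
    hi = max(config.class_effect_amplitude, 1e-3)
    acc_hi = current if hi == config.class_effect_amplitude else _baseline_accuracy(config, hi, k)
    evals = 1 if hi == config.class_effect_amplitude else 2
    while acc_hi < target_accuracy and hi < 10.0 and evals < max_iter:
        hi *= 2.0
        acc_hi = _baseline_accuracy(config, hi, k)
        evals += 1
    if acc_hi < target_accuracy:
        raise CalibrationError(
            f"could not bracket target {target_accuracy}%: accuracy at "
            f"amplitude {hi:.4g} is {acc_hi:.2f}%"
        )

    best = (hi, acc_hi)
    while evals < max_iter:
        mid = 0.5 * (lo + hi)
        acc_mid = _baseline_accuracy(config, mid, k)
        evals += 1
        if abs(acc_mid - target_accuracy) < abs(best[1] - target_accuracy):
            best = (mid, acc_mid)
        if abs(acc_mid - target_accuracy) <= tolerance:
            return replace(config, class_effect_amplitude=mid)
        if acc_mid < target_accuracy:
            lo, acc_lo = mid, acc_mid
        else:
            hi, acc_hi = mid, acc_mid
    raise CalibrationError(
        f"no convergence after {max_iter} evaluations; best amplitude "
        f"{best[0]:.4g} gives {best[1]:.2f}% (bracket [{lo:.4g}, {hi:.4g}])"
    )
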