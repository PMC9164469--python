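import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seedspec._rng import derive_rng
from seedspec.perturbations import (
    FLIP_LEVELS,
    NOISE_LEVELS,
    REDUCTION_LEVELS,
    FlipRecord,
    ManipulationPlan,
    add_spectral_noise,
    add_spectral_noise_directional,
    flip_labels,
    flip_log_frame,
    reduce_training,
    undo_flips,
)

from conftest import make_balanced_dataset


def rng(seed=0):
    return derive_rng(seed, "test")


class TestManipulationPlan:
    def test_default_grids_match_protocol(self):
        assert FLIP_LEVELS == (0.0, 0.01, 0.02, 0.04, 0.06, 0.08, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)
        assert NOISE_LEVELS == (0.0, 0.005, 0.01, 0.02, 0.04, 0.06, 0.08, 0.10)
        assert REDUCTION_LEVELS == (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.75, 0.90)

    def test_level_zero_required(self):
        with pytest.raises(ValueError, match="include 0"):
            ManipulationPlan("assignment_error", (0.01, 0.02))

    def test_domain_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            ManipulationPlan("assignment_error", (0.0, 0.6))
        with pytest.raises(ValueError, match="outside"):
            ManipulationPlan("spectral_noise", (0.0, 0.2))
        with pytest.raises(ValueError, match="outside"):
            ManipulationPlan("size_reduction", (0.0, 0.95))

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            ManipulationPlan("bogus", (0.0,))

    def test_unsorted_levels_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            ManipulationPlan("spectral_noise", (0.0, 0.04, 0.02))


class TestFlipLabels:
    def test_six_percent_of_1000_flips_60_per_class(self):
        ds = make_balanced_dataset(1000, n_bands=3)
        _, log = flip_labels(ds, 0.06, rng())
        per_class = {0: 0, 1: 0}
        for rec in log:
            per_class[rec.original_label] += 1
        assert per_class == {0: 60, 1: 60}

    def test_rate_zero_identity(self):
        ds = make_balanced_dataset(20, n_bands=4)
        out, log = flip_labels(ds, 0.0, rng())
        assert out.equals(ds)
        assert log == []

    def test_balanced_counts_preserved(self):
        ds = make_balanced_dataset(50, n_bands=4)
        out, _ = flip_labels(ds, 0.30, rng(3))
        assert out.class_counts() == ds.class_counts()

    def test_rounding_33_at_10pct_gives_3(self):
        # round-half-away-from-zero: round(3.3) = 3 per class
        ds = make_balanced_dataset(33, n_bands=3)
        _, log = flip_labels(ds, 0.10, rng())
        assert len(log) == 6

    def test_reflectance_multiset_invariant(self):
        ds = make_balanced_dataset(30, n_bands=5, rng_seed=2)
        out, _ = flip_labels(ds, 0.2, rng(1))
        assert np.array_equal(out.reflectance, ds.reflectance)
        assert np.array_equal(out.object_ids, ds.object_ids)

    def test_involution_restores_labels(self):
        ds = make_balanced_dataset(40, n_bands=4, rng_seed=5)
        flipped, log = flip_labels(ds, 0.25, rng(7))
        restored = undo_flips(flipped, log)
        assert restored.equals(ds)

    def test_rate_out_of_domain(self):
        ds = make_balanced_dataset(10, n_bands=3)
        with pytest.raises(ValueError, match=r"\[0, 0.5\]"):
            flip_labels(ds, 0.6, rng())

    def test_empty_class_rejected(self):
        from seedspec.synthetic_data import GeneratorConfig
        from seedspec.spectra_core import BandGrid
        from seedspec.synthetic_data import generate

        ds = generate(
            GeneratorConfig(
                subsamples=(("a", 10, 1.0),),
                band_grid=BandGrid.uniform(432.0, 1025.0, 3),
                rng_seed=0,
            )
        )
        with pytest.raises(ValueError, match="non-empty"):
            flip_labels(ds, 0.1, rng())

    def test_purity(self):
        ds = make_balanced_dataset(25, n_bands=4)
        out1, log1 = flip_labels(ds, 0.2, rng(9))
        out2, log2 = flip_labels(ds, 0.2, rng(9))
        assert out1.equals(out2)
        assert log1 == log2

    def test_record_requires_distinct_labels(self):
        with pytest.raises(ValueError, match="differ"):
            FlipRecord("x", 1, 1)

    def test_flip_log_frame_columns(self):
        ds = make_balanced_dataset(10, n_bands=3)
        _, log = flip_labels(ds, 0.2, rng())
        frame = flip_log_frame(log)
        assert list(frame.columns) == ["object_id", "original_label", "new_label"]
        assert len(frame) == len(log)

    @settings(max_examples=20, deadline=None)
    @given(
        n=st.integers(min_value=10, max_value=60),
        rate=st.floats(min_value=0.0, max_value=0.5),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_log_size_matches_rounding_rule(self, n, rate, seed):
        ds = make_balanced_dataset(n, n_bands=3)
        _, log = flip_labels(ds, rate, rng(seed))
        k = int(np.floor(rate * n + 0.5))
        assert len(log) == 2 * k


class TestSpectralNoise:
    def test_worked_example_bounds_1000_pm_2pct(self):
        ds = make_balanced_dataset(50, n_bands=10, rng_seed=1)
        out = add_spectral_noise(ds, 0.02, rng(4))
        ratio = out.reflectance / ds.reflectance
        assert np.all(ratio >= 0.98)
        assert np.all(ratio <= 1.02)

    def test_zero_range_bit_identical(self):
        ds = make_balanced_dataset(10, n_bands=5)
        out = add_spectral_noise(ds, 0.0, rng())
        assert np.array_equal(out.reflectance, ds.reflectance)

    def test_mean_ratio_near_one(self):
        # 10^5 draws: mean of (perturbed/original) within 3 sd of the
        # Uniform(-r, r) mean of 1
        r = 0.05
        ds = make_balanced_dataset(500, n_bands=100, rng_seed=2)
        out = add_spectral_noise(ds, r, rng(8))
        u = out.reflectance / ds.reflectance - 1.0
        n = u.size
        assert n == 100_000
        se = (r / np.sqrt(3)) / np.sqrt(n)
        assert abs(u.mean()) <= 3 * se

    def test_uniformity_kolmogorov_smirnov(self):
        r = 0.04
        ds = make_balanced_dataset(100, n_bands=50, rng_seed=3)
        out = add_spectral_noise(ds, r, rng(12))
        u = (out.reflectance / ds.reflectance - 1.0).ravel()
        result = stats.kstest(u, stats.uniform(loc=-r, scale=2 * r).cdf)
        assert result.pvalue > 0.001

    def test_labels_and_shape_untouched(self):
        ds = make_balanced_dataset(20, n_bands=6)
        out = add_spectral_noise(ds, 0.1, rng())
        assert np.array_equal(out.labels, ds.labels)
        assert out.reflectance.shape == ds.reflectance.shape

    def test_negative_range_rejected(self):
        ds = make_balanced_dataset(5, n_bands=3)
        with pytest.raises(ValueError, match=">= 0"):
            add_spectral_noise(ds, -0.01, rng())


class TestDirectionalNoise:
    def test_positive_sign_support(self):
        ds = make_balanced_dataset(30, n_bands=8, rng_seed=4)
        out = add_spectral_noise_directional(ds, 0.02, sign="positive", rng=rng(5))
        ratio = out.reflectance / ds.reflectance
        assert np.all(ratio >= 1.0)
        assert np.all(ratio <= 1.02)

    def test_negative_sign_support(self):
        ds = make_balanced_dataset(30, n_bands=8, rng_seed=4)
        out = add_spectral_noise_directional(ds, 0.02, sign="negative", rng=rng(5))
        ratio = out.reflectance / ds.reflectance
        assert np.all(ratio <= 1.0)
        assert np.all(ratio >= 0.98)

    def test_window_leaves_outside_bands_unchanged(self):
        ds = make_balanced_dataset(20, n_bands=30, rng_seed=6)
        out = add_spectral_noise_directional(
            ds, 0.05, sign="both", band_window_nm=(600.0, 700.0), rng=rng(6)
        )
        mask = ds.band_grid.window_mask(600.0, 700.0)
        assert np.array_equal(out.reflectance[:, ~mask], ds.reflectance[:, ~mask])
        assert not np.array_equal(out.reflectance[:, mask], ds.reflectance[:, mask])

    def test_both_full_window_stream_equivalent(self):
        ds = make_balanced_dataset(15, n_bands=10, rng_seed=7)
        a = add_spectral_noise(ds, 0.03, rng(21))
        b = add_spectral_noise_directional(ds, 0.03, sign="both", rng=rng(21))
        assert a.equals(b)

    def test_empty_window_rejected(self):
        ds = make_balanced_dataset(5, n_bands=5)
        with pytest.raises(ValueError, match="no bands"):
            add_spectral_noise_directional(
                ds, 0.02, band_window_nm=(1.0, 2.0), rng=rng()
            )

    def test_bad_sign_rejected(self):
        ds = make_balanced_dataset(5, n_bands=5)
        with pytest.raises(ValueError, match="sign"):
            add_spectral_noise_directional(ds, 0.02, sign="up", rng=rng())


class TestReduceTraining:
    def test_ten_percent_of_1000_removes_100_per_class(self):
        ds = make_balanced_dataset(1000, n_bands=3)
        out = reduce_training(ds, 0.10, rng())
        cb = out.class_counts()
        assert (cb.n_class0, cb.n_class1) == (900, 900)

    def test_zero_fraction_identity(self):
        ds = make_balanced_dataset(30, n_bands=4)
        assert reduce_training(ds, 0.0, rng()).equals(ds)

    def test_ninety_percent_leaves_100_per_class(self):
        ds = make_balanced_dataset(1000, n_bands=3)
        cb = reduce_training(ds, 0.90, rng(2)).class_counts()
        assert (cb.n_class0, cb.n_class1) == (100, 100)

    def test_submultiset_and_order_preserved(self):
        ds = make_balanced_dataset(40, n_bands=5, rng_seed=9)
        out = reduce_training(ds, 0.25, rng(3))
        kept = {oid: i for i, oid in enumerate(ds.object_ids)}
        positions = [kept[oid] for oid in out.object_ids]
        assert positions == sorted(positions)
        idx = np.asarray(positions)
        assert np.array_equal(out.reflectance, ds.reflectance[idx])
        assert np.array_equal(out.labels, ds.labels[idx])

    def test_emptying_class_rejected(self):
        ds = make_balanced_dataset(2, n_bands=3)
        with pytest.raises(ValueError, match="empty class"):
            reduce_training(ds, 0.80, rng())

    def test_fraction_domain(self):
        ds = make_balanced_dataset(10, n_bands=3)
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            reduce_training(ds, 1.0, rng())

    def test_purity(self):
        ds = make_balanced_dataset(30, n_bands=4)
        assert reduce_training(ds, 0.3, rng(17)).equals(reduce_training(ds, 0.3, rng(17)))

    @settings(max_examples=20, deadline=None)
    @given(
        n=st.integers(min_value=20, max_value=80),
        fraction=st.floats(min_value=0.0, max_value=0.75),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_balance_preserved_within_rounding(self, n, fraction, seed):
        ds = make_balanced_dataset(n, n_bands=3)
        cb = reduce_training(ds, fraction, rng(seed)).class_counts()
        assert cb.n_class0 == cb.n_class1  # balanced in, balanced out
        assert cb.n_class0 == n - int(np.floor(fraction * n + 0.5))
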