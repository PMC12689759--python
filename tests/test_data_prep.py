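"""Dataset I/O, preprocessing chain, contamination arithmetic, noise, generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.io import savemat

from avehybrid.data_prep import (
    BENCHMARK_TABLE,
    NoiseSpec,
    SplitSpec,
    TabularDataset,
    apply_minmax,
    compute_outlier_fraction,
    contamination_rate,
    filter_normals,
    fit_minmax,
    generate_synthetic,
    inject_label_noise,
    load_dataset,
    select_features,
    train_test_split,
)


class TestLoadDataset:
    def test_csv(self, tmp_path):
        p = tmp_path / "toy.csv"
        pd.DataFrame(
            {"f1": [0.0, 1, 2, 3, 4], "f2": [1.0, 1, 1, 0, 0], "y": [0, 0, 0, 1, 1]}
        ).to_csv(p, index=False)
        ds = load_dataset(p)
        assert (ds.n, ds.d) == (5, 2)
        assert ds.feature_names == ["f1", "f2"]
        assert ds.n_outliers == 2

    def test_array_container(self, tmp_path):
        p = tmp_path / "toy.npz"
        np.savez(p, X=np.ones((10, 3)), y=np.r_[np.zeros(8), np.ones(2)])
        ds = load_dataset(p)
        assert (ds.n, ds.d, ds.n_outliers) == (10, 3, 2)

    def test_odds_matrix(self, tmp_path):
        p = tmp_path / "toy.mat"
        savemat(p, {"X": np.ones((10, 3)), "y": np.r_[np.zeros(7), np.ones(3)].reshape(-1, 1)})
        ds = load_dataset(p)
        assert (ds.n, ds.d) == (10, 3)
        assert ds.n_outliers == int(ds.y.sum()) == 3

    def test_nan_cell_names_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"f1": [1.0, np.nan], "y": [0, 1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="row 1.*f1"):
            load_dataset(p)

    def test_missing_label_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"f1": [1.0, 2.0], "label": [0, 1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="label column"):
            load_dataset(p)
        assert load_dataset(p, label_col="label").d == 1

    def test_non_binary_labels_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"f1": [1.0, 2.0], "y": [0, 2]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="binary"):
            load_dataset(p)


class TestSelectFeatures:
    def test_identity_is_noop(self, small_dataset):
        out = select_features(small_dataset, "identity")
        assert out is small_dataset

    def test_variance_threshold_drops_constant_column(self):
        X = np.c_[np.arange(5.0), np.full(5, 3.0)]
        ds = TabularDataset(X, np.zeros(5), ["a", "b"])
        out = select_features(ds, "variance_threshold", 0.0)
        assert out.d == 1 and out.feature_names == ["a"]

    def test_all_constant_errors(self):
        ds = TabularDataset(np.full((4, 2), 1.0), np.zeros(4))
        with pytest.raises(ValueError, match="every feature"):
            select_features(ds, "variance_threshold", 0.0)


class TestSplit:
    def make(self, n=100, n_out=10):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(n_out), np.zeros(n - n_out)].astype(int)
        return TabularDataset(rng.normal(size=(n, 3)), y)

    def test_exact_stratification_arithmetic(self):
        tr, te = train_test_split(self.make(), SplitSpec(0.6, True, 0))
        assert (tr.n, tr.n_outliers) == (60, 6)
        assert (te.n, te.n_outliers) == (40, 4)

    def test_partition_is_disjoint_and_complete(self):
        ds = self.make()
        tr, te = train_test_split(ds, SplitSpec(seed=3))
        joined = np.vstack([tr.X, te.X])
        assert joined.shape[0] == ds.n
        assert {tuple(r) for r in joined} == {tuple(r) for r in ds.X}

    def test_same_seed_reproduces_partition(self):
        ds = self.make()
        a = train_test_split(ds, SplitSpec(seed=5))
        b = train_test_split(ds, SplitSpec(seed=5))
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].y, b[1].y)

    def test_tiny_class_suggests_non_stratified(self):
        ds = TabularDataset(np.random.default_rng(0).normal(size=(10, 2)),
                            np.r_[np.ones(1), np.zeros(9)].astype(int))
        with pytest.raises(ValueError, match="stratified=False"):
            train_test_split(ds, SplitSpec(stratified=True))
        tr, te = train_test_split(ds, SplitSpec(stratified=False))
        assert tr.n + te.n == 10

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestMinMax:
    def test_column_scaling(self):
        sp = fit_minmax(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(
            apply_minmax(np.array([[0.0], [5.0], [10.0]]), sp).ravel(), [0, 0.5, 1]
        )

    def test_constant_column_maps_to_zero(self):
        sp = fit_minmax(np.full((3, 1), 3.0))
        np.testing.assert_array_equal(apply_minmax(np.full((3, 1), 3.0), sp), 0.0)

    def test_out_of_range_test_values_not_clipped(self):
        sp = fit_minmax(np.array([[0.0], [10.0]]))
        assert apply_minmax(np.array([[12.0]]), sp)[0, 0] == pytest.approx(1.2)

    def test_no_leakage_from_test_rows(self, rng):
        train = rng.normal(size=(20, 4))
        sp1 = fit_minmax(train)
        sp2 = fit_minmax(train)  # test rows never enter the fit
        np.testing.assert_array_equal(sp1.min_, sp2.min_)
        np.testing.assert_array_equal(sp1.max_, sp2.max_)

    def test_dimension_mismatch(self):
        sp = fit_minmax(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="features"):
            apply_minmax(np.zeros((3, 5)), sp)


class TestFilterNormals:
    def test_count_arithmetic(self, rng):
        y = np.r_[np.ones(6), np.zeros(54)].astype(int)
        ds = TabularDataset(rng.normal(size=(60, 2)), y)
        assert filter_normals(ds).shape[0] == 54

    def test_all_normal_is_identity(self, rng):
        ds = TabularDataset(rng.normal(size=(5, 2)), np.zeros(5))
        np.testing.assert_array_equal(filter_normals(ds), ds.X)

    def test_all_outlier_errors(self, rng):
        ds = TabularDataset(rng.normal(size=(5, 2)), np.ones(5))
        with pytest.raises(ValueError, match="no normal"):
            filter_normals(ds)

    def test_row_order_preserved(self, rng):
        X = np.arange(12.0).reshape(6, 2)
        ds = TabularDataset(X, np.array([0, 1, 0, 1, 0, 0]))
        np.testing.assert_array_equal(filter_normals(ds), X[[0, 2, 4, 5]])


class TestContaminationArithmetic:
    def test_every_benchmark_row_reproduces_printed_percentage(self):
        for name, _, n, d, n_out, printed in BENCHMARK_TABLE:
            decimals = len(str(printed).split(".")[1])
            y = np.r_[np.ones(n_out), np.zeros(n - n_out)]
            pct = 100.0 * compute_outlier_fraction(y)
            assert round(pct, decimals) == pytest.approx(printed), name

    def test_fraction_examples(self):
        assert compute_outlier_fraction(np.r_[np.ones(9), np.zeros(205)]) == pytest.approx(
            9 / 214
        )
        assert compute_outlier_fraction(np.zeros(7)) == 0.0
        with pytest.raises(ValueError):
            compute_outlier_fraction(np.array([]))

    def test_rate_is_third_of_fraction(self):
        assert contamination_rate(0.3) == pytest.approx(0.1)
        assert contamination_rate(0.0) == 0.0
        assert contamination_rate(9 / 214) == pytest.approx(0.014019, abs=5e-7)

    def test_override_replaces_computed_value(self):
        assert contamination_rate(0.3, override=0.02) == 0.02

    def test_out_of_range_fraction(self):
        with pytest.raises(ValueError):
            contamination_rate(1.5)


class TestLabelNoise:
    def make_train(self, n_anom=50, n_norm=100):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(n_anom), np.zeros(n_norm)].astype(int)
        return TabularDataset(rng.normal(size=(n_anom + n_norm, 3)), y)

    def test_zero_rate_is_noop(self):
        ds = self.make_train()
        out = inject_label_noise(ds, NoiseSpec(0.0, seed=0))
        np.testing.assert_array_equal(out.y, ds.y)

    def test_floor_arithmetic_flips_exactly(self):
        ds = self.make_train(n_anom=50)
        out = inject_label_noise(ds, NoiseSpec(0.10, seed=0))
        assert ds.n_outliers - out.n_outliers == 5

    def test_full_rate_removes_all_anomaly_labels(self):
        out = inject_label_noise(self.make_train(), NoiseSpec(1.0, seed=0))
        assert out.n_outliers == 0

    def test_features_untouched_and_flips_only_one_to_zero(self):
        ds = self.make_train()
        out = inject_label_noise(ds, NoiseSpec(0.2, seed=3))
        np.testing.assert_array_equal(out.X, ds.X)
        changed = ds.y != out.y
        assert np.all(ds.y[changed] == 1) and np.all(out.y[changed] == 0)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            NoiseSpec(1.5)


class TestGenerateSynthetic:
    def test_outlier_count_contract(self):
        ds = generate_synthetic(n=1000, d=4, contamination=0.05, seed=0)
        assert ds.n_outliers == 50
        assert compute_outlier_fraction(ds.y) == pytest.approx(0.05, abs=1 / 1000)

    def test_same_seed_bit_identical(self):
        a = generate_synthetic(n=300, d=5, contamination=0.1, seed=7)
        b = generate_synthetic(n=300, d=5, contamination=0.1, seed=7)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    @pytest.mark.parametrize("mechanism", ["uniform_background", "scaled_covariance"])
    def test_alternative_mechanisms_produce_valid_datasets(self, mechanism):
        ds = generate_synthetic(n=400, d=3, contamination=0.08, mechanism=mechanism,
                                separation=5.0, seed=2)
        assert ds.n_outliers == 32

    def test_zero_separation_outliers_indistinguishable(self):
        """With no displacement, planted 'outliers' match the inlier cluster:
        a two-sample location test on distances to the inlier mean should
        almost never reject at alpha=0.01."""
        rejections = 0
        for seed in range(20):
            ds = generate_synthetic(n=500, d=5, contamination=0.1,
                                    mechanism="shifted_cluster", separation=0.0,
                                    seed=seed)
            center = ds.X[ds.y == 0].mean(axis=0)
            dist = np.linalg.norm(ds.X - center, axis=1)
            _, p = stats.ttest_ind(dist[ds.y == 1], dist[ds.y == 0], equal_var=False)
            rejections += p < 0.01
        assert rejections <= 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_synthetic(n=100, contamination=0.6)
        with pytest.raises(ValueError):
            generate_synthetic(n=100, mechanism="bad")
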