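import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from evohis import (
    Dataset,
    SyntheticSpec,
    impute_missing,
    load_dataset,
    make_synthetic,
    minmax_normalize,
    one_hot_encode,
    supervised_resample,
)
from evohis.errors import (
    ClassCountError,
    EmptyResampleError,
    LabelColumnError,
    UnimputableFeatureError,
)


class TestLoadDataset:
    def test_csv_missing_cells_flagged(self, csv_file):
        ds = load_dataset(csv_file, "csv", label_column="cls", positive_label="yes")
        assert ds.missing_mask.sum() == 1
        assert ds.missing_mask[2, 0]
        assert list(ds.labels) == [1, 0, 1, 0]

    def test_nominal_detection_csv(self, csv_file):
        ds = load_dataset(csv_file, "csv", label_column="cls", positive_label="yes")
        assert ds.feature_kinds == ("numeric", "nominal")

    def test_three_class_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,cls\n1,x\n2,y\n3,z\n")
        with pytest.raises(ClassCountError):
            load_dataset(path, "csv", label_column="cls", positive_label="x")

    def test_single_class_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,cls\n1,x\n2,x\n")
        with pytest.raises(ClassCountError):
            load_dataset(path, "csv", label_column="cls", positive_label="x")

    def test_missing_label_column(self, csv_file):
        with pytest.raises(LabelColumnError):
            load_dataset(csv_file, "csv", label_column="nope", positive_label="yes")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "absent.csv", "csv", label_column="c", positive_label="x")

    def test_arff_declared_nominal(self, arff_file):
        ds = load_dataset(arff_file, "arff", label_column="cls", positive_label="yes")
        assert ds.feature_kinds == ("numeric", "nominal")
        assert ds.missing_mask.sum() == 1

    def test_arff_matches_csv(self, csv_file, arff_file):
        a = load_dataset(csv_file, "csv", label_column="cls", positive_label="yes")
        b = load_dataset(arff_file, "arff", label_column="cls", positive_label="yes")
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)


class TestImpute:
    def test_nominal_mode(self):
        ds = Dataset(
            np.array([[0.0], [0.0], [1.0], [np.nan]]),
            np.array([1, 1, 0, 0]),
            ("nom",),
            ("nominal",),
        )
        out = impute_missing(ds)
        assert out.features[3, 0] == 0.0  # mode is code 0 ("A")
        assert not out.has_missing()

    def test_numeric_mean(self):
        ds = Dataset(
            np.array([[0.0, 0], [2.0, 0], [np.nan, 1]]),
            np.array([1, 0, 1]),
            ("x", "y"),
            ("numeric", "numeric"),
        )
        out = impute_missing(ds)
        assert out.features[2, 0] == pytest.approx(1.0)

    def test_no_missing_identity(self, separable_dataset):
        assert impute_missing(separable_dataset) is separable_dataset

    def test_observed_cells_unchanged(self, tiny_dataset):
        out = impute_missing(tiny_dataset)
        keep = ~tiny_dataset.missing_mask
        np.testing.assert_array_equal(out.features[keep], tiny_dataset.features[keep])

    def test_fully_missing_feature(self):
        ds = Dataset(
            np.array([[np.nan, 1.0], [np.nan, 2.0]]),
            np.array([1, 0]),
            ("x", "y"),
            ("numeric", "numeric"),
        )
        with pytest.raises(UnimputableFeatureError):
            impute_missing(ds)


class TestNormalize:
    def test_direct_formula(self):
        ds = Dataset(
            np.array([[2.0], [4.0], [6.0]]),
            np.array([1, 0, 1]),
            ("x",),
            ("numeric",),
        )
        np.testing.assert_allclose(
            minmax_normalize(ds).features[:, 0], [0.0, 0.5, 1.0]
        )

    def test_binary_column_fixed_point(self):
        ds = Dataset(
            np.array([[0.0], [1.0], [0.0]]),
            np.array([1, 0, 1]),
            ("x",),
            ("numeric",),
        )
        np.testing.assert_array_equal(minmax_normalize(ds).features, ds.features)

    def test_constant_column_to_zero(self):
        ds = Dataset(
            np.array([[5.0], [5.0], [5.0]]),
            np.array([1, 0, 1]),
            ("x",),
            ("numeric",),
        )
        np.testing.assert_array_equal(minmax_normalize(ds).features[:, 0], [0, 0, 0])

    def test_idempotent(self, separable_dataset):
        once = minmax_normalize(separable_dataset)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(once.features, twice.features, atol=1e-12)

    def test_preserves_metadata(self, tiny_dataset):
        out = minmax_normalize(impute_missing(tiny_dataset))
        assert out.feature_names == tiny_dataset.feature_names
        np.testing.assert_array_equal(out.labels, tiny_dataset.labels)
        assert out.features.shape == tiny_dataset.features.shape
        assert out.features.min() >= 0 and out.features.max() <= 1

    def test_requires_imputed(self, tiny_dataset):
        with pytest.raises(ValueError):
            minmax_normalize(tiny_dataset)


class TestResample:
    def test_size_conservation(self, small_balanced_dataset):
        out = supervised_resample(small_balanced_dataset, seed=0, size_percent=100.0)
        assert out.n_instances == small_balanced_dataset.n_instances

    def test_determinism(self, small_balanced_dataset):
        a = supervised_resample(small_balanced_dataset, seed=5, bias_to_uniform=0.7)
        b = supervised_resample(small_balanced_dataset, seed=5, bias_to_uniform=0.7)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_bias_to_uniform_balances(self):
        ds = make_synthetic(
            SyntheticSpec(n_instances=1000, n_features=3, positive_fraction=0.9, seed=3)
        )
        out = supervised_resample(ds, seed=0, bias_to_uniform=1.0)
        assert abs(out.n_positive - 500) < 3 * np.sqrt(1000 * 0.25)

    def test_zero_size_error(self, small_balanced_dataset):
        with pytest.raises(EmptyResampleError):
            supervised_resample(small_balanced_dataset, seed=0, size_percent=0.1)
        with pytest.raises(EmptyResampleError):
            supervised_resample(small_balanced_dataset, seed=0, size_percent=0.0)

    def test_half_size(self, small_balanced_dataset):
        out = supervised_resample(small_balanced_dataset, seed=0, size_percent=50.0)
        assert out.n_instances == round(small_balanced_dataset.n_instances * 0.5)

    def test_bias_zero_preserves_proportions(self):
        # chi-square goodness of fit on pooled class counts over 50 seeds
        ds = make_synthetic(
            SyntheticSpec(n_instances=300, n_features=3, positive_fraction=0.7, seed=9)
        )
        p_emp = ds.n_positive / ds.n_instances
        pos = sum(
            supervised_resample(ds, seed=s, bias_to_uniform=0.0).n_positive
            for s in range(50)
        )
        total = 50 * ds.n_instances
        _, p = sps.chisquare([pos, total - pos], [total * p_emp, total * (1 - p_emp)])
        assert p > 0.001


class TestMakeSynthetic:
    def test_bit_reproducible(self):
        spec = SyntheticSpec(n_instances=50, n_features=3, seed=11, missing_rate=0.05)
        a, b = make_synthetic(spec), make_synthetic(spec)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)
        np.testing.assert_array_equal(
            a.features[~a.missing_mask], b.features[~b.missing_mask]
        )

    def test_seeds_differ(self):
        a = make_synthetic(SyntheticSpec(n_instances=50, n_features=3, seed=1))
        b = make_synthetic(SyntheticSpec(n_instances=50, n_features=3, seed=2))
        assert not np.array_equal(a.features, b.features)

    def test_positive_count_sane(self):
        ds = make_synthetic(
            SyntheticSpec(n_instances=100, n_features=2, positive_fraction=0.5, seed=4)
        )
        assert 30 <= ds.n_positive <= 70

    def test_separable_is_linearly_classifiable(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        ds = make_synthetic(
            SyntheticSpec(n_instances=200, n_features=5, class_separation=6.0, seed=2)
        )
        acc = cross_val_score(
            LogisticRegression(), ds.features, ds.labels, cv=10
        ).mean()
        assert acc >= 0.95

    def test_no_signal_near_chance(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        ds = make_synthetic(
            SyntheticSpec(n_instances=200, n_features=5, class_separation=0.0, seed=2)
        )
        acc = cross_val_score(LogisticRegression(), ds.features, ds.labels, cv=10).mean()
        assert 0.35 <= acc <= 0.65

    def test_missing_rate(self):
        ds = make_synthetic(
            SyntheticSpec(n_instances=100, n_features=4, missing_rate=0.1, seed=5)
        )
        assert ds.missing_mask.sum() == round(0.1 * 100 * 4)

    def test_label_noise_flips(self):
        clean = make_synthetic(SyntheticSpec(n_instances=100, n_features=2, seed=6))
        noisy = make_synthetic(
            SyntheticSpec(n_instances=100, n_features=2, seed=6, label_noise=0.2)
        )
        assert (clean.labels != noisy.labels).sum() == 20


class TestOneHot:
    def test_nominal_expanded(self):
        ds = Dataset(
            np.array([[0.5, 0.0], [0.2, 1.0], [0.9, 2.0]]),
            np.array([1, 0, 1]),
            ("num", "nom"),
            ("numeric", "nominal"),
        )
        X = one_hot_encode(ds)
        assert X.shape == (3, 4)  # numeric + 3 one-hot columns

    def test_binary_nominal_stays_single_column(self, tiny_dataset):
        X = one_hot_encode(impute_missing(tiny_dataset))
        assert X.shape == (4, 2)


@settings(max_examples=25, deadline=None)
@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.integers(min_value=10, max_value=60),
    st.integers(min_value=1, max_value=6),
)
def test_preprocess_roundtrip_properties(seed, n, d):
    ds = make_synthetic(
        SyntheticSpec(n_instances=n, n_features=d, seed=seed, missing_rate=0.1)
    )
    out = minmax_normalize(impute_missing(ds))
    assert not out.has_missing()
    assert out.features.min() >= 0.0 and out.features.max() <= 1.0
    np.testing.assert_array_equal(out.labels, ds.labels)
    assert out.feature_names == ds.feature_names
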