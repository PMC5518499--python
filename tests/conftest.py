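import numpy as np
import pytest

from evohis import Dataset, SyntheticSpec, make_synthetic


@pytest.fixture
def tiny_dataset():
    """4 instances, one numeric and one nominal feature, one missing cell."""
    feats = np.array([[0.0, 0.0], [2.0, 0.0], [np.nan, 1.0], [4.0, 1.0]])
    return Dataset(
        feats,
        labels=np.array([1, 1, 0, 0]),
        feature_names=("num", "nom"),
        feature_kinds=("numeric", "nominal"),
    )


@pytest.fixture
def separable_dataset():
    """Well-separated two-cloud dataset; any sensible classifier aces it."""
    return make_synthetic(
        SyntheticSpec(n_instances=200, n_features=5, class_separation=6.0, seed=42)
    )


@pytest.fixture
def small_balanced_dataset():
    return make_synthetic(
        SyntheticSpec(n_instances=80, n_features=4, class_separation=4.0, seed=7)
    )


@pytest.fixture
def csv_file(tmp_path):
    path = tmp_path / "data.csv"
    path.write_text(
        "a,b,cls\n"
        "1.0,x,yes\n"
        "2.0,y,no\n"
        ",x,yes\n"
        "4.0,y,no\n"
    )
    return path


@pytest.fixture
def arff_file(tmp_path):
    path = tmp_path / "data.arff"
    path.write_text(
        "@relation toy\n"
        "@attribute a numeric\n"
        "@attribute b {x, y}\n"
        "@attribute cls {yes, no}\n"
        "@data\n"
        "1.0,x,yes\n"
        "2.0,y,no\n"
        "?,x,yes\n"
        "4.0,y,no\n"
    )
    return path
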