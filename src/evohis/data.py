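"""Dataset representation, loading, preprocessing, resampling and synthesis.

A :class:`Dataset` holds an ``n x d`` numeric feature matrix (nominal
features are integer-coded), a binary label vector (1 = positive class,
0 = negative class) and a boolean missing-value mask.  Preprocessing is
mode/mean imputation followed by per-feature min-max normalization;
resampling follows Weka's supervised ``Resample`` filter semantics
(with replacement, a ``bias_to_uniform`` knob interpolating between the
empirical and the uniform class distribution, and a size percentage).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ClassCountError,
    EmptyResampleError,
    LabelColumnError,
    UnimputableFeatureError,
)

NUMERIC = "numeric"
NOMINAL = "nominal"

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "load_dataset",
    "impute_missing",
    "minmax_normalize",
    "supervised_resample",
    "make_synthetic",
    "one_hot_encode",
]


@dataclass(frozen=True)
class Dataset:
    """An in-memory binary-classification dataset.

    Parameters
    ----------
    features : ndarray of shape (n, d)
        Numeric feature matrix; cells flagged in ``missing_mask`` hold NaN.
    labels : ndarray of shape (n,)
        Integer labels, 1 for the positive class and 0 for the negative.
    feature_names : tuple of str
    feature_kinds : tuple of str
        Per-feature flag, ``"numeric"`` or ``"nominal"``.
    missing_mask : ndarray of shape (n, d), bool
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple
    feature_kinds: tuple
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if feats.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = feats.shape
        if n < 2 or d < 1:
            raise ValueError(f"need n >= 2 and d >= 1, got shape {(n, d)}")
        if labels.shape != (n,):
            raise ValueError("labels length must match number of instances")
        uniq = set(np.unique(labels).tolist())
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise ClassCountError(
                f"labels must contain both classes 0 and 1, got {sorted(uniq)}"
            )
        mask = self.missing_mask
        if mask is None:
            mask = np.isnan(feats)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != feats.shape:
            raise ValueError("missing_mask shape must match features")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "feature_kinds", tuple(self.feature_kinds))
        object.__setattr__(self, "missing_mask", mask)
        if len(self.feature_names) != d or len(self.feature_kinds) != d:
            raise ValueError("feature_names/feature_kinds length must equal d")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n_instances - self.labels.sum())

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic two-class Gaussian dataset.

    ``class_separation`` is the distance between the class mean vectors in
    units of the (unit) within-class standard deviation.
    """

    n_instances: int = 200
    n_features: int = 5
    class_separation: float = 2.0
    positive_fraction: float = 0.5
    label_noise: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_instances < 2 or self.n_features < 1:
            raise ValueError("n_instances >= 2 and n_features >= 1 required")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# loading


def _parse_arff(path):
    """Minimal reader for the standard Weka ARFF dialect ('?' = missing)."""
    names, kinds, nominal_values = [], [], []
    rows = []
    in_data = False
    attr_re = re.compile(r"@attribute\s+('([^']+)'|\S+)\s+(.+)", re.IGNORECASE)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            if in_data:
                rows.append([v.strip().strip("'") for v in line.split(",")])
                continue
            low = line.lower()
            if low.startswith("@data"):
                in_data = True
            elif low.startswith("@attribute"):
                m = attr_re.match(line)
                if m is None:
                    raise ValueError(f"unparseable ARFF attribute line: {line!r}")
                name = m.group(2) or m.group(1)
                decl = m.group(3).strip()
                names.append(name)
                if decl.startswith("{"):
                    kinds.append(NOMINAL)
                    vals = [v.strip().strip("'") for v in decl.strip("{}").split(",")]
                    nominal_values.append(vals)
                else:
                    kinds.append(NUMERIC)
                    nominal_values.append(None)
    df = pd.DataFrame(rows, columns=names).replace("?", np.nan)
    for name, kind in zip(names, kinds):
        if kind == NUMERIC:
            df[name] = pd.to_numeric(df[name])
    return df, dict(zip(names, kinds))


def load_dataset(path, format="csv", *, label_column, positive_label):
    """Load a CSV or ARFF file into a :class:`Dataset`.

    Empty strings and ``"?"`` are treated as missing.  ``positive_label``
    is mapped to class 1; the other label value to class 0.
    """
    if format == "csv":
        df = pd.read_csv(path, na_values=["?", ""], skipinitialspace=True)
        declared_kinds = {}
    elif format == "arff":
        df, declared_kinds = _parse_arff(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if label_column not in df.columns:
        raise LabelColumnError(f"label column {label_column!r} not in {list(df.columns)}")
    raw_labels = df[label_column]
    if raw_labels.isna().any():
        raise ClassCountError("label column contains missing values")
    values = sorted(raw_labels.astype(str).unique())
    if len(values) != 2:
        raise ClassCountError(
            f"label column must have exactly 2 values, found {len(values)}: {values}"
        )
    if str(positive_label) not in values:
        raise ClassCountError(
            f"positive label {positive_label!r} not among label values {values}"
        )
    labels = (raw_labels.astype(str) == str(positive_label)).to_numpy(dtype=int)

    feats = df.drop(columns=[label_column])
    names, kinds, cols = [], [], []
    for name in feats.columns:
        col = feats[name]
        kind = declared_kinds.get(name)
        if kind is None:
            kind = NUMERIC if pd.api.types.is_numeric_dtype(col) else NOMINAL
        if kind == NOMINAL:
            # integer-code nominal values in sorted order; NaN stays NaN
            cats = sorted(col.dropna().astype(str).unique())
            mapping = {c: i for i, c in enumerate(cats)}
            coded = col.map(lambda v: mapping.get(str(v), np.nan) if pd.notna(v) else np.nan)
            cols.append(coded.to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
        names.append(str(name))
        kinds.append(kind)
    matrix = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return Dataset(matrix, labels, tuple(names), tuple(kinds))


# ---------------------------------------------------------------------------
# preprocessing


def impute_missing(ds: Dataset) -> Dataset:
    """Fill missing cells: per-feature mode for nominal, mean for numeric."""
    if not ds.has_missing():
        return ds
    feats = ds.features.copy()
    for j in range(ds.n_features):
        col_mask = ds.missing_mask[:, j]
        if not col_mask.any():
            continue
        observed = feats[~col_mask, j]
        if observed.size == 0:
            raise UnimputableFeatureError(
                f"feature {ds.feature_names[j]!r} has no observed values"
            )
        if ds.feature_kinds[j] == NOMINAL:
            vals, counts = np.unique(observed, return_counts=True)
            fill = vals[np.argmax(counts)]  # ties -> smallest code
        else:
            fill = observed.mean()
        feats[col_mask, j] = fill
    return replace(ds, features=feats, missing_mask=np.zeros_like(ds.missing_mask))


def minmax_normalize(ds: Dataset) -> Dataset:
    """Map every feature to [0, 1] by (x - min) / (max - min).

    Constant features map to 0 (Weka convention; avoids division by zero).
    Requires an imputed dataset.
    """
    if ds.has_missing():
        raise ValueError("normalize requires an imputed dataset (no missing values)")
    feats = ds.features.copy()
    lo = feats.min(axis=0)
    hi = feats.max(axis=0)
    span = hi - lo
    constant = span == 0
    span[constant] = 1.0
    feats = (feats - lo) / span
    feats[:, constant] = 0.0
    return replace(ds, features=feats)


def one_hot_encode(ds: Dataset) -> np.ndarray:
    """Design matrix for classifier training: nominal columns one-hot expanded."""
    if ds.has_missing():
        raise ValueError("encode requires an imputed dataset")
    cols = []
    for j in range(ds.n_features):
        col = ds.features[:, j]
        if ds.feature_kinds[j] == NOMINAL:
            values = np.unique(col)
            if values.size <= 2:
                cols.append((col == values.max()).astype(float))
            else:
                for v in values:
                    cols.append((col == v).astype(float))
        else:
            cols.append(col)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# resampling


def supervised_resample(
    ds: Dataset,
    seed: int,
    bias_to_uniform: float = 0.0,
    size_percent: float = 100.0,
) -> Dataset:
    """Sample with replacement, optionally biasing class frequencies to uniform.

    Per-class sampling probabilities interpolate between the empirical class
    distribution (``bias_to_uniform=0``) and the uniform distribution over the
    two classes (``bias_to_uniform=1``), mirroring Weka's supervised
    ``Resample`` filter.  Output size is ``round(n * size_percent / 100)``.
    """
    if not 0.0 <= bias_to_uniform <= 1.0:
        raise ValueError("bias_to_uniform must lie in [0, 1]")
    if size_percent <= 0:
        raise EmptyResampleError("size_percent must be positive")
    n = ds.n_instances
    size = int(round(n * size_percent / 100.0))
    if size == 0:
        raise EmptyResampleError(f"requested size rounds to zero (n={n}, {size_percent}%)")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(ds.labels == 1)
    neg_idx = np.flatnonzero(ds.labels == 0)
    p_pos = (1.0 - bias_to_uniform) * (len(pos_idx) / n) + bias_to_uniform * 0.5
    draw_pos = rng.random(size) < p_pos
    picks = np.empty(size, dtype=int)
    n_pos_draws = int(draw_pos.sum())
    picks[draw_pos] = rng.choice(pos_idx, size=n_pos_draws, replace=True)
    picks[~draw_pos] = rng.choice(neg_idx, size=size - n_pos_draws, replace=True)
    return Dataset(
        ds.features[picks],
        ds.labels[picks],
        ds.feature_names,
        ds.feature_kinds,
        ds.missing_mask[picks],
    )


# ---------------------------------------------------------------------------
# synthesis


def make_synthetic(spec: SyntheticSpec) -> Dataset:
    """Two Gaussian class-conditional clouds separated along a random direction.

    Positives are drawn at ``+sep/2 * u`` and negatives at ``-sep/2 * u``
    where ``u`` is a random unit vector, both with identity covariance.
    A ``label_noise`` fraction of labels is flipped and a ``missing_rate``
    fraction of cells masked.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_instances, spec.n_features
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    labels = (rng.random(n) < spec.positive_fraction).astype(int)
    # guarantee both classes non-empty (binomial support edge cases)
    if labels.sum() == 0:
        labels[rng.integers(n)] = 1
    elif labels.sum() == n:
        labels[rng.integers(n)] = 0
    offset = spec.class_separation / 2.0
    signs = np.where(labels == 1, offset, -offset)
    features = rng.normal(size=(n, d)) + signs[:, None] * direction[None, :]

    if spec.label_noise > 0:
        n_flip = int(round(spec.label_noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        labels = labels.copy()
        labels[flip] = 1 - labels[flip]
        if labels.sum() == 0 or labels.sum() == n:
            labels[flip[0]] = 1 - labels[flip[0]]

    mask = np.zeros((n, d), dtype=bool)
    if spec.missing_rate > 0:
        n_missing = int(round(spec.missing_rate * n * d))
        cells = rng.choice(n * d, size=n_missing, replace=False)
        mask.flat[cells] = True
        features = features.copy()
        features[mask] = np.nan

    names = tuple(f"f{j}" for j in range(d))
    kinds = tuple(NUMERIC for _ in range(d))
    return Dataset(features, labels, names, kinds, mask)
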