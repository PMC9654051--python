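"""The seven attribute-weighting (feature-selection) models.

Each model scores every feature of the mined table — per-gene FPKM columns
plus the categorical tissue attribute — against the binary diet class, and
each model's raw weights are min-max normalised to [0, 1] (0 = unimportant,
1 = most important). The models are:

* ``info_gain`` — mutual information I(feature bins; class), base 2
* ``info_gain_ratio`` — info gain / H(feature bins)
* ``uncertainty`` — symmetric uncertainty 2 I / (H(class) + H(bins))
* ``gini_index`` — Gini impurity reduction of the class given the bins
* ``chi_squared`` — raw Pearson chi-square statistic of the bins x class table
* ``relief`` — ReliefF (k nearest hits/misses, full deterministic pass)
* ``rule`` — OneR-style: single-feature majority rule accuracy above the
  majority-class baseline, floored at 0

Numeric features are discretised into equal-frequency bins first (default 5);
categorical features use their categories as bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CLASS_COLUMN

#: model columns in report order
MODELS = (
    "info_gain_ratio",
    "rule",
    "chi_squared",
    "gini_index",
    "uncertainty",
    "relief",
    "info_gain",
)

CONTINGENCY_MODELS = ("info_gain", "info_gain_ratio", "chi_squared", "gini_index", "uncertainty")


@dataclass
class WeightingConfig:
    #: "entropy" = supervised Fayyad-Irani MDL partitioning (default);
    #: "equal_frequency" = unsupervised quantile bins with ``n_bins`` levels
    discretization: str = "entropy"
    n_bins: int = 5
    relief_k: int = 5
    relief_iterations: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discretization not in ("entropy", "equal_frequency"):
            raise ValueError(f"unknown discretization {self.discretization!r}")


@dataclass
class ContingencyTable:
    """Feature-bin x class count table."""

    counts: np.ndarray  # (n_bins, n_classes) non-negative ints
    bin_labels: Sequence = field(default_factory=list)
    class_labels: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty contingency table")


def discretize_equal_frequency(values, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile-edge) discretisation to integer bin labels.

    Edges are the interior quantiles; intervals are right-closed, so tied
    values always land in the same bin. Duplicate edges are collapsed, and
    labels are re-coded to consecutive integers, so the effective bin count
    may be below ``n_bins`` (a constant vector yields one bin) and no bin is
    empty.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    v = np.asarray(values, dtype=float)
    edges = np.unique(np.quantile(v, np.arange(1, n_bins) / n_bins))
    labels = np.searchsorted(edges, v, side="left")
    _, labels = np.unique(labels, return_inverse=True)  # drop empty codes
    return labels


def _class_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def discretize_entropy(values, class_labels, min_leaf: int = 2) -> np.ndarray:
    """Supervised discretisation by recursive minimal-entropy partitioning.

    Candidate cuts are boundary midpoints between sorted distinct values; the
    cut maximising class information gain is accepted only if it passes the
    Fayyad-Irani MDL criterion, then each side is partitioned recursively.
    A feature carrying no class information ends up in a single bin, which
    every contingency-based weight maps to exactly 0 — so null features are
    silenced rather than scored on binning noise.
    """
    v = np.asarray(values, dtype=float)
    cls, cats = _codes(class_labels)
    n_classes = len(cats)
    order = np.argsort(v, kind="stable")
    v_s, c_s = v[order], cls[order]
    cuts: list[float] = []

    def class_counts(seg: np.ndarray) -> np.ndarray:
        return np.bincount(seg, minlength=n_classes)

    def partition(lo: int, hi: int) -> None:  # [lo, hi) on the sorted arrays
        n = hi - lo
        if n < 2 * min_leaf:
            return
        seg_counts = class_counts(c_s[lo:hi])
        h_s = _class_entropy(seg_counts)
        if h_s == 0.0:
            return
        best_gain, best_i = 0.0, -1
        left = np.zeros(n_classes, dtype=np.int64)
        for i in range(lo + 1, hi):
            left[c_s[i - 1]] += 1
            if v_s[i] == v_s[i - 1]:
                continue
            nl, nr = i - lo, hi - i
            if nl < min_leaf or nr < min_leaf:
                continue
            gain = h_s - (nl * _class_entropy(left) + nr * _class_entropy(seg_counts - left)) / n
            if gain > best_gain:
                best_gain, best_i = gain, i
        if best_i < 0:
            return
        left = class_counts(c_s[lo:best_i])
        right = seg_counts - left
        k = int((seg_counts > 0).sum())
        k1, k2 = int((left > 0).sum()), int((right > 0).sum())
        h1, h2 = _class_entropy(left), _class_entropy(right)
        delta = np.log2(3.0**k - 2.0) - (k * h_s - k1 * h1 - k2 * h2)
        if best_gain <= (np.log2(n - 1) + delta) / n:
            return
        cuts.append((v_s[best_i - 1] + v_s[best_i]) / 2.0)
        partition(lo, best_i)
        partition(best_i, hi)

    partition(0, len(v))
    labels = np.searchsorted(np.sort(np.asarray(cuts)), v, side="left")
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _codes(x) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(x)
    return cat.codes.astype(np.int64), list(cat.categories)


def contingency(
    feature, class_labels, n_bins: int = 5, method: str = "equal_frequency"
) -> ContingencyTable:
    """Bin a feature and cross-tabulate it against the class.

    Numeric features are discretised with the chosen ``method``
    (``equal_frequency`` quantile bins or supervised ``entropy``
    partitioning); categorical features use their categories as bins.
    """
    feature = np.asarray(feature) if not isinstance(feature, pd.Series) else feature
    if len(feature) != len(class_labels):
        raise ValueError("feature and class labels have different lengths")
    arr = feature.to_numpy() if isinstance(feature, pd.Series) else feature
    if np.issubdtype(np.asarray(arr).dtype, np.number):
        if method == "entropy":
            bins = discretize_entropy(arr, class_labels)
        elif method == "equal_frequency":
            bins = discretize_equal_frequency(arr, n_bins)
        else:
            raise ValueError(f"unknown discretization method {method!r}")
        bin_labels = list(range(int(bins.max()) + 1))
    else:
        bins, bin_labels = _codes(arr)
    cls, cls_labels = _codes(class_labels)
    n_b, n_c = len(bin_labels), len(cls_labels)
    table = np.bincount(bins * n_c + cls, minlength=n_b * n_c).reshape(n_b, n_c)
    return ContingencyTable(table, bin_labels, cls_labels)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _gini(p: np.ndarray) -> float:
    return float(1.0 - (p**2).sum())


def weight_from_contingency(ct: ContingencyTable, model: str) -> float:
    """One of the five contingency-based weights (see module docstring)."""
    counts = ct.counts
    n = counts.sum()
    p_bin = counts.sum(axis=1) / n
    p_cls = counts.sum(axis=0) / n
    h_cls = _entropy(p_cls)
    h_bin = _entropy(p_bin)

    if model in ("info_gain", "info_gain_ratio", "uncertainty"):
        cond = 0.0
        for b in range(counts.shape[0]):
            row = counts[b]
            if row.sum() > 0:
                cond += p_bin[b] * _entropy(row / row.sum())
        ig = h_cls - cond
        if model == "info_gain":
            return max(0.0, ig)
        if model == "info_gain_ratio":
            return max(0.0, ig / h_bin) if h_bin > 0 else 0.0
        denom = h_cls + h_bin
        return max(0.0, 2.0 * ig / denom) if denom > 0 else 0.0
    if model == "gini_index":
        cond = 0.0
        for b in range(counts.shape[0]):
            row = counts[b]
            if row.sum() > 0:
                cond += p_bin[b] * _gini(row / row.sum())
        return max(0.0, _gini(p_cls) - cond)
    if model == "chi_squared":
        expected = np.outer(p_bin, p_cls) * n
        mask = expected > 0
        return float((((counts - expected) ** 2)[mask] / expected[mask]).sum())
    raise ValueError(f"unknown contingency model {model!r}")


def _split_features(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    if CLASS_COLUMN not in table.columns:
        raise ValueError(f"mined table lacks the {CLASS_COLUMN!r} class column")
    X = table.drop(columns=[CLASS_COLUMN])
    return X, table[CLASS_COLUMN]


def _feature_diff_matrix(X: pd.DataFrame) -> np.ndarray:
    """Samples x features matrix scaled for Relief: numeric features min-max
    scaled to [0, 1] (constant -> 0), categorical features coded so that
    |difference| clipped to {0, 1} is the 0/1 mismatch indicator."""
    out = np.empty(X.shape, dtype=float)
    for j, col in enumerate(X.columns):
        s = X[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            rng = v.max() - v.min()
            out[:, j] = 0.0 if rng == 0 else (v - v.min()) / rng
        else:
            codes, _ = _codes(s)
            out[:, j] = codes
    return out


def relief_weights(
    table: pd.DataFrame,
    k_neighbors: int = 5,
    n_iterations: int | str = "all",
    seed: int | None = None,
) -> pd.Series:
    """ReliefF weights for every feature of the mined table.

    For each reference sample the k nearest same-class (hits) and k nearest
    other-class (misses) neighbours are found under Manhattan distance on the
    scaled features; each feature is credited with the mean miss diff minus
    the mean hit diff, averaged over reference samples:

        W(f) = sum_i [ sum_miss diff(f,i,m)/(k n) - sum_hit diff(f,i,h)/(k n) ]

    ``n_iterations="all"`` visits every sample (deterministic); an integer
    draws a seeded sample of reference instances.
    """
    X, y = _split_features(table)
    n = len(X)
    numeric = np.array([pd.api.types.is_numeric_dtype(X[c]) for c in X.columns])
    scaled = _feature_diff_matrix(X)
    cls, _ = _codes(y)
    for c in np.unique(cls):
        if (cls == c).sum() <= k_neighbors:
            raise ValueError(
                f"class {c} has {(cls == c).sum()} samples; needs > k_neighbors={k_neighbors} "
                "(reduce relief_k)"
            )

    # pairwise diffs: numeric -> |scaled difference|, categorical -> 0/1 mismatch
    if n_iterations == "all":
        refs = np.arange(n)
    else:
        if not isinstance(n_iterations, (int, np.integer)) or n_iterations < 1:
            raise ValueError("n_iterations must be 'all' or a positive integer")
        refs = np.random.default_rng(seed).choice(n, size=min(int(n_iterations), n), replace=False)

    dist = np.zeros((n, n))
    # chunk over features to bound memory at large feature counts
    for j0 in range(0, scaled.shape[1], 512):
        block = scaled[:, j0 : j0 + 512]
        d = np.abs(block[:, None, :] - block[None, :, :])
        d[:, :, ~numeric[j0 : j0 + 512]] = (d[:, :, ~numeric[j0 : j0 + 512]] > 0).astype(float)
        dist += d.sum(axis=2)

    w = np.zeros(scaled.shape[1])
    for i in refs:
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i]
        same = cls[order] == cls[i]
        hits = order[same][:k_neighbors]
        misses = order[~same][:k_neighbors]
        dh = np.abs(scaled[hits] - scaled[i])
        dm = np.abs(scaled[misses] - scaled[i])
        dh[:, ~numeric] = (dh[:, ~numeric] > 0).astype(float)
        dm[:, ~numeric] = (dm[:, ~numeric] > 0).astype(float)
        w += dm.sum(axis=0) / k_neighbors - dh.sum(axis=0) / k_neighbors
    w /= len(refs)
    return pd.Series(w, index=X.columns, name="relief")


def weight_relief(
    table: pd.DataFrame,
    feature: str,
    k_neighbors: int = 5,
    n_iterations: int | str = "all",
    seed: int | None = None,
) -> float:
    """ReliefF weight of one feature (distances still use all features)."""
    return float(relief_weights(table, k_neighbors, n_iterations, seed)[feature])


def weight_rule(feature, class_labels, n_bins: int = 5, method: str = "equal_frequency") -> float:
    """OneR-style rule weight: majority-class-per-bin training accuracy minus
    the majority-class baseline, floored at 0."""
    ct = contingency(feature, class_labels, n_bins, method)
    n = ct.counts.sum()
    accuracy = ct.counts.max(axis=1).sum() / n
    baseline = ct.counts.sum(axis=0).max() / n
    return max(0.0, accuracy - baseline)


def normalize_weights(raw: pd.Series) -> pd.Series:
    """Min-max map to [0, 1]; a constant raw vector maps to all zeros."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn(f"constant raw weights for model {raw.name!r}; normalised to 0", stacklevel=2)
        return pd.Series(0.0, index=raw.index, name=raw.name)
    return (raw - lo) / (hi - lo)


@dataclass
class WeightMatrix:
    """Raw and min-max-normalised weights, features x 7 models."""

    raw: pd.DataFrame
    norm: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MODELS) - set(self.raw.columns)
        if missing:
            raise ValueError(f"missing model column(s): {sorted(missing)}")

    @property
    def features(self) -> list[str]:
        return list(self.raw.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.norm[list(MODELS)].copy()
        out.columns = [f"norm_{m}" for m in MODELS]
        for m in MODELS:
            out[f"raw_{m}"] = self.raw[m]
        return out


def run_all_models(table: pd.DataFrame, config: WeightingConfig | None = None) -> WeightMatrix:
    """Apply all seven models to every feature of the mined table."""
    config = config or WeightingConfig()
    X, y = _split_features(table)
    if X.shape[1] < 2:
        raise ValueError("mined table needs at least two features")
    if pd.Categorical(y).codes.max() < 1:
        raise ValueError("both diet classes must be present")
    raw = pd.DataFrame(index=X.columns, columns=list(MODELS), dtype=float)
    rows = {}
    for col in X.columns:
        ct = contingency(X[col], y, config.n_bins, config.discretization)
        n = ct.counts.sum()
        acc = ct.counts.max(axis=1).sum() / n
        base = ct.counts.sum(axis=0).max() / n
        rows[col] = [weight_from_contingency(ct, m) for m in CONTINGENCY_MODELS] + [max(0.0, acc - base)]
    block = pd.DataFrame.from_dict(rows, orient="index", columns=[*CONTINGENCY_MODELS, "rule"])
    raw[list(CONTINGENCY_MODELS)] = block[list(CONTINGENCY_MODELS)]
    raw["rule"] = block["rule"]
    raw["relief"] = relief_weights(
        table, config.relief_k, config.relief_iterations, config.seed
    )
    norm = raw.apply(normalize_weights, axis=0)
    return WeightMatrix(raw=raw, norm=norm)
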