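"""Collaborative feature weighting: entropy x dependency.

Three steps produce the cell-line x feature weight matrix Z:

1. inter-cell-line weight: Shannon entropy H_j (bits) of each feature's
   empirical value distribution over compounds — how much information the
   feature carries regardless of cell line;
2. intra-cell-line weight: the dependency between the feature and each
   cell line's observed activities — |Pearson r| for quantitative
   features, the Pearson contingency coefficient (against activity
   quartile bins) for qualitative ones;
3. final weight z_ij = H_j * dep_ij.

A feature constant across all compounds (e.g. a structural count absent
from the whole series) has zero entropy and hence zero final weight in
every cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ActivityTable, DescriptorTable, QUALITATIVE, align

__all__ = [
    "FeatureWeightReport",
    "feature_entropy",
    "dependency_quantitative",
    "dependency_qualitative",
    "weight_matrix",
]


@dataclass
class FeatureWeightReport:
    """Per-feature entropy (r,), per-(cell line, feature) dependency (n, r)
    and their product (n, r)."""

    feature_names: list
    cellline_ids: list
    entropy: np.ndarray
    dependency: np.ndarray
    final: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {"feature": self.feature_names, "entropy": self.entropy}
        for i, cl in enumerate(self.cellline_ids):
            cols[f"dependency_{cl}"] = self.dependency[i]
        for i, cl in enumerate(self.cellline_ids):
            cols[f"final_{cl}"] = self.final[i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _discretize(column: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Bin a feature column: distinct values for integer-valued features
    (descriptor counts), equal-width bins otherwise."""
    column = np.asarray(column, dtype=float)
    if np.all(column == np.round(column)):
        return column.astype(int)
    lo, hi = column.min(), column.max()
    if hi == lo:
        return np.zeros(len(column), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(column, edges[1:-1]), 0, n_bins - 1)


def feature_entropy(column, n_bins: int = 10, normalize: bool = False) -> float:
    """Shannon entropy (bits) of a feature's discretized value distribution.

    Constant columns score 0.  With ``normalize=True`` the entropy is
    divided by log2 of the number of occupied bins (0 if only one bin).
    """
    codes = _discretize(np.asarray(column, dtype=float), n_bins)
    _, counts = np.unique(codes, return_counts=True)
    h = float(stats.entropy(counts, base=2))
    if normalize:
        k = len(counts)
        h = h / np.log2(k) if k > 1 else 0.0
    return h


def dependency_quantitative(feature, activity) -> float:
    """|Pearson r| between a quantitative feature and observed activities;
    0 when either side has zero variance."""
    f = np.asarray(feature, dtype=float)
    a = np.asarray(activity, dtype=float)
    if f.shape != a.shape:
        raise ValueError("feature and activity lengths differ")
    if len(f) < 2:
        raise ValueError("need at least 2 paired observations")
    if np.std(f) == 0 or np.std(a) == 0:
        return 0.0
    return float(abs(np.corrcoef(f, a)[0, 1]))


def dependency_qualitative(feature, activity, n_bins: int = 4) -> float:
    """Pearson contingency coefficient C = sqrt(chi2 / (chi2 + N)) on the
    (feature category) x (activity quantile bin) table; 0 for degenerate
    single-row or single-column tables."""
    f = np.asarray(feature)
    a = np.asarray(activity, dtype=float)
    if f.shape != a.shape:
        raise ValueError("feature and activity lengths differ")
    if len(f) < 2:
        raise ValueError("need at least 2 paired observations")
    qs = np.quantile(a, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(qs, a, side="left")
    table = pd.crosstab(pd.Series(f), pd.Series(bins)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    return float(np.sqrt(chi2 / (chi2 + n)))


def weight_matrix(x: ActivityTable, y: DescriptorTable,
                  normalize_entropy: bool = False) -> FeatureWeightReport:
    """Run the three weighting steps on aligned activity/descriptor tables.

    Dependencies are computed per cell line on the compounds observed in
    that cell line, dispatching on the feature's quantitative/qualitative
    kind.
    """
    x, y = align(x, y)
    m, n = x.shape
    r = y.shape[1]
    entropy = np.array([
        feature_entropy(y.values[:, j], normalize=normalize_entropy)
        for j in range(r)
    ])
    dependency = np.zeros((n, r))
    for i in range(n):
        obs = x.mask[:, i].astype(bool)
        act = x.values[obs, i]
        for j in range(r):
            feat = y.values[obs, j]
            if y.kinds[j] == QUALITATIVE:
                dependency[i, j] = dependency_qualitative(feat, act)
            else:
                dependency[i, j] = dependency_quantitative(feat, act)
    final = entropy[np.newaxis, :] * dependency
    return FeatureWeightReport(
        list(y.feature_names), list(x.cellline_ids), entropy, dependency, final
    )
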