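"""Train/test partitioning: repeated random splits and the greedy
maximin "diverse subset" ranking used in chemoinformatics.

The diversity ranking starts from the first compound of the table,
then repeatedly appends the compound whose minimum Euclidean distance
(on per-feature z-scored descriptors) to all already-ranked compounds
is largest, breaking ties by lowest row index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DescriptorTable

__all__ = ["SplitPlan", "random_split", "diversity_ranking", "diverse_split"]

RANDOM = "random"
DIVERSE = "diverse_subset"


@dataclass
class SplitPlan:
    """Disjoint train/test compound positions covering 0..m-1."""

    train_indices: list
    test_indices: list
    method: str
    seed: int = None

    def __post_init__(self):
        self.train_indices = [int(i) for i in self.train_indices]
        self.test_indices = [int(i) for i in self.test_indices]
        tr, te = set(self.train_indices), set(self.test_indices)
        m = len(self.train_indices) + len(self.test_indices)
        if tr & te or tr | te != set(range(m)):
            raise ValueError("train/test must partition 0..m-1")

    @property
    def m(self) -> int:
        return len(self.train_indices) + len(self.test_indices)

    def to_csv(self, path, compound_ids=None) -> None:
        ids = compound_ids or list(range(self.m))
        rows = [(ids[i], "train") for i in self.train_indices]
        rows += [(ids[i], "test") for i in self.test_indices]
        pd.DataFrame(rows, columns=["compound_id", "role"]).to_csv(
            path, index=False
        )


def random_split(m: int, test_fraction: float = 1 / 3,
                 seed: int = 0) -> SplitPlan:
    """Seeded uniform split; |test| = round(m * test_fraction)."""
    if m < 3:
        raise ValueError("need at least 3 compounds to split")
    n_test = int(round(m * test_fraction))
    if n_test < 1 or n_test >= m:
        raise ValueError(
            f"test_fraction={test_fraction} leaves an empty train or test set"
        )
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(m, size=n_test, replace=False))
    train = np.setdiff1d(np.arange(m), test)
    return SplitPlan(train.tolist(), test.tolist(), RANDOM, seed)


def _zscore(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    out = np.zeros_like(values, dtype=float)
    nz = sd > 0
    out[:, nz] = (values[:, nz] - mu[nz]) / sd[nz]
    return out  # zero-variance features contribute nothing to distances


def diversity_ranking(y) -> np.ndarray:
    """Greedy maximin ordering of compounds by descriptor diversity.

    Position 0 is the table's first row (the reference); each subsequent
    position is the unranked compound maximizing its minimum distance to
    everything already ranked, ties broken by lowest row index.
    """
    values = y.values if isinstance(y, DescriptorTable) else np.asarray(y, float)
    m = values.shape[0]
    if m == 0:
        return np.array([], dtype=int)
    Z = _zscore(values)
    ranked = [0]
    # min distance from each row to the ranked set, updated incrementally
    mindist = np.linalg.norm(Z - Z[0], axis=1)
    mindist[0] = -np.inf
    for _ in range(m - 1):
        nxt = int(np.argmax(mindist))  # argmax takes the lowest index on ties
        ranked.append(nxt)
        d = np.linalg.norm(Z - Z[nxt], axis=1)
        mindist = np.minimum(mindist, d)
        mindist[nxt] = -np.inf
    return np.array(ranked, dtype=int)


def diverse_split(y, test_fraction: float = 1 / 3,
                  test_from: str = "tail") -> SplitPlan:
    """Deterministic split along the diversity ranking.

    ``test_from='tail'`` (default) keeps the most diverse head of the
    ranking for training; 'head' inverts the assignment.
    """
    values = y.values if isinstance(y, DescriptorTable) else np.asarray(y, float)
    m = values.shape[0]
    if m < 3:
        raise ValueError("need at least 3 compounds to split")
    # = ceil((1 - test_fraction) * m), robust to float representation of 1/3
    n_train = m - int(math.floor(test_fraction * m + 1e-9))
    if n_train < 1 or n_train >= m:
        raise ValueError("degenerate split sizes")
    order = diversity_ranking(values)
    head, tail = order[:n_train].tolist(), order[n_train:].tolist()
    if test_from == "tail":
        train, test = head, tail
    elif test_from == "head":
        n_test = m - n_train
        train, test = order[n_test:].tolist(), order[:n_test].tolist()
    else:
        raise ValueError("test_from must be 'head' or 'tail'")
    return SplitPlan(sorted(train), sorted(test), DIVERSE, None)
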