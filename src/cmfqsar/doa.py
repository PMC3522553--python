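"""Domain-of-applicability analysis via leverage and the Williams plot.

The leverage of a query compound with descriptor row x_i against a
training design matrix X is h_i = x_i^T (X^T X)^{-1} x_i — its Mahalanobis-
like distance from the training descriptor space.  Predictions for
compounds with h_i above the warning leverage h* = 3k/n (k descriptors,
n training compounds) are extrapolations and flagged as structural (X)
outliers.  Response (Y) outliers are compounds whose standardized
prediction residual exceeds 3 sigma, where sigma is the root-mean-square
of the residuals.  Plotting standardized residuals against leverage is
the Williams plot; this module produces its table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DOAReport", "leverages", "warning_leverage", "williams_table"]


@dataclass
class DOAReport:
    compound_ids: list
    leverage: np.ndarray
    std_residual: np.ndarray
    x_outlier: np.ndarray
    y_outlier: np.ndarray
    warning_leverage: float
    k: int
    n_train: int
    singular: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound_id": self.compound_ids,
            "leverage": self.leverage,
            "std_residual": self.std_residual,
            "x_outlier": self.x_outlier,
            "y_outlier": self.y_outlier,
        })

    def to_csv(self, path, scalars_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if scalars_path is not None:
            with open(scalars_path, "w") as fh:
                json.dump({"k": self.k, "n_train": self.n_train,
                           "warning_leverage": self.warning_leverage,
                           "singular": self.singular}, fh)


def leverages(train_descriptors, query_descriptors,
              rcond: float = 1e-10):
    """h_i = x_i^T (X^T X)^{-1} x_i for each query row.

    Uses the Moore–Penrose pseudoinverse (cutoff ``rcond``) when X^T X is
    singular, e.g. with collinear descriptor columns.
    """
    X = np.atleast_2d(np.asarray(train_descriptors, dtype=float))
    Q = np.atleast_2d(np.asarray(query_descriptors, dtype=float))
    if X.shape[1] != Q.shape[1]:
        raise ValueError(
            f"descriptor count mismatch: train has {X.shape[1]}, "
            f"query has {Q.shape[1]}"
        )
    G = np.linalg.pinv(X.T @ X, rcond=rcond)
    return np.einsum("ij,jk,ik->i", Q, G, Q)


def warning_leverage(k: int, n_train: int) -> float:
    """The fixed warning threshold h* = 3k/n."""
    if k <= 0 or n_train <= 0:
        raise ValueError("k and n_train must be positive")
    return 3.0 * k / n_train


def williams_table(train_descriptors, query_descriptors, residuals,
                   compound_ids=None, center: bool = False) -> DOAReport:
    """Build the Williams-plot table for a set of query compounds.

    ``residuals`` are the held-out prediction residuals aligned with the
    query rows; they are standardized by their root-mean-square (all-zero
    residuals standardize to 0).  ``center=True`` subtracts the training
    column means from both designs before computing leverages.
    """
    X = np.atleast_2d(np.asarray(train_descriptors, dtype=float))
    Q = np.atleast_2d(np.asarray(query_descriptors, dtype=float))
    res = np.asarray(residuals, dtype=float)
    if len(res) != Q.shape[0]:
        raise ValueError("residuals not aligned with query rows")
    if center:
        mu = X.mean(axis=0)
        X = X - mu
        Q = Q - mu
    n_train, k = X.shape
    h = leverages(X, Q)
    hstar = warning_leverage(k, n_train)
    sigma = float(np.sqrt(np.mean(res ** 2)))
    std_res = res / sigma if sigma > 0 else np.zeros_like(res)
    singular = np.linalg.matrix_rank(X) < k
    if compound_ids is None:
        compound_ids = list(range(Q.shape[0]))
    return DOAReport(
        list(compound_ids), h, std_res,
        h > hstar, np.abs(std_res) > 3.0,
        hstar, k, n_train, bool(singular),
    )
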