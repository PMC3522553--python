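"""Metrics, single-cell-line baselines, and the comparison harness.

The harness mirrors the evaluation protocol for collaborative QSAR:
for each cell line, part of the compounds are held out; ridge regression
and (optionally) support-vector regression are trained per cell line on
training-compound descriptors, while the factorization model sees the
full table with the held-out cells of that one column masked as missing
and predicts them from the remaining entries of all columns plus the
descriptors.  All methods are scored on identical held-out cells by RMSE
and R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

from .data import ActivityTable, DescriptorTable, align
from .factorization import CMFImputer
from .splits import diverse_split, random_split

__all__ = [
    "MetricPair",
    "ComparisonReport",
    "rmse",
    "r_squared",
    "fit_ridge",
    "run_comparison",
    "sweep_regularization",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_TRAIN_RATIOS",
]

DEFAULT_LAMBDA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_TRAIN_RATIOS = (0.15, 0.35, 0.55, 0.75)


@dataclass
class MetricPair:
    rmse: float
    r_squared: float


def rmse(observed, predicted) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted lengths differ")
    if y.size == 0:
        raise ValueError("empty vectors")
    e = y - yhat
    return float(np.sqrt(np.mean(e * e)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_err/SS_tot (may be negative).

    SS_tot is taken about the mean of the observed values; a constant
    observed vector makes the metric undefined and raises.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted lengths differ")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant observed vector")
    ss_err = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_err / ss_tot


def fit_ridge(descriptors, activities, alpha: float = 1.0):
    """Penalized least squares with an unpenalized intercept.

    Returns (weights, intercept).  With alpha=0 a rank-deficient design
    raises, advising a positive alpha.
    """
    Z = np.atleast_2d(np.asarray(descriptors, dtype=float))
    a = np.asarray(activities, dtype=float)
    if Z.shape[0] != len(a):
        raise ValueError("row counts differ")
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if alpha == 0:
        Zc = Z - Z.mean(axis=0)
        if np.linalg.matrix_rank(Zc) < Z.shape[1]:
            raise np.linalg.LinAlgError(
                "singular normal equations with alpha=0; use alpha > 0"
            )
    model = Ridge(alpha=alpha, solver="cholesky" if alpha > 0 else "auto")
    model.fit(Z, a)
    return model.coef_.copy(), float(model.intercept_)


@dataclass
class ComparisonReport:
    """Tidy per-(cell line, method, repeat) metrics plus the per-compound
    squared errors behind error-distribution boxplots."""

    metrics: pd.DataFrame        # cell_line, method, repeat, rmse, r_squared
    squared_errors: pd.DataFrame  # cell_line, method, repeat, compound_id, sq_error
    protocol: str

    def to_csv(self, path) -> None:
        self.metrics.to_csv(path, index=False)

    def median_rmse(self) -> pd.DataFrame:
        return (self.metrics.groupby(["cell_line", "method"])["rmse"]
                .median().unstack())

    def wilcoxon(self, method_a="cmf", method_b="ridge",
                 metric="rmse") -> float:
        """Paired two-sided Wilcoxon signed-rank p-value over the
        per-(cell line, repeat) metric pairs of two methods."""
        piv = self.metrics.pivot_table(
            index=["cell_line", "repeat"], columns="method", values=metric
        )
        a, b = piv[method_a].to_numpy(), piv[method_b].to_numpy()
        if np.allclose(a, b):
            return 1.0
        return float(_sps.wilcoxon(a, b).pvalue)


def _zscore_train(train, test):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def run_comparison(x: ActivityTable, y: DescriptorTable,
                   protocol: str = "random", n_repeats: int = 10,
                   seed: int = 0, test_fraction: float = 1 / 3,
                   ridge_alpha: float = 1.0, include_svr: bool = True,
                   cmf_params: dict = None) -> ComparisonReport:
    """Compare the factorization against per-cell-line baselines.

    ``protocol='random'`` draws ``n_repeats`` seeded 2/3–1/3 compound
    splits (seeds seed..seed+n_repeats-1); ``protocol='diverse'`` uses
    the single deterministic diverse-subset split.  Cell lines with
    fewer than 2 observed training values are skipped with a warning.
    """
    x, y = align(x, y)
    m, n = x.shape
    cmf_params = dict(cmf_params or {})
    cmf_params.setdefault("random_state", seed)
    if protocol == "random":
        plans = [random_split(m, test_fraction, seed + rep)
                 for rep in range(n_repeats)]
    elif protocol == "diverse":
        plans = [diverse_split(y, test_fraction)]
    else:
        raise ValueError("protocol must be 'random' or 'diverse'")

    rows, err_rows = [], []
    for rep, plan in enumerate(plans):
        tr = np.array(plan.train_indices)
        te = np.array(plan.test_indices)
        for j, cl in enumerate(x.cellline_ids):
            tr_obs = tr[x.mask[tr, j] > 0]
            te_obs = te[x.mask[te, j] > 0]
            if len(tr_obs) < 2 or len(te_obs) == 0:
                warnings.warn(
                    f"cell line {cl!r} skipped in repeat {rep}: "
                    "too few observed values"
                )
                continue
            truth = x.values[te_obs, j]
            Ztr, Zte = _zscore_train(y.values[tr_obs].copy(),
                                     y.values[te_obs].copy())
            preds = {}
            w, b = fit_ridge(Ztr, x.values[tr_obs, j], ridge_alpha)
            preds["ridge"] = Zte @ w + b
            if include_svr:
                svr = SVR(kernel="rbf").fit(Ztr, x.values[tr_obs, j])
                preds["svr"] = svr.predict(Zte)
            # mask this column's test cells only; all other data stays
            xm = x.copy()
            xm.mask[te, j] = 0.0
            xm.values[te, j] = 0.0
            est = CMFImputer(**cmf_params).fit(xm, y)
            preds["cmf"] = est.predict()[te_obs, j]
            for method, p in preds.items():
                rows.append((cl, method, rep, rmse(truth, p),
                             r_squared(truth, p)))
                for idx, c in enumerate(te_obs):
                    err_rows.append((cl, method, rep,
                                     x.compound_ids[c],
                                     float((truth[idx] - p[idx]) ** 2)))
    metrics = pd.DataFrame(
        rows, columns=["cell_line", "method", "repeat", "rmse", "r_squared"]
    )
    sq = pd.DataFrame(
        err_rows,
        columns=["cell_line", "method", "repeat", "compound_id", "sq_error"],
    )
    return ComparisonReport(metrics, sq, protocol)


def sweep_regularization(x: ActivityTable, y: DescriptorTable,
                         grid=DEFAULT_LAMBDA_GRID,
                         ratios=DEFAULT_TRAIN_RATIOS,
                         seeds=(0, 1, 2),
                         cmf_params: dict = None) -> pd.DataFrame:
    """RMSE over all cell lines' held-out cells for each (lambda, ratio).

    For each seed and training ratio, that fraction of the observed cells
    (uniformly over the whole matrix) is kept for training and the rest
    held out; the factorization is fit with lambda1 = lambda2 = lambda.
    Returns a DataFrame indexed by lambda with one column per ratio
    (median over seeds).
    """
    x, y = align(x, y)
    cmf_params = dict(cmf_params or {})
    cmf_params.pop("lambda1", None)
    cmf_params.pop("lambda2", None)
    obs = np.argwhere(x.mask > 0)
    out = np.full((len(grid), len(ratios), len(seeds)), np.nan)
    for si, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        for ri, ratio in enumerate(ratios):
            n_train = int(round(ratio * len(obs)))
            keep = np.zeros(len(obs), dtype=bool)
            keep[rng.choice(len(obs), size=n_train, replace=False)] = True
            xm = x.copy()
            held = obs[~keep]
            xm.mask[held[:, 0], held[:, 1]] = 0.0
            xm.values[held[:, 0], held[:, 1]] = 0.0
            truth = x.values[held[:, 0], held[:, 1]]
            for gi, lam in enumerate(grid):
                est = CMFImputer(lambda1=lam, lambda2=lam,
                                 random_state=seed, **cmf_params)
                est.fit(xm, y)
                pred = est.predict()[held[:, 0], held[:, 1]]
                out[gi, ri, si] = rmse(truth, pred)
    table = np.median(out, axis=2)
    return pd.DataFrame(table, index=list(grid),
                        columns=[f"{r:.0%}" for r in ratios])
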