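"""Collective matrix factorization for multi-cell-line activity prediction.

The model jointly factorizes the (partially observed) compound x cell-line
activity matrix X ~ U V^T and the complete compound x descriptor matrix
Y ~ U W^T, sharing the compound factor matrix U.  Minimizing

    L(U, V, W) = 1/2 ||I o (X - U V^T)||_F^2
               + lambda1/2 ||Y - U W^T||_F^2
               + lambda2/2 (||U||_F^2 + ||V||_F^2 + ||W||_F^2)

(I the observation indicator, o the entrywise product) lets activity data
from all cell lines and the structural descriptors inform every prediction;
missing activities are read off U V^T.

Optimization is plain gradient descent with a step-halving line search:
each iteration takes the analytic gradients, starts at step size 1 and
halves until the objective strictly decreases, then updates U, V, W
simultaneously.  The trace of accepted objectives is non-increasing by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ActivityTable, DescriptorTable

__all__ = [
    "CMFImputer",
    "FactorModel",
    "FitConfig",
    "FitTrace",
    "init_factors",
    "objective_basic",
    "objective_cmf",
    "gradients",
    "fit_cmf",
    "predict",
]

STOP_MAX_ITER = "max_iter"
STOP_TOL = "tol_reached"
STOP_STALLED = "line_search_stalled"


@dataclass
class FactorModel:
    """The three latent factor matrices and the objective's weights.

    U: (m, d) compound factors, shared between both reconstructions.
    V: (n, d) cell-line factors.  W: (r, d) descriptor factors.
    lambda1 weighs the descriptor-reconstruction term, lambda2 the
    ridge penalty on all three factors.
    """

    U: np.ndarray
    V: np.ndarray
    W: np.ndarray
    lambda1: float = 0.1
    lambda2: float = 0.1
    compound_ids: list = None
    cellline_ids: list = None
    feature_names: list = None

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        d = self.U.shape[1]
        if self.V.shape[1] != d or self.W.shape[1] != d:
            raise ValueError("U, V, W must share the latent dimension d")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be nonnegative")

    @property
    def d(self) -> int:
        return self.U.shape[1]

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.U.copy(), self.V.copy(), self.W.copy(),
            self.lambda1, self.lambda2,
            self.compound_ids, self.cellline_ids, self.feature_names,
        )

    def to_json(self, path=None) -> str:
        doc = {
            "d": self.d,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "U": self.U.tolist(),
            "V": self.V.tolist(),
            "W": self.W.tolist(),
            "compound_ids": self.compound_ids,
            "cellline_ids": self.cellline_ids,
            "feature_names": self.feature_names,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FactorModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            np.array(doc["U"], dtype=float),
            np.array(doc["V"], dtype=float),
            np.array(doc["W"], dtype=float),
            doc["lambda1"],
            doc["lambda2"],
            doc.get("compound_ids"),
            doc.get("cellline_ids"),
            doc.get("feature_names"),
        )


@dataclass
class FitConfig:
    """Optimizer settings: iteration cap T, absolute-decrease tolerance
    epsilon, the RNG seed for initialization, the uniform init scale, and
    the line-search halving cap."""

    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_scale: float = 0.1
    max_halvings: int = 50

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init_scale < 0:
            raise ValueError("init_scale must be nonnegative")
        if self.max_halvings < 1:
            raise ValueError("max_halvings must be positive")


@dataclass
class FitTrace:
    objective_per_iter: list = field(default_factory=list)
    step_sizes: list = field(default_factory=list)
    stop_reason: str = ""


def init_factors(m, n, r, d=3, config: FitConfig = None,
                 lambda1=0.1, lambda2=0.1) -> FactorModel:
    """Seeded uniform [0, init_scale] initialization of U, V, W."""
    if d > min(m, n, r):
        raise ValueError(f"latent dimension d={d} exceeds min(m,n,r)="
                         f"{min(m, n, r)}")
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return FactorModel(
        rng.uniform(0, s, (m, d)) if s > 0 else np.zeros((m, d)),
        rng.uniform(0, s, (n, d)) if s > 0 else np.zeros((n, d)),
        rng.uniform(0, s, (r, d)) if s > 0 else np.zeros((r, d)),
        lambda1, lambda2,
    )


def _as_xy(x, y):
    """Accept tables or raw arrays; return X, mask, Y."""
    if isinstance(x, ActivityTable):
        X, mask = x.values, x.mask
    else:
        X = np.asarray(x, dtype=float)
        mask = (~np.isnan(X)).astype(float)
        X = np.nan_to_num(X)
    Y = y.values if isinstance(y, DescriptorTable) else np.asarray(y, float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("activity and descriptor row counts differ")
    return X, mask, Y


def objective_basic(U, V, x, lambda1=0.0, lambda2=0.0) -> float:
    """Masked factorization objective ||I o (X - U V^T)||_F^2
    + lambda1 ||U||_F^2 + lambda2 ||V||_F^2 (no descriptor term)."""
    if isinstance(x, ActivityTable):
        X, mask = x.values, x.mask
    else:
        X = np.asarray(x, dtype=float)
        mask = (~np.isnan(X)).astype(float)
        X = np.nan_to_num(X)
    U = np.asarray(U, float)
    V = np.asarray(V, float)
    if U.shape[0] != X.shape[0] or V.shape[0] != X.shape[1]:
        raise ValueError("factor shapes inconsistent with X")
    R = mask * (X - U @ V.T)
    return float((R * R).sum() + lambda1 * (U * U).sum()
                 + lambda2 * (V * V).sum())


def _objective(U, V, W, X, mask, Y, lambda1, lambda2) -> float:
    Rx = mask * (X - U @ V.T)
    Ry = Y - U @ W.T
    return float(
        0.5 * (Rx * Rx).sum()
        + 0.5 * lambda1 * (Ry * Ry).sum()
        + 0.5 * lambda2 * ((U * U).sum() + (V * V).sum() + (W * W).sum())
    )


def objective_cmf(model: FactorModel, x, y) -> float:
    """The joint objective L(U, V, W) (see module docstring)."""
    X, mask, Y = _as_xy(x, y)
    U, V, W = model.U, model.V, model.W
    if U.shape[0] != X.shape[0] or V.shape[0] != X.shape[1] \
            or W.shape[0] != Y.shape[1]:
        raise ValueError("factor shapes inconsistent with X/Y")
    return _objective(U, V, W, X, mask, Y, model.lambda1, model.lambda2)


def _gradients(U, V, W, X, mask, Y, lambda1, lambda2):
    Ex = mask * (U @ V.T - X)         # masked activity residual
    Ey = U @ W.T - Y                  # descriptor residual (Y complete)
    gU = Ex @ V + lambda1 * (Ey @ W) + lambda2 * U
    gV = Ex.T @ U + lambda2 * V
    gW = lambda1 * (Ey.T @ U) + lambda2 * W
    return gU, gV, gW


def gradients(model: FactorModel, x, y):
    """Analytic gradients of the joint objective w.r.t. U, V, W."""
    X, mask, Y = _as_xy(x, y)
    U, V, W = model.U, model.V, model.W
    if U.shape[0] != X.shape[0] or V.shape[0] != X.shape[1] \
            or W.shape[0] != Y.shape[1]:
        raise ValueError("factor shapes inconsistent with X/Y")
    return _gradients(U, V, W, X, mask, Y, model.lambda1, model.lambda2)


def _descend(U, V, W, X, mask, Y, lambda1, lambda2,
             max_iter, tol, max_halvings):
    """Gradient descent with step-halving line search.

    Returns updated factors and a FitTrace whose first entry is the
    initial objective.
    """
    trace = FitTrace()
    L = _objective(U, V, W, X, mask, Y, lambda1, lambda2)
    trace.objective_per_iter.append(L)
    stop = STOP_MAX_ITER
    for _ in range(max_iter):
        gU, gV, gW = _gradients(U, V, W, X, mask, Y, lambda1, lambda2)
        gamma = 1.0
        accepted = False
        for _h in range(max_halvings):
            Lnew = _objective(U - gamma * gU, V - gamma * gV,
                              W - gamma * gW, X, mask, Y, lambda1, lambda2)
            if Lnew < L:
                accepted = True
                break
            gamma /= 2.0
        if not accepted:
            stop = STOP_STALLED
            break
        U = U - gamma * gU
        V = V - gamma * gV
        W = W - gamma * gW
        decrease = L - Lnew
        L = Lnew
        trace.objective_per_iter.append(L)
        trace.step_sizes.append(gamma)
        if decrease <= tol:
            stop = STOP_TOL
            break
    trace.stop_reason = stop
    return U, V, W, trace


class CMFImputer(TransformerMixin, BaseEstimator):
    """Impute missing activities by collective matrix factorization.

    Fits X ~ U V^T jointly with the side matrix of compound descriptors
    Y ~ U W^T, sharing compound factors U, by gradient descent with a
    step-halving line search.  ``transform`` fills the missing entries
    of the activity matrix with the model reconstruction.

    Parameters
    ----------
    n_components : int, default=3
        Latent dimension d; must satisfy d <= min(m, n, r).
    lambda1 : float, default=0.1
        Weight of the descriptor-reconstruction term.
    lambda2 : float, default=0.1
        Ridge penalty on U, V and W.
    max_iter : int, default=500
        Iteration cap T.
    tol : float, default=1e-6
        Stop when the absolute objective decrease falls to this value.
    init_scale : float, default=0.1
        Factors start uniform on [0, init_scale].
    max_halvings : int, default=50
        Line-search budget per iteration; exhausting it stops the fit.
    random_state : int, default=0
        Seed for the initialization.

    Attributes
    ----------
    U_, V_, W_ : ndarray
        Fitted factor matrices.
    trace_ : FitTrace
        Objective per accepted iteration, accepted step sizes, stop reason.
    n_iter_ : int
        Number of accepted updates.

    Examples
    --------
    >>> from cmfqsar.simulate import simulate_lowrank
    >>> x, y, _ = simulate_lowrank(20, 4, 6, 2, 0.0, 0.0, 0.2, seed=0)
    >>> est = CMFImputer(n_components=2, lambda1=1.0, lambda2=1e-6,
    ...                  random_state=0).fit(x, y)
    >>> est.predict().shape
    (20, 4)
    """

    def __init__(self, n_components=3, lambda1=0.1, lambda2=0.1,
                 max_iter=500, tol=1e-6, init_scale=0.1, max_halvings=50,
                 random_state=0):
        self.n_components = n_components
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.max_iter = max_iter
        self.tol = tol
        self.init_scale = init_scale
        self.max_halvings = max_halvings
        self.random_state = random_state

    def fit(self, X, Y, model0: FactorModel = None):
        """Fit the factorization.

        X may be an ActivityTable or an (m, n) array with NaN marking
        missing cells; Y a DescriptorTable or complete (m, r) array.
        ``model0`` overrides the seeded uniform initialization.
        """
        Xv, mask, Yv = _as_xy(X, Y)
        m, n = Xv.shape
        r = Yv.shape[1]
        if model0 is None:
            cfg = FitConfig(self.max_iter, self.tol, self.random_state,
                            self.init_scale, self.max_halvings)
            model0 = init_factors(m, n, r, self.n_components, cfg,
                                  self.lambda1, self.lambda2)
        lam1, lam2 = model0.lambda1, model0.lambda2
        U, V, W, trace = _descend(
            model0.U.copy(), model0.V.copy(), model0.W.copy(),
            Xv, mask, Yv, lam1, lam2,
            self.max_iter, self.tol, self.max_halvings,
        )
        self.U_, self.V_, self.W_ = U, V, W
        self.lambda1_, self.lambda2_ = lam1, lam2
        self.trace_ = trace
        self.n_iter_ = len(trace.step_sizes)
        self.objective_ = trace.objective_per_iter[-1]
        if isinstance(X, ActivityTable):
            self.compound_ids_ = list(X.compound_ids)
            self.cellline_ids_ = list(X.cellline_ids)
        return self

    def predict(self):
        """Reconstructed activity matrix U V^T (observed and missing cells)."""
        return self.U_ @ self.V_.T

    def transform(self, X):
        """Return X with its missing cells filled from the reconstruction."""
        if isinstance(X, ActivityTable):
            Xv, mask = X.values, X.mask
        else:
            Xv = np.asarray(X, dtype=float)
            mask = (~np.isnan(Xv)).astype(float)
            Xv = np.nan_to_num(Xv)
        full = self.predict()
        return mask * Xv + (1 - mask) * full

    def factor_model(self) -> FactorModel:
        return FactorModel(self.U_.copy(), self.V_.copy(), self.W_.copy(),
                           self.lambda1_, self.lambda2_,
                           getattr(self, "compound_ids_", None),
                           getattr(self, "cellline_ids_", None))


def fit_cmf(x, y, model0: FactorModel, config: FitConfig = None):
    """Functional fit: run Algorithm-style descent from ``model0``.

    Returns (fitted FactorModel, FitTrace)."""
    config = config or FitConfig()
    est = CMFImputer(
        n_components=model0.d, lambda1=model0.lambda1,
        lambda2=model0.lambda2, max_iter=config.max_iter, tol=config.tol,
        init_scale=config.init_scale, max_halvings=config.max_halvings,
        random_state=config.seed,
    )
    est.fit(x, y, model0=model0)
    fitted = FactorModel(est.U_, est.V_, est.W_, model0.lambda1,
                         model0.lambda2)
    if isinstance(x, ActivityTable):
        fitted.compound_ids = list(x.compound_ids)
        fitted.cellline_ids = list(x.cellline_ids)
    if isinstance(y, DescriptorTable):
        fitted.feature_names = list(y.feature_names)
    return fitted, est.trace_


def predict(model: FactorModel) -> np.ndarray:
    """Reconstruction U V^T; callers index the cells they held out."""
    return model.U @ model.V.T
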