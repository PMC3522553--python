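"""Synthetic ground-truth generators for the factorization and its harness.

Three generators cover the shapes the package is exercised on:

* ``simulate_lowrank`` — an exactly low-rank activity/descriptor pair
  with optional Gaussian noise and per-column missingness, for recovery
  experiments;
* ``simulate_dli_panel`` — a 93-compound x 4-cell-line dataset with
  28 integer count descriptors emulating a drug-like-index table,
  including one structural count identically zero across the series and
  activities driven by five planted features;
* ``simulate_shared_latent`` — per-cell-line activity columns whose
  shared-signal fraction is dialed by ``cross_column_signal``, for
  measuring the gain of borrowing information across cell lines.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ActivityTable, DescriptorTable

__all__ = [
    "SynthTruth",
    "simulate_lowrank",
    "simulate_dli_panel",
    "simulate_shared_latent",
]

#: cell-line names used by the DLI panel fixture
CELL_LINES = ["BxPC-3", "NCI-H446", "SW1990", "NCI-H157"]

#: feature column (0-based) that is identically zero in the panel-shaped
#: fixture — the analogue of a bonding-pattern count absent from the series
ZERO_FEATURE = 17

#: features whose planted linear combination drives the fixture activities
TRUE_FEATURES = (0, 4, 12, 22, 26)


@dataclass
class SynthTruth:
    """Generating factors / coefficients behind a synthetic dataset."""

    U: np.ndarray = None
    V: np.ndarray = None
    W: np.ndarray = None
    noise_sd_x: float = 0.0
    noise_sd_y: float = 0.0
    missing_fraction: np.ndarray = None
    seed: int = 0
    true_features: tuple = None
    coefficients: np.ndarray = None
    column_scales: np.ndarray = None


def _ids(prefix, k):
    return [f"{prefix}{i:03d}" for i in range(k)]


def simulate_lowrank(m, n, r, d, noise_sd_x=0.0, noise_sd_y=0.0,
                     missing_fraction=0.0, seed=0):
    """Exactly rank-<=d activity and descriptor matrices sharing U.

    Factors are absolute values of standard-normal draws; X = U V^T plus
    noise clipped at zero, Y = U W^T plus noise.  ``missing_fraction``
    may be a scalar or a length-n sequence; round(f*m) cells per column
    are masked uniformly at random.
    """
    if d > min(m, n, r):
        raise ValueError("d must not exceed min(m, n, r)")
    frac = np.broadcast_to(np.asarray(missing_fraction, dtype=float), (n,))
    if (frac < 0).any() or (frac >= 1).any():
        raise ValueError("missing_fraction must be in [0, 1)")
    if ((m - np.round(frac * m)) < 2).any():
        raise ValueError("missingness leaves fewer than 2 observed per column")
    rng = np.random.default_rng(seed)
    U = np.abs(rng.standard_normal((m, d)))
    V = np.abs(rng.standard_normal((n, d)))
    W = np.abs(rng.standard_normal((r, d)))
    X = U @ V.T
    if noise_sd_x > 0:
        X = np.clip(X + rng.normal(0, noise_sd_x, X.shape), 0, None)
    Y = U @ W.T
    if noise_sd_y > 0:
        Y = Y + rng.normal(0, noise_sd_y, Y.shape)
    mask = np.ones((m, n))
    for j in range(n):
        k = int(round(frac[j] * m))
        if k:
            mask[rng.choice(m, size=k, replace=False), j] = 0.0
    x = ActivityTable(_ids("C", m), _ids("T", n), X, mask)
    y = DescriptorTable(_ids("C", m), _ids("F", r), Y)
    truth = SynthTruth(U=U, V=V, W=W, noise_sd_x=noise_sd_x,
                       noise_sd_y=noise_sd_y, missing_fraction=frac.copy(),
                       seed=seed)
    return x, y, truth


def simulate_dli_panel(seed=0, noise_sd=0.3):
    """A 93 x 4 activity table with 28 integer count descriptors.

    Descriptor counts have Poisson marginals (rates spread over 0.5–8);
    column ``ZERO_FEATURE`` is identically zero.  Activities are a
    nonnegative linear function of the five ``TRUE_FEATURES`` columns
    (per-cell-line positive coefficients) plus Gaussian noise, clipped
    at zero; the mask is full.
    """
    m, n, r = 93, 4, 28
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0.5, 8.0, r)
    Y = rng.poisson(rates, (m, r)).astype(float)
    Y[:, ZERO_FEATURE] = 0.0
    coef = rng.uniform(0.3, 1.0, (n, len(TRUE_FEATURES)))
    base = Y[:, list(TRUE_FEATURES)]
    X = base @ coef.T / base.mean() + rng.normal(0, noise_sd, (m, n))
    X = np.clip(X, 0, None)
    x = ActivityTable(_ids("C", m), list(CELL_LINES), X, np.ones((m, n)))
    y = DescriptorTable(_ids("C", m), [f"DLI{j + 1}" for j in range(r)], Y)
    truth = SynthTruth(noise_sd_x=noise_sd, seed=seed,
                       true_features=TRUE_FEATURES, coefficients=coef)
    return x, y, truth


def simulate_shared_latent(m, n, d, cross_column_signal, seed=0,
                           noise_sd_x=0.1, noise_sd_y=0.3, r=None):
    """Activity columns with a tunable shared-signal fraction.

    Each column j is c_j * (s * z_shared + (1 - s) * z_j) where z_shared
    comes from the shared compound factors U (also behind the descriptor
    matrix Y = U W^T + noise), z_j from column-specific independent
    factors, c_j > 0 a per-column scale, and s = ``cross_column_signal``.
    At s=1 and zero noise all columns are equal up to positive scaling;
    at s=0 columns are mutually independent.
    """
    if not 0.0 <= cross_column_signal <= 1.0:
        raise ValueError("cross_column_signal must be in [0, 1]")
    r = r if r is not None else max(2 * d, 8)
    rng = np.random.default_rng(seed)
    U = np.abs(rng.standard_normal((m, d)))
    v0 = np.abs(rng.standard_normal(d))
    z_shared = U @ v0
    Z = np.empty((m, n))
    s = cross_column_signal
    for j in range(n):
        Uj = np.abs(rng.standard_normal((m, d)))
        vj = np.abs(rng.standard_normal(d))
        Z[:, j] = s * z_shared + (1.0 - s) * (Uj @ vj)
    scales = rng.uniform(0.5, 2.0, n)
    X = Z * scales
    if noise_sd_x > 0:
        X = X + rng.normal(0, noise_sd_x, X.shape)
    X = np.clip(X, 0, None)
    W = np.abs(rng.standard_normal((r, d)))
    Y = U @ W.T
    if noise_sd_y > 0:
        Y = Y + rng.normal(0, noise_sd_y, Y.shape)
    x = ActivityTable(_ids("C", m), _ids("T", n), X, np.ones((m, n)))
    y = DescriptorTable(_ids("C", m), _ids("F", r), Y)
    truth = SynthTruth(U=U, V=np.outer(scales, v0), W=W,
                       noise_sd_x=noise_sd_x, noise_sd_y=noise_sd_y,
                       seed=seed, column_scales=scales)
    return x, y, truth
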