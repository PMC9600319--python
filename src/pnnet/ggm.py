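"""Targeted ridge estimation of a partial-correlation network.

The network estimator is a Gaussian graphical model fitted by targeted
ridge (archetype-I) regularization of the precision matrix: given a
sample covariance ``S``, a penalty ``lambda > 0`` and a symmetric
positive semi-definite target ``T``, the estimate is the closed form

    Omega(lambda) = { [lambda I + (1/4)(S - lambda T)^2]^{1/2}
                      + (1/2)(S - lambda T) }^{-1}

evaluated through the eigendecomposition of ``S - lambda T``: an
eigenvalue ``e`` of ``S - lambda T`` maps to the eigenvalue
``1 / (sqrt(lambda + e^2/4) + e/2)`` of ``Omega``, which is positive for
every ``lambda > 0``, so the estimate is always symmetric positive
definite -- even when ``S`` is singular.  As ``lambda -> 0`` with
invertible ``S`` the estimate converges to ``S^{-1}``, and shrinkage is
toward ``T^{-1}`` as ``lambda`` grows.

The precision estimate is converted to partial correlations and
sparsified by absolute thresholding (default cut-off 0.1, inclusive)
into a conditional-independence graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .variables import ROLES

__all__ = [
    "CovarianceEstimate",
    "PrecisionEstimate",
    "sample_covariance",
    "scaled_identity_target",
    "ridge_precision",
    "select_penalty",
    "default_penalty_grid",
    "precision_to_pcor",
    "sparsify_threshold",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class CovarianceEstimate:
    """Sample covariance with the sample size and variable names attached."""

    matrix: np.ndarray
    n: int
    names: tuple[str, ...]


@dataclass(frozen=True)
class PrecisionEstimate:
    """Ridge precision estimate with its penalty and target."""

    matrix: np.ndarray
    penalty: float
    target: np.ndarray
    names: tuple[str, ...]


def _check_symmetric(M: np.ndarray, what: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{what} must be a square matrix")
    if not np.allclose(M, M.T, atol=_SYM_TOL):
        raise ValueError(f"{what} must be symmetric")
    return 0.5 * (M + M.T)


def sample_covariance(panel: pd.DataFrame, ml: bool = True) -> CovarianceEstimate:
    """Covariance of the (transformed) panel columns.

    Uses the maximum-likelihood divisor ``n`` by default, matching the
    penalized-likelihood formulation of the ridge estimator; ``ml=False``
    gives the unbiased ``n - 1`` divisor.
    """
    if panel.isna().any().any():
        raise ValueError("panel contains missing values; apply listwise_complete first")
    n = len(panel)
    if n < 2:
        raise ValueError("need at least two rows")
    X = panel.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n if ml else n - 1)
    return CovarianceEstimate(matrix=S, n=n, names=tuple(panel.columns))


def scaled_identity_target(S: np.ndarray) -> np.ndarray:
    """Default ridge target ``nu * I`` with ``nu = p / trace(S)``."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    tr = float(np.trace(S))
    if tr <= 0:
        raise ValueError("covariance trace must be positive")
    return (p / tr) * np.eye(p)


def _resolve_target(S: np.ndarray, target) -> np.ndarray:
    if target is None or (isinstance(target, str) and target == "scaled-identity"):
        return scaled_identity_target(S)
    if isinstance(target, str):
        if target == "zero":
            return np.zeros_like(S)
        if target == "identity":
            return np.eye(S.shape[0])
        raise ValueError(f"unknown target {target!r}")
    T = _check_symmetric(target, "target")
    if np.linalg.eigvalsh(T).min() < -_SYM_TOL:
        raise ValueError("target must be positive semi-definite")
    return T


def ridge_precision(
    S: CovarianceEstimate | np.ndarray,
    penalty: float,
    target="scaled-identity",
) -> PrecisionEstimate:
    """Targeted ridge precision estimate at the given penalty.

    ``target`` may be ``"scaled-identity"`` (``p/trace(S) * I``, default),
    ``"identity"``, ``"zero"``, or an explicit symmetric PSD matrix.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if isinstance(S, CovarianceEstimate):
        names, Smat = S.names, S.matrix
    else:
        Smat = np.asarray(S, dtype=float)
        names = tuple(f"x{i}" for i in range(Smat.shape[0]))
    Smat = _check_symmetric(Smat, "covariance")
    T = _resolve_target(Smat, target)
    # spectral evaluation of the closed form
    evals, V = np.linalg.eigh(Smat - penalty * T)
    omega_evals = 1.0 / (np.sqrt(penalty + 0.25 * evals**2) + 0.5 * evals)
    Omega = (V * omega_evals) @ V.T
    Omega = 0.5 * (Omega + Omega.T)
    return PrecisionEstimate(matrix=Omega, penalty=float(penalty), target=T, names=names)


def default_penalty_grid(num: int = 25) -> np.ndarray:
    """Logarithmic penalty grid from 1e-4 to 1e2."""
    return np.logspace(-4, 2, num)


def _gauss_loglik(Omega: np.ndarray, S_test: np.ndarray) -> float:
    # per-observation Gaussian log-likelihood, constants dropped
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return -np.inf
    return 0.5 * (logdet - float(np.trace(S_test @ Omega)))


def select_penalty(
    panel: pd.DataFrame,
    grid=None,
    k: int = 5,
    seed: int = 0,
    target="scaled-identity",
    return_scores: bool = False,
):
    """K-fold cross-validated penalty selection.

    For each grid value, fits the ridge precision on the training folds
    and scores the held-out Gaussian log-likelihood; returns the grid
    value with the highest mean held-out score.  Fold assignment is a
    seeded permutation, so the selection is deterministic under ``seed``.
    """
    if grid is None:
        grid = default_penalty_grid()
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("penalty grid is empty")
    if np.any(grid <= 0):
        raise ValueError("penalties must be positive")
    n = len(panel)
    if not 2 <= k <= n:
        raise ValueError(f"fold count must be in [2, {n}]")
    X = panel.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    fold = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(fold)
    scores = np.zeros(grid.size)
    for f in range(k):
        train, test = X[fold != f], X[fold == f]
        if len(train) < 2 or len(test) < 1:
            raise ValueError("degenerate folds; reduce k")
        S_train = _cov_ml(train)
        # score test data around the training mean (the fitted mean)
        dm = test.mean(axis=0) - train.mean(axis=0)
        S_test = _cov_ml(test) + np.outer(dm, dm)
        for j, lam in enumerate(grid):
            Om = ridge_precision(S_train, lam, target=target).matrix
            scores[j] += _gauss_loglik(Om, S_test)
    scores /= k
    best = grid[int(np.argmax(scores))]
    if return_scores:
        return float(best), scores
    return float(best)


def _cov_ml(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / len(X)


def precision_to_pcor(precision: PrecisionEstimate | np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    ``P_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`` off the diagonal,
    unit diagonal.
    """
    Omega = precision.matrix if isinstance(precision, PrecisionEstimate) else np.asarray(precision, float)
    Omega = _check_symmetric(Omega, "precision")
    d = np.diag(Omega)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    scale = 1.0 / np.sqrt(d)
    P = -Omega * np.outer(scale, scale)
    np.fill_diagonal(P, 1.0)
    return P


def sparsify_threshold(
    pcor: np.ndarray,
    cutoff: float = 0.1,
    names: tuple[str, ...] | None = None,
    roles: dict[str, str] | None = None,
) -> nx.Graph:
    """Threshold the partial-correlation matrix into a graph.

    An edge ``(i, j)`` is present iff ``|P_ij| >= cutoff`` (inclusive)
    and carries the signed partial correlation as its ``weight``.  Node
    ``role`` attributes are attached when available.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    P = _check_symmetric(pcor, "partial-correlation matrix")
    p = P.shape[0]
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    if roles is None:
        roles = {v: ROLES.get(v, "variable") for v in names}
    G = nx.Graph(threshold=float(cutoff))
    for v in names:
        G.add_node(v, role=roles.get(v, "variable"))
    for i in range(p):
        for j in range(i + 1, p):
            w = float(P[i, j])
            if abs(w) >= cutoff:
                G.add_edge(names[i], names[j], weight=w, sign=1 if w > 0 else -1)
    return G
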