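"""Gaussian mixture model fitted by expectation-maximization.

Intensities are modelled as a mixture of M Gaussian components, one per
tissue class: p(x_i | theta) = sum_j alpha_j N(x_i; mu_j, Sigma_j).  The
E-step computes per-pixel posterior class probabilities by Bayes' rule, the
M-step re-estimates weights, means and covariances from those posteriors,
and the two alternate until the log-likelihood stalls.

The module also hosts the generic EM engine shared with the spatially
regularized variant (:mod:`emseg.spatial`): every function accepts an
optional neighbourhood-average feature array and a spatial weight ``beta``;
with ``beta = 0`` the spatial terms are skipped entirely, so the standard
and spatial code paths are bit-identical in that limit.

All density work is done in log-space with log-sum-exp normalization, so
responsibilities never underflow to an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io import ImageVolume, normalize_intensity

logger = logging.getLogger(__name__)

#: Default variance floor on [0,1]-normalized intensities; applied after the
#: covariance update to prevent singular collapse onto a single value.
VARIANCE_FLOOR = 1e-8


class NumericalDomainError(ValueError):
    """Raised when a covariance matrix is not positive-definite."""


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass
class MixtureParams:
    """Mixture parameters: weights alpha_j, means mu_j, covariances Sigma_j.

    Stored as arrays of shape ``(M,)``, ``(M, D)`` and ``(M, D, D)``; the
    single-channel case is D = 1.  Weights are non-negative and sum to one.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.means.ndim == 1:
            self.means = self.means[:, None]
        if self.covariances.ndim == 1:
            self.covariances = self.covariances[:, None, None]
        M = self.weights.shape[0]
        if self.means.shape[0] != M or self.covariances.shape[0] != M:
            raise ValueError("weights, means and covariances disagree on M")

    @classmethod
    def from_scalars(cls, weights: Sequence[float], means: Sequence[float],
                     variances: Sequence[float]) -> "MixtureParams":
        return cls(np.asarray(weights, float), np.asarray(means, float),
                   np.asarray(variances, float))

    @property
    def n_components(self) -> int:
        return int(self.weights.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.means.shape[1])

    def validate(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("negative mixing coefficient")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixing coefficients must sum to 1")
        for cov in self.covariances:
            if not np.all(np.isfinite(cov)):
                raise ValueError("non-finite covariance")

    def scaled(self, scale: float, offset: float) -> "MixtureParams":
        """Parameters after the affine intensity map x -> offset + scale*x."""
        return MixtureParams(self.weights.copy(),
                             offset + scale * self.means,
                             (scale ** 2) * self.covariances)


@dataclass
class FitResult:
    """Outcome of an EM fit.

    ``labels`` is the argmax of the responsibilities reshaped to the image
    (ties resolved to the lowest component index).  ``params`` is reported on
    the original intensity scale; ``log_likelihood_trace`` is recorded on the
    internal [0,1]-normalized scale, one entry per iteration evaluated at the
    then-current parameters.
    """

    params: MixtureParams
    responsibilities: np.ndarray
    labels: np.ndarray
    log_likelihood_trace: list
    n_iterations: int
    converged: bool
    beta: float = 0.0
    value_range: Optional[tuple] = None
    stop_reason: str = ""


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log multivariate normal density at each row of ``X`` (shape (N, D))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    D = mean.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalDomainError("covariance is not positive-definite") from exc
    diff = X - mean
    sol = solve_triangular(L, diff.T, lower=True)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (D * np.log(2.0 * np.pi) + logdet + maha)


def component_pdf(x, mean, covariance) -> float:
    """Gaussian component density N(x; mu, Sigma) at a single point."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(np.exp(_log_gauss(x[None, :], mean, covariance)[0]))


def _log_component_matrix(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(N, M) matrix of log p_j(x_i | theta_j), without mixing weights."""
    return np.stack(
        [_log_gauss(X, params.means[j], params.covariances[j])
         for j in range(params.n_components)],
        axis=1,
    )


def _log_blended(X: np.ndarray, params: MixtureParams,
                 Xb: Optional[np.ndarray], beta: float) -> np.ndarray:
    """log of A_ij = (1-beta) p_j(x_i) + beta p_j(xbar_i), shape (N, M).

    ``beta = 0`` takes the plain-density branch so the spatial term never
    enters the arithmetic (exact reduction to the standard model).
    """
    logp = _log_component_matrix(X, params)
    if beta == 0.0:
        return logp
    if Xb is None:
        raise ValueError("beta > 0 requires a neighbourhood-average array")
    logpb = _log_component_matrix(Xb, params)
    if beta == 1.0:
        return logpb
    return np.logaddexp(np.log1p(-beta) + logp, np.log(beta) + logpb)


# ---------------------------------------------------------------------------
# E / M / likelihood (generic in beta; public wrappers fix beta = 0)
# ---------------------------------------------------------------------------


def _as_features(data) -> tuple[np.ndarray, tuple]:
    """Flatten a single-channel image/volume to an (N, 1) feature array."""
    if isinstance(data, ImageVolume):
        arr = data.data
    else:
        arr = np.asarray(data, dtype=float)
    return arr.reshape(-1, 1), arr.shape


def _loglik(X, params, Xb=None, beta=0.0) -> float:
    logA = _log_blended(X, params, Xb, beta)
    return float(np.sum(logsumexp(np.log(params.weights) + logA, axis=1)))


def _e_step(X, params, Xb=None, beta=0.0) -> np.ndarray:
    with np.errstate(divide="ignore"):  # zero weights are legal
        logr = np.log(params.weights) + _log_blended(X, params, Xb, beta)
    logr -= logsumexp(logr, axis=1, keepdims=True)
    return np.exp(logr)


def _m_step(X, R, Xb=None, beta=0.0, variance_floor=VARIANCE_FLOOR,
            normalize_covariance=False) -> MixtureParams:
    X = np.asarray(X, dtype=float)
    R = np.asarray(R, dtype=float)
    N, D = X.shape
    M = R.shape[1]
    Nj = R.sum(axis=0)
    collapsed = np.flatnonzero(Nj <= N * 1e-300)
    if beta == 0.0:
        Z = X
    else:
        Z = (1.0 - beta) * X + beta * Xb
    means = np.empty((M, D))
    covs = np.empty((M, D, D))
    safe_Nj = np.where(Nj > 0, Nj, 1.0)
    for j in range(M):
        means[j] = R[:, j] @ Z / safe_Nj[j]
        diff = X - means[j]
        C = (R[:, j, None] * diff).T @ diff
        if beta != 0.0:
            diffb = Xb - means[j]
            C = C + beta * ((R[:, j, None] * diffb).T @ diffb)
        C = C / safe_Nj[j]
        if normalize_covariance and beta != 0.0:
            C = C / (1.0 + beta)
        covs[j] = _floor_cov(C, variance_floor)
    weights = Nj / N
    if collapsed.size:
        # component collapse: re-seed from the pixel the model explains worst
        i_star = int(np.argmin(R.max(axis=1)))
        data_cov = _floor_cov(np.atleast_2d(np.cov(X, rowvar=False)), variance_floor)
        for j in collapsed:
            logger.warning("component %d collapsed; re-seeding from pixel %d", j, i_star)
            means[j] = X[i_star]
            covs[j] = data_cov
            weights[j] = 1.0 / N
        weights = weights / weights.sum()
    return MixtureParams(weights, means, covs)


def _floor_cov(C: np.ndarray, floor: float) -> np.ndarray:
    C = np.atleast_2d(C)
    if C.shape == (1, 1):
        return np.array([[max(C[0, 0], floor)]])
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    return (V * np.maximum(w, floor)) @ V.T


def log_likelihood(data, params: MixtureParams) -> float:
    """Mixture log-likelihood sum_i log sum_j alpha_j p_j(x_i | theta_j)."""
    X, _ = _as_features(data)
    if X.size == 0:
        raise ValueError("empty data")
    return _loglik(X, params)


def e_step(data, params: MixtureParams) -> np.ndarray:
    """Posterior class probabilities p(j | x_i, theta), shape (N, M)."""
    X, _ = _as_features(data)
    return _e_step(X, params)


def m_step(data, responsibilities: np.ndarray,
           variance_floor: float = VARIANCE_FLOOR) -> MixtureParams:
    """Re-estimate weights, means and covariances from responsibilities."""
    X, _ = _as_features(data)
    return _m_step(X, np.asarray(responsibilities, float),
                   variance_floor=variance_floor)


# ---------------------------------------------------------------------------
# initialization and the fit loop
# ---------------------------------------------------------------------------


def _init_params(X: np.ndarray, M: int, init, seed: int,
                 variance_floor: float) -> MixtureParams:
    N, D = X.shape
    if isinstance(init, MixtureParams):
        return init
    global_cov = _floor_cov(np.atleast_2d(np.cov(X, rowvar=False)) if N > 1
                            else np.eye(D), variance_floor)
    if init == "kmeans":
        km = KMeans(n_clusters=M, n_init=10, random_state=seed).fit(X)
        order = np.argsort(km.cluster_centers_[:, 0])
        means = km.cluster_centers_[order]
        weights = np.array([np.mean(km.labels_ == order[j]) for j in range(M)])
        covs = np.empty((M, D, D))
        for j in range(M):
            pts = X[km.labels_ == order[j]]
            covs[j] = (_floor_cov(np.atleast_2d(np.cov(pts, rowvar=False)),
                                  variance_floor)
                       if pts.shape[0] > 1 else global_cov)
        return MixtureParams(weights, means, covs)
    if init == "quantile":
        qs = (2 * np.arange(M) + 1) / (2 * M)
        means = np.stack([np.quantile(X[:, d], qs) for d in range(D)], axis=1)
        covs = np.broadcast_to(global_cov, (M, D, D)).copy()
        return MixtureParams(np.full(M, 1.0 / M), means, covs)
    raise ValueError(f"unknown init {init!r}")


def _fit(X: np.ndarray, M: int, init, seed: int, tol: float, max_iter: int,
         Xb: Optional[np.ndarray] = None, beta: float = 0.0,
         variance_floor: float = VARIANCE_FLOOR,
         normalize_covariance: bool = False) -> dict:
    """Generic EM loop on pre-normalized features; returns fit internals.

    Convergence: relative objective change below ``tol``.  For ``beta > 0``
    the printed update rules are not a proven ascent on the objective, so the
    loop additionally stops after two consecutive decreases, keeping the
    best-objective parameters seen.
    """
    params = _init_params(X, M, init, seed, variance_floor)
    trace: list[float] = []
    best_ll = -np.inf
    best_params = params
    decreases = 0
    converged = False
    stop_reason = "max_iter"
    for it in range(max_iter):
        ll = _loglik(X, params, Xb, beta)
        trace.append(ll)
        if ll >= best_ll:
            best_ll = ll
            best_params = params
        if it > 0:
            prev = trace[-2]
            rel = abs(ll - prev) / max(abs(prev), 1e-300)
            if rel < tol:
                converged = True
                stop_reason = "tol"
                break
            if beta != 0.0:
                decreases = decreases + 1 if ll < prev else 0
                if decreases >= 2:
                    params = best_params
                    stop_reason = "objective_decreased"
                    logger.info("objective decreased twice; keeping best parameters")
                    break
        R = _e_step(X, params, Xb, beta)
        params = _m_step(X, R, Xb, beta, variance_floor, normalize_covariance)
    R = _e_step(X, params, Xb, beta)
    return dict(params=params, responsibilities=R, trace=trace,
                n_iterations=len(trace), converged=converged,
                stop_reason=stop_reason)


def fit_gmm(data, M: int, init="kmeans", seed: int = 0, tol: float = 1e-6,
            max_iter: int = 200,
            variance_floor: float = VARIANCE_FLOOR) -> FitResult:
    """Fit an M-component Gaussian mixture to image intensities by EM.

    Intensities are min-max normalized to [0, 1] internally (hard labels are
    invariant under this affine map); the returned parameters are mapped back
    to the input scale.  Deterministic for a given ``seed``.
    """
    X, shape = _as_features(data)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    n_distinct = np.unique(X[:, 0] if X.shape[1] == 1 else X, axis=0).shape[0]
    if M < 1 or M > n_distinct:
        raise ValueError(f"M={M} exceeds the number of distinct values ({n_distinct})")
    Xn, (vmin, vmax) = normalize_intensity(X)
    if isinstance(init, MixtureParams):
        scale = vmax - vmin if vmax > vmin else 1.0
        init = init.scaled(1.0 / scale, -vmin / scale)
    out = _fit(Xn, M, init, seed, tol, max_iter, variance_floor=variance_floor)
    labels = np.argmax(out["responsibilities"], axis=1).reshape(shape)
    scale = vmax - vmin if vmax > vmin else 1.0
    return FitResult(
        params=out["params"].scaled(scale, vmin),
        responsibilities=out["responsibilities"],
        labels=labels,
        log_likelihood_trace=out["trace"],
        n_iterations=out["n_iterations"],
        converged=out["converged"],
        beta=0.0,
        value_range=(vmin, vmax),
        stop_reason=out["stop_reason"],
    )
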