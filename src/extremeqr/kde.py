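"""Kernel estimation of conditional-density weights.

The efficiency weight for weighted quantile regression at level tau is the
conditional density of the response evaluated at the conditional quantile,
w_i = f(xi(tau | x_i) | x_i). Neither factor is observed, so both are
estimated nonparametrically:

* densities via the whitened ("Fukunaga") multivariate normal-kernel
  estimator  f_hat(z) = (det S)^(-1/2) / (n h^d) * sum_i k((z - Z_i)' S^-1
  (z - Z_i) / h^2)  with k(u) = (2 pi)^(-d/2) exp(-u/2) and S the sample
  covariance of the coordinates being smoothed;
* the conditional cdf via the Nadaraya-Watson ratio
  F_hat(y | x) = sum_i K_h(x - x_i) 1{y_i <= y} / sum_i K_h(x - x_i),
  inverted over the observed response grid to get
  xi_hat(tau | x) = inf{y_(j) : F_hat(y_(j) | x) >= tau};
* the conditional density as the ratio of a joint (y, x) estimate to a
  marginal x estimate, each with its own covariance whitening and the
  normal-reference bandwidth h = (4/(d+2))^(1/(d+4)) n^(-1/(d+4)) in its
  own dimension.

Degenerate coordinates (a constant column makes S singular) raise rather
than being silently regularized.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .data import ObservationSet, WeightVector, validate_tau

__all__ = [
    "bandwidth_optimal",
    "FukunagaKDE",
    "mv_kde",
    "conditional_cdf",
    "conditional_quantile",
    "density_weights",
]


def bandwidth_optimal(n: int, d: int) -> float:
    """Normal-reference bandwidth A(K) n^(-1/(d+4)), A(K) = (4/(d+2))^(1/(d+4)).

    ``n`` is the sample size and ``d`` the dimension being smoothed.
    """
    if n < 1 or d < 1:
        raise ValueError("need n >= 1 and d >= 1")
    return (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * float(n) ** (-1.0 / (d + 4.0))


def _whitening(data: np.ndarray, cov: np.ndarray | None):
    """Sample covariance (ddof=1) of ``data`` and its Cholesky factor.

    Raises ValueError when the covariance is singular (e.g. a constant
    column) — callers may jitter, we do not regularize.
    """
    d = data.shape[1]
    if cov is None:
        if data.shape[0] < 2:
            raise ValueError("need at least 2 points to estimate a covariance; pass cov explicitly")
        cov = np.atleast_2d(np.cov(data, rowvar=False, ddof=1))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape != (d, d):
        raise ValueError(f"covariance must be {d}x{d}; got {cov.shape}")
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("singular or non-positive-definite covariance (constant column?)") from exc
    return cov, chol


class FukunagaKDE:
    """Whitened multivariate normal-kernel density estimator.

    Parameters
    ----------
    data : ndarray, shape (n, d)
    bandwidth : float, optional
        Defaults to the normal-reference rule in this ``d``.
    cov : ndarray (d, d), optional
        Whitening matrix; defaults to the sample covariance (ddof=1).
    """

    def __init__(self, data: np.ndarray, bandwidth: float | None = None, cov: np.ndarray | None = None):
        data = np.asarray(data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        self.data = data
        self.n, self.d = data.shape
        self.cov, self._chol = _whitening(data, cov)
        self.bandwidth = float(bandwidth) if bandwidth is not None else bandwidth_optimal(self.n, self.d)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        # det(S)^(-1/2) from the Cholesky diagonal
        self._sqrt_det = float(np.prod(np.diag(self._chol)))

    def mahalanobis_sq(self, query: np.ndarray) -> np.ndarray:
        """(q - Z_i)' S^-1 (q - Z_i) for every query row and data row; (m, n)."""
        query = np.asarray(query, dtype=float)
        squeeze = query.ndim == 1
        if squeeze:
            query = query[None, :]
        diff = query[:, None, :] - self.data[None, :, :]  # (m, n, d)
        z = linalg.solve_triangular(self._chol, diff.reshape(-1, self.d).T, lower=True)
        u = (z ** 2).sum(axis=0).reshape(query.shape[0], self.n)
        return u[0] if squeeze else u

    def __call__(self, query: np.ndarray):
        """Density estimate at one query point (d-vector) or m points (m, d)."""
        query = np.asarray(query, dtype=float)
        squeeze = query.ndim == 1
        u = self.mahalanobis_sq(query)
        if squeeze:
            u = u[None, :]
        h, d = self.bandwidth, self.d
        kern = (2.0 * np.pi) ** (-d / 2.0) * np.exp(-u / (2.0 * h * h))
        f = kern.sum(axis=1) / (self.n * h ** d * self._sqrt_det)
        return float(f[0]) if squeeze else f


def mv_kde(data: np.ndarray, query: np.ndarray, bandwidth: float | None = None, cov: np.ndarray | None = None):
    """One-shot functional form of :class:`FukunagaKDE`."""
    return FukunagaKDE(data, bandwidth=bandwidth, cov=cov)(query)


def _x_kernel_weights(data: ObservationSet, x0: np.ndarray, bandwidth: float | None):
    """Unnormalized normal-kernel weights K_h(x0 - x_i) on the regressor block.

    Constants cancel in the Nadaraya-Watson ratio, so only exp(-u/(2h^2))
    is returned. ``x0`` may be a single k-vector or an (m, k) array.
    """
    Z = data.regressors
    if Z.shape[1] == 0:
        raise ValueError("conditional estimation needs at least one non-intercept regressor")
    kde = FukunagaKDE(Z, bandwidth=bandwidth)
    u = kde.mahalanobis_sq(np.asarray(x0, dtype=float))
    return np.exp(-u / (2.0 * kde.bandwidth ** 2))


def conditional_cdf(data: ObservationSet, x0, y, bandwidth: float | None = None):
    """Nadaraya-Watson conditional cdf estimate F_hat(y | x0).

    Nondecreasing and right-continuous in ``y``; tends to the marginal
    empirical cdf as the bandwidth grows. ``y`` may be scalar or an array.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    K = _x_kernel_weights(data, x0, bandwidth)
    total = K.sum()
    if not total > 0:
        raise ValueError("all kernel weights vanished at x0; increase the bandwidth")
    y = np.asarray(y, dtype=float)
    ind = data.y[None, :] <= np.atleast_1d(y)[:, None]
    out = np.clip(ind @ K / total, 0.0, 1.0)
    # exact endpoints despite rounding in the weight sum
    out[np.all(ind, axis=1)] = 1.0
    return float(out[0]) if y.ndim == 0 else out


def conditional_quantile(data: ObservationSet, x0, tau: float, bandwidth: float | None = None) -> float:
    """xi_hat(tau | x0) = inf over observed responses y_(j) with
    F_hat(y_(j) | x0) >= tau."""
    tau = validate_tau(tau)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    K = _x_kernel_weights(data, x0, bandwidth)
    total = K.sum()
    if not total > 0:
        raise ValueError("all kernel weights vanished at x0; increase the bandwidth")
    order = np.argsort(data.y, kind="stable")
    csum = np.cumsum(K[order])
    idx = int(np.searchsorted(csum, tau * total, side="left"))
    idx = min(idx, data.n - 1)
    return float(data.y[order][idx])


def density_weights(
    data: ObservationSet,
    tau: float,
    bandwidth_joint: float | None = None,
    bandwidth_marginal: float | None = None,
) -> WeightVector:
    """Kernel estimate of the conditional-density weights
    w_hat_i = f_hat(xi_hat(tau | x_i) | x_i).

    The joint (y, x) density uses dimension k+1 and the marginal x density
    dimension k, each whitened by its own sample covariance and smoothed
    with its own normal-reference bandwidth unless overridden.
    """
    tau = validate_tau(tau)
    if data.n < 10:
        raise ValueError("kernel weight estimation needs at least 10 observations")
    Z = data.regressors
    if Z.shape[1] == 0:
        raise ValueError("density weights need at least one non-intercept regressor")

    # xi_hat at every observed x_i, vectorized over the shared kernel matrix
    kde_x = FukunagaKDE(Z)  # also validates the covariance
    h_x = kde_x.bandwidth
    K = np.exp(-kde_x.mahalanobis_sq(Z) / (2.0 * h_x * h_x))  # (n, n)
    totals = K.sum(axis=1)
    order = np.argsort(data.y, kind="stable")
    csum = np.cumsum(K[:, order], axis=1)
    idx = np.sum(csum < tau * totals[:, None], axis=1)
    idx = np.minimum(idx, data.n - 1)
    xi_hat = data.y[order][idx]

    joint = np.column_stack([data.y, Z])
    kde_joint = FukunagaKDE(joint, bandwidth=bandwidth_joint)
    kde_marg = FukunagaKDE(Z, bandwidth=bandwidth_marginal)
    f_joint = kde_joint(np.column_stack([xi_hat, Z]))
    mu_x = kde_marg(Z)
    w = f_joint / mu_x
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("kernel weight estimation produced non-positive weights")
    return WeightVector(w, kind="density_kde")
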