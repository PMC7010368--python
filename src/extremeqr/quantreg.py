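"""Check-loss (quantile) regression solved as a linear program.

The tau-th regression quantile minimizes the asymmetric absolute ("check"
or "pinball") loss

    sum_i w_i * rho_tau(y_i - x_i' beta),    rho_tau(u) = u (tau - 1{u < 0}),

over beta, for strictly positive weights w_i that do not depend on y. The
problem is linear: writing the residual as u_i - v_i with u_i, v_i >= 0,
the program is

    min  sum_i w_i (tau u_i + (1 - tau) v_i)
    s.t. X beta + u - v = y,   u, v >= 0,   beta free,

and is solved here with the HiGHS simplex/IPM backends via
``scipy.optimize.linprog``. Weights enter the objective multiplicatively,
so the unweighted estimator is the special case w_i = 1 and any positive
rescaling of the weights leaves the minimizer unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .data import ObservationSet, QuantileFit, WeightVector, validate_tau

__all__ = [
    "check_loss",
    "fit_quantile_regression",
    "norm_weights",
    "fit_least_squares",
]

#: objective agreement tolerance for declaring the LP solution optimal
LP_TOL = 1e-9


def check_loss(u, tau: float):
    """Check loss rho_tau(u) = u * (tau - 1{u < 0}), elementwise.

    Nonnegative for all u, zero iff u = 0; at u = 0 the indicator is 0
    (zero residuals count as non-negative).
    """
    tau = validate_tau(tau)
    u = np.asarray(u, dtype=float)
    out = u * (tau - (u < 0))
    return float(out) if out.ndim == 0 else out


def fit_quantile_regression(
    data: ObservationSet,
    tau: float,
    weights: WeightVector | None = None,
) -> QuantileFit:
    """Fit the tau-th (weighted) regression quantile by linear programming.

    Parameters
    ----------
    data : ObservationSet
    tau : float in (0, 1)
    weights : WeightVector, optional
        Per-observation positive weights; uniform if omitted.

    Returns
    -------
    QuantileFit
        ``objective`` is the weighted check loss recomputed from ``beta``;
        ``status`` is ``"optimal"`` or ``"rank_deficient"`` (the LP still
        returns one of the optimal basic solutions in the latter case).

    Raises
    ------
    ValueError
        If n < p or the weights do not match the data.
    RuntimeError
        If the LP solver fails (infeasible/unbounded/numerical).
    """
    tau = validate_tau(tau)
    n, p = data.n, data.p
    if n < p:
        raise ValueError(f"need at least as many observations as regressors (n={n}, p={p})")
    if weights is None:
        weights = WeightVector.uniform(n)
    if len(weights) != n:
        raise ValueError(f"weight vector of length {len(weights)} for {n} observations")
    w = weights.w

    # variables: [beta (p, free), u (n, >=0), v (n, >=0)]
    c = np.concatenate([np.zeros(p), tau * w, (1.0 - tau) * w])
    A_eq = sparse.hstack(
        [sparse.csr_matrix(data.X), sparse.identity(n, format="csr"), -sparse.identity(n, format="csr")],
        format="csr",
    )
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=data.y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile-regression LP failed: {res.message}")

    beta = res.x[:p]
    residuals = data.y - data.X @ beta
    objective = float(np.sum(w * check_loss(residuals, tau)))
    status = "optimal"
    if np.linalg.matrix_rank(data.X) < p:
        status = "rank_deficient"
    return QuantileFit(
        tau=tau,
        beta=beta,
        objective=objective,
        residuals=residuals,
        status=status,
        weight_kind=weights.kind,
    )


def norm_weights(data: ObservationSet, include_intercept: bool = False) -> WeightVector:
    """Inverse-design-norm weights w_i = ||x_i||^-1 / sum_j ||x_j||^-1.

    By default the norm runs over the k non-intercept regressors
    (||x_i|| = sqrt(x_i1^2 + ... + x_ik^2)). With ``include_intercept=True``
    the constant coordinate joins the norm (||x_i|| = sqrt(1 + x_i1^2 + ...)),
    which keeps the weights bounded on designs whose regressors approach
    zero and breaks the proportionality to 1/x_i in single-regressor
    designs. The weights sum to 1.

    Raises
    ------
    ValueError
        If a (non-intercept) regressor row has zero norm; the error names
        the offending rows.
    """
    Z = data.X if include_intercept else data.regressors
    if Z.shape[1] == 0:
        raise ValueError("norm weights need at least one non-intercept regressor")
    norms = np.linalg.norm(Z, axis=1)
    zero_rows = np.flatnonzero(norms == 0.0)
    if zero_rows.size:
        raise ValueError(f"zero-norm regressor row(s) at index {zero_rows.tolist()}")
    inv = 1.0 / norms
    return WeightVector(inv / inv.sum(), kind="norm")


def fit_least_squares(data: ObservationSet) -> np.ndarray:
    """Ordinary least-squares coefficients (the L2 baseline).

    Raises
    ------
    ValueError
        If n < p.
    numpy.linalg.LinAlgError
        If the design is rank deficient.
    """
    if data.n < data.p:
        raise ValueError(f"need n >= p for least squares (n={data.n}, p={data.p})")
    beta, _, rank, _ = np.linalg.lstsq(data.X, data.y, rcond=None)
    if rank < data.p:
        raise np.linalg.LinAlgError(f"rank-deficient design (rank {rank} < p={data.p})")
    return beta
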