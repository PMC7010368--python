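"""Core containers shared across the package.

The regression machinery works on an :class:`ObservationSet` — a response
vector ``y`` paired with a design matrix ``X`` whose first column is the
constant 1 — plus per-observation :class:`WeightVector` objects and the
:class:`QuantileFit` record returned by the solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WEIGHT_KINDS",
    "validate_tau",
    "ObservationSet",
    "WeightVector",
    "QuantileFit",
]

WEIGHT_KINDS = ("uniform", "norm", "density_oracle", "density_kde")

INTERCEPT_NAME = "const"


def validate_tau(tau: float) -> float:
    """Validate a quantile level, returning it as a float.

    Raises
    ------
    ValueError
        If ``tau`` is not strictly between 0 and 1.
    """
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"quantile level must lie in the open interval (0, 1); got {tau}")
    return tau


@dataclass
class ObservationSet:
    """A response vector and a design matrix with a leading intercept column.

    Parameters
    ----------
    y : ndarray, shape (n,)
        Response values.
    X : ndarray, shape (n, p)
        Design matrix; the first column must be identically 1 (intercept).
    columns : tuple of str
        Names for the ``p`` design columns, first entry names the intercept.
    """

    y: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design matrix X must be two-dimensional")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one observation and one regressor column")
        if self.y.shape[0] != n:
            raise ValueError(f"y has length {self.y.shape[0]} but X has {n} rows")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise ValueError("ObservationSet does not admit missing or infinite values")
        if not np.all(self.X[:, 0] == 1.0):
            raise ValueError("first design column must be the constant 1 (intercept)")
        if not self.columns:
            self.columns = (INTERCEPT_NAME,) + tuple(f"x{j}" for j in range(1, p))
        self.columns = tuple(self.columns)
        if len(self.columns) != p:
            raise ValueError(f"{len(self.columns)} column names for {p} design columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        """Number of non-intercept regressors."""
        return self.p - 1

    @property
    def regressors(self) -> np.ndarray:
        """The design matrix without the intercept column, shape (n, k)."""
        return self.X[:, 1:]

    @classmethod
    def from_arrays(cls, x: np.ndarray, y: np.ndarray, names: tuple[str, ...] | None = None) -> "ObservationSet":
        """Build a set from raw regressor column(s) ``x`` and response ``y``,
        prepending the intercept."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        X = np.column_stack([np.ones(x.shape[0]), x])
        cols = (INTERCEPT_NAME,) + tuple(names) if names else ()
        return cls(y=np.asarray(y, dtype=float), X=X, columns=cols)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df.insert(0, "y", self.y)
        return df


@dataclass
class WeightVector:
    """Positive per-observation weights w_i(x_i, tau).

    ``kind`` records provenance: ``uniform`` (all-equal), ``norm``
    (inverse-design-norm, normalized to sum 1), ``density_oracle`` (true
    conditional density at the true conditional quantile, simulations only)
    or ``density_kde`` (kernel estimate of the same quantity).
    """

    w: np.ndarray
    kind: str = "uniform"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).reshape(-1)
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}; expected one of {WEIGHT_KINDS}")
        if self.w.size == 0:
            raise ValueError("empty weight vector")
        if not np.isfinite(self.w).all() or np.any(self.w <= 0):
            raise ValueError("weights must be strictly positive and finite")
        if self.kind == "norm" and not np.isclose(self.w.sum(), 1.0, rtol=0, atol=1e-10):
            raise ValueError("norm weights must sum to 1")

    def __len__(self) -> int:
        return self.w.size

    @classmethod
    def uniform(cls, n: int) -> "WeightVector":
        return cls(np.ones(n), kind="uniform")


@dataclass
class QuantileFit:
    """Result of a (weighted) quantile-regression fit at level tau.

    ``objective`` is the minimized weighted check loss recomputed from
    ``beta``; ``residuals`` are y_i - x_i' beta.
    """

    tau: float
    beta: np.ndarray
    objective: float
    residuals: np.ndarray
    status: str = "optimal"
    weight_kind: str = "uniform"

    def __post_init__(self) -> None:
        self.tau = validate_tau(self.tau)
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.residuals = np.asarray(self.residuals, dtype=float).reshape(-1)
        self.objective = float(self.objective)
        if self.objective < 0:
            raise ValueError("check-loss objective cannot be negative")

    def predict(self, X: np.ndarray):
        """Fitted conditional quantile at design row(s) X; returns a float
        for a single row."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return float(X @ self.beta)
        return X @ self.beta

    def to_record(self) -> dict:
        return {
            "tau": self.tau,
            "beta": self.beta.tolist(),
            "objective": self.objective,
            "weight_kind": self.weight_kind,
            "status": self.status,
        }
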