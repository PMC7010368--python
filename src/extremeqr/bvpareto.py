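"""Bivariate Pareto (Mardia type I) simulator with closed-form truth.

The joint law on (1, inf)^2 with tail index alpha > 0 has cdf

    F(x, y) = 1 - x^-alpha - y^-alpha + (x + y - 1)^-alpha,

Pareto(alpha) margins, conditional density

    f(y | x) = (alpha + 1) x^(alpha+1) / (x + y - 1)^(alpha+2),

and a conditional quantile function that is exactly linear in x:

    xi(tau | x) = 1 + x * ((1 - tau)^(-1/(alpha+1)) - 1).

The conditional density evaluated at the conditional quantile,

    f(xi(tau | x)) = (alpha + 1) (1 - tau)^((alpha+2)/(alpha+1)) / x,

is the "oracle" efficiency weight for weighted quantile regression: it is
the quantity the kernel machinery in :mod:`extremeqr.kde` estimates from
data. Because truth is available in closed form, this model anchors the
Monte Carlo efficiency study in :mod:`extremeqr.benchmark`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ObservationSet, WeightVector, validate_tau

__all__ = ["BivariatePareto"]


@dataclass(frozen=True)
class BivariatePareto:
    """Mardia type I bivariate Pareto with common tail index ``alpha``."""

    alpha: float = 3.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"tail index alpha must be positive; got {self.alpha}")

    # -- closed forms -----------------------------------------------------

    def joint_cdf(self, x, y):
        """F(x, y) on x > 1, y > 1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(x <= 1) or np.any(y <= 1):
            raise ValueError("joint cdf is defined for x > 1 and y > 1")
        a = self.alpha
        out = 1.0 - x ** -a - y ** -a + (x + y - 1.0) ** -a
        return float(out) if out.ndim == 0 else out

    def marginal_cdf(self, x):
        """Pareto margin F(x) = 1 - x^-alpha, x > 1."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 1):
            raise ValueError("marginal cdf is defined for x > 1")
        out = 1.0 - x ** -self.alpha
        return float(out) if out.ndim == 0 else out

    def conditional_pdf(self, y, x):
        """f(y | x) = (alpha+1) x^(alpha+1) / (x + y - 1)^(alpha+2)."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        a = self.alpha
        out = (a + 1.0) * x ** (a + 1.0) / (x + y - 1.0) ** (a + 2.0)
        return float(out) if out.ndim == 0 else out

    def conditional_cdf(self, y, x):
        """F(y | x) = 1 - (x / (x + y - 1))^(alpha+1), the integral of f(.|x)."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        out = 1.0 - (x / (x + y - 1.0)) ** (self.alpha + 1.0)
        return float(out) if out.ndim == 0 else out

    def quantile_slope(self, tau: float) -> float:
        """Slope of the conditional-quantile line: (1-tau)^(-1/(alpha+1)) - 1."""
        tau = validate_tau(tau)
        return (1.0 - tau) ** (-1.0 / (self.alpha + 1.0)) - 1.0

    def true_conditional_quantile(self, tau: float, x):
        """xi(tau | x) = 1 + x * quantile_slope(tau); linear in x, intercept 1."""
        x = np.asarray(x, dtype=float)
        out = 1.0 + x * self.quantile_slope(tau)
        return float(out) if out.ndim == 0 else out

    def conditional_density_at_quantile(self, tau: float, x):
        """f(xi(tau|x)) = (alpha+1)(1-tau)^((alpha+2)/(alpha+1)) / x."""
        tau = validate_tau(tau)
        x = np.asarray(x, dtype=float)
        a = self.alpha
        out = (a + 1.0) * (1.0 - tau) ** ((a + 2.0) / (a + 1.0)) / x
        return float(out) if out.ndim == 0 else out

    # -- sampling ---------------------------------------------------------

    def sample(self, n: int, seed=None) -> ObservationSet:
        """Draw n pairs by inverse-cdf composition: X from the Pareto margin,
        then Y from the conditional law given X.

        X = (1 - U1)^(-1/alpha);  Y = 1 + X ((1 - U2)^(-1/(alpha+1)) - 1),

        with U1, U2 independent uniforms from one seeded generator.
        Deterministic given ``seed`` (an int or a numpy Generator).
        """
        if n < 1:
            raise ValueError("need n >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        a = self.alpha
        u1 = rng.random(n)
        u2 = rng.random(n)
        x = (1.0 - u1) ** (-1.0 / a)
        y = 1.0 + x * ((1.0 - u2) ** (-1.0 / (a + 1.0)) - 1.0)
        return ObservationSet.from_arrays(x, y, names=("x",))

    def oracle_weights(self, data: ObservationSet, tau: float) -> WeightVector:
        """Eq-true efficiency weights w_i = f(xi(tau | x_i)) for a
        single-regressor ObservationSet drawn from this model."""
        if data.k != 1:
            raise ValueError("oracle weights are defined for the single-regressor design")
        x = data.regressors[:, 0]
        w = self.conditional_density_at_quantile(tau, x)
        return WeightVector(w, kind="density_oracle")
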