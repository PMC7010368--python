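"""Shared fixtures and independent test oracles."""

from itertools import combinations

import numpy as np
import pytest

from extremeqr import BivariatePareto, ObservationSet
from extremeqr.quantreg import check_loss


def brute_force_quantreg(data: ObservationSet, tau: float, weights=None):
    """Independent oracle for the check-loss minimum: enumerate every
    p-point interpolating line/plane (quantile-regression optima occur at
    basic solutions) and return (best objective, best beta)."""
    w = np.ones(data.n) if weights is None else weights.w
    best_obj, best_beta = np.inf, None
    for idx in combinations(range(data.n), data.p):
        Xs = data.X[list(idx)]
        if abs(np.linalg.det(Xs)) < 1e-10:
            continue
        beta = np.linalg.solve(Xs, data.y[list(idx)])
        obj = float(np.sum(w * check_loss(data.y - data.X @ beta, tau)))
        if obj < best_obj:
            best_obj, best_beta = obj, beta
    return best_obj, best_beta


@pytest.fixture(scope="session")
def pareto_model():
    return BivariatePareto(3.0)


@pytest.fixture(scope="session")
def pareto_sample_500(pareto_model):
    """One seeded alpha=3 sample of size 500, reused by the KDE tests."""
    return pareto_model.sample(500, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
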