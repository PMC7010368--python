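"""Check-loss regression: LP solver, weights, and the L2 baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from extremeqr import ObservationSet, WeightVector
from extremeqr.quantreg import (
    check_loss,
    fit_least_squares,
    fit_quantile_regression,
    norm_weights,
)

from conftest import brute_force_quantreg


# -- check loss ------------------------------------------------------------


@pytest.mark.parametrize(
    "u, tau, expected",
    [(2.0, 0.95, 1.9), (-2.0, 0.95, 0.1), (0.0, 0.3, 0.0), (0.0, 0.9, 0.0)],
)
def test_check_loss_branches(u, tau, expected):
    assert check_loss(u, tau) == pytest.approx(expected, abs=1e-15)


def test_check_loss_rejects_bad_tau():
    for tau in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            check_loss(1.0, tau)


@settings(deadline=None, derandomize=True)
@given(
    u=st.floats(-1e6, 1e6, allow_nan=False),
    tau=st.floats(0.01, 0.99),
)
def test_check_loss_nonnegative_and_zero_iff_zero(u, tau):
    val = check_loss(u, tau)
    assert val >= 0.0
    assert (val == 0.0) == (u == 0.0)


# -- quantile regression LP ------------------------------------------------


def _toy(x, y):
    return ObservationSet.from_arrays(np.asarray(x, float), np.asarray(y, float))


def test_two_point_interpolation():
    fit = fit_quantile_regression(_toy([0, 1], [0, 1]), 0.5)
    assert fit.beta == pytest.approx([0.0, 1.0], abs=1e-9)
    assert fit.objective == pytest.approx(0.0, abs=1e-9)


def test_three_point_fit_matches_enumeration_oracle():
    data = _toy([1, 2, 3], [1, 2, 10])
    fit = fit_quantile_regression(data, 0.5)
    best_obj, best_beta = brute_force_quantreg(data, 0.5)
    assert fit.objective == pytest.approx(best_obj, abs=1e-9)
    assert fit.beta == pytest.approx(best_beta, abs=1e-8)


def test_constant_weight_rescaling_leaves_fit_unchanged(rng):
    x = rng.normal(size=25)
    y = 1.0 + 2.0 * x + rng.standard_t(3, size=25)
    data = _toy(x, y)
    base = fit_quantile_regression(data, 0.7)
    scaled = fit_quantile_regression(
        data, 0.7, weights=WeightVector(np.full(25, 7.5), kind="uniform")
    )
    assert scaled.beta == pytest.approx(base.beta, abs=1e-8)
    assert scaled.objective == pytest.approx(7.5 * base.objective, rel=1e-9)


def test_objective_equals_recomputed_weighted_check_loss(rng):
    x = rng.normal(size=40)
    y = rng.standard_t(2, size=40)
    data = _toy(x, y)
    w = WeightVector(rng.uniform(0.5, 2.0, size=40), kind="density_oracle")
    fit = fit_quantile_regression(data, 0.9, weights=w)
    recomputed = float(np.sum(w.w * check_loss(data.y - data.X @ fit.beta, 0.9)))
    assert fit.objective == pytest.approx(recomputed, rel=1e-12)
    assert fit.residuals == pytest.approx(data.y - data.X @ fit.beta)


def test_lp_objective_matches_enumeration_on_random_instances(rng):
    """Spot check of basic-solution optimality on small random designs."""
    for _ in range(30):
        n = int(rng.integers(4, 13))
        p = int(rng.integers(2, 4))
        x = rng.normal(size=(n, p - 1))
        y = rng.standard_t(3, size=n)
        data = ObservationSet.from_arrays(x, y)
        tau = float(rng.uniform(0.1, 0.9))
        fit = fit_quantile_regression(data, tau)
        best_obj, _ = brute_force_quantreg(data, tau)
        assert fit.objective == pytest.approx(best_obj, abs=1e-8)


def test_weighted_subgradient_condition(rng):
    """At the optimum, each design column's weighted subgradient must be
    coverable by the zero-residual points."""
    x = rng.normal(size=60)
    y = 2 + x + rng.gumbel(size=60)
    data = _toy(x, y)
    tau = 0.8
    w = WeightVector(rng.uniform(0.5, 2.0, size=60), kind="density_oracle")
    fit = fit_quantile_regression(data, tau, weights=w)
    at_zero = np.abs(fit.residuals) < 1e-8
    grad = (tau - (fit.residuals < 0)) * ~at_zero
    for j in range(data.p):
        lhs = abs(np.sum(w.w * grad * data.X[:, j]))
        rhs = np.sum(w.w[at_zero] * max(tau, 1 - tau) * np.abs(data.X[at_zero, j])) + 1e-7
        assert lhs <= rhs


def test_scale_and_shift_equivariance(rng):
    x = rng.normal(size=30)
    y = 1 + 2 * x + rng.standard_t(4, size=30)
    data = _toy(x, y)
    fit = fit_quantile_regression(data, 0.6)
    # response scaling
    scaled = fit_quantile_regression(_toy(x, 3.5 * y), 0.6)
    assert scaled.beta == pytest.approx(3.5 * fit.beta, abs=1e-7)
    # regressor shift: intercept absorbs -a * slope, slope unchanged
    shifted = fit_quantile_regression(_toy(x + 2.0, y), 0.6)
    assert shifted.beta[1] == pytest.approx(fit.beta[1], abs=1e-7)
    assert shifted.beta[0] == pytest.approx(fit.beta[0] - 2.0 * fit.beta[1], abs=1e-7)


def test_quantile_coverage_bounds(rng):
    """Fraction of strictly negative residuals <= tau <= fraction of
    non-positive residuals, up to the <= p interpolated points."""
    n = 400
    x = rng.normal(size=n)
    y = x + rng.standard_t(3, size=n)
    data = _toy(x, y)
    for tau in (0.25, 0.5, 0.9, 0.95):
        fit = fit_quantile_regression(data, tau)
        neg = np.mean(fit.residuals < -1e-9)
        nonpos = np.mean(fit.residuals <= 1e-9)
        assert neg <= tau + 1e-12
        assert nonpos >= tau - 1e-12


def test_matches_statsmodels_where_it_converges(rng):
    sm = pytest.importorskip("statsmodels.api")
    x = rng.normal(size=200)
    y = 1 + x + rng.standard_t(3, size=200)
    data = _toy(x, y)
    for tau in (0.5, 0.9):
        ours = fit_quantile_regression(data, tau)
        theirs = sm.QuantReg(data.y, data.X).fit(q=tau)
        obj_theirs = float(np.sum(check_loss(data.y - data.X @ theirs.params, tau)))
        # the LP optimum can only be at least as good as IRLS
        assert ours.objective <= obj_theirs + 1e-6
        assert ours.beta == pytest.approx(theirs.params, abs=5e-3)


def test_underdetermined_design_raises():
    data = _toy([1.0], [1.0])  # n=1 < p=2
    with pytest.raises(ValueError):
        fit_quantile_regression(data, 0.5)


def test_rank_deficient_design_is_flagged():
    X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
    data = ObservationSet(y=np.arange(6.0), X=X)
    fit = fit_quantile_regression(data, 0.5)
    assert fit.status == "rank_deficient"


# -- norm weights ----------------------------------------------------------


def test_norm_weights_symmetric_pair():
    w = norm_weights(_toy([2, 2], [0, 0]))
    assert w.w == pytest.approx([0.5, 0.5])
    assert w.kind == "norm"


def test_norm_weights_direct_arithmetic():
    # 1/1 and 1/3 normalized
    w = norm_weights(_toy([1, 3], [0, 0]))
    assert w.w == pytest.approx([0.75, 0.25])


def test_norm_weights_sum_to_one(rng):
    x = rng.uniform(0.5, 4.0, size=(15, 2))
    w = norm_weights(ObservationSet.from_arrays(x, np.zeros(15)))
    assert w.w.sum() == pytest.approx(1.0, abs=1e-12)


def test_norm_weights_zero_row_names_offender():
    with pytest.raises(ValueError, match=r"\[1\]"):
        norm_weights(_toy([2.0, 0.0, 1.0], [0, 0, 0]))


def test_norm_weights_intercept_inclusion_changes_norm():
    w = norm_weights(_toy([1, 3], [0, 0]), include_intercept=True)
    inv = 1.0 / np.sqrt([2.0, 10.0])
    assert w.w == pytest.approx(inv / inv.sum())


# -- least squares ---------------------------------------------------------


def test_least_squares_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    beta = fit_least_squares(_toy(x, 2 + 3 * x))
    assert beta == pytest.approx([2.0, 3.0], abs=1e-10)


def test_least_squares_hand_computed_normal_equations():
    beta = fit_least_squares(_toy([0, 1, 2], [0, 1, 0]))
    assert beta == pytest.approx([1.0 / 3.0, 0.0], abs=1e-12)


def test_least_squares_residual_orthogonality(rng):
    x = rng.normal(size=(20, 2))
    y = rng.normal(size=20)
    data = ObservationSet.from_arrays(x, y)
    beta = fit_least_squares(data)
    resid = data.y - data.X @ beta
    assert data.X.T @ resid == pytest.approx(np.zeros(3), abs=1e-9)


def test_least_squares_rank_deficiency_raises():
    X = np.column_stack([np.ones(5), np.arange(5.0), 3 * np.arange(5.0)])
    data = ObservationSet(y=np.arange(5.0), X=X)
    with pytest.raises(np.linalg.LinAlgError):
        fit_least_squares(data)
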