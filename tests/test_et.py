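"""Unit and property tests for the ET likelihood engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from petlik.et import (
    ETObjective,
    et_estimate,
    et_weights,
    inner_lambda_solve,
    log_et_ratio,
    score_lambda,
)
from petlik.missing import StackedMomentSystem
from petlik.models import LinearIVModel

finite_floats = st.floats(-3, 3, allow_nan=False)


@pytest.mark.parametrize(
    "lam, G, expected",
    [
        (np.zeros(2), np.random.default_rng(0).normal(size=(4, 2)), np.full(4, 0.25)),
        (np.array([2.0]), np.array([[1.3]]), np.array([1.0])),
        (np.array([1.0]), np.array([[0.0], [np.log(3)]]), np.array([0.25, 0.75])),
    ],
)
def test_et_weights_examples(lam, G, expected):
    np.testing.assert_allclose(et_weights(lam, G), expected, atol=1e-12)


def test_et_weights_rejects_nonfinite():
    with pytest.raises(ValueError):
        et_weights(np.array([np.nan]), np.ones((2, 1)))


@pytest.mark.parametrize(
    "lam, G, expected",
    [
        (np.zeros(3), np.random.default_rng(1).normal(size=(5, 3)), 0.0),
        (np.array([1.0]), np.zeros((2, 1)), 0.0),
        (np.array([1.0]), np.array([[np.log(2)], [np.log(4)]]), np.log(3)),
    ],
)
def test_log_et_ratio_examples(lam, G, expected):
    assert log_et_ratio(lam, G) == pytest.approx(expected, abs=1e-12)


def test_score_lambda_examples():
    G = np.random.default_rng(2).normal(size=(6, 2))
    np.testing.assert_allclose(score_lambda(np.zeros(2), G), G.mean(axis=0))
    assert np.allclose(score_lambda(np.ones(3), np.zeros((4, 3))), 0.0)


def test_score_lambda_matches_finite_difference():
    rng = np.random.default_rng(3)
    G = rng.normal(size=(8, 2))
    lam = np.array([0.3, -0.2])
    # U_n1 is the gradient of f(lam) = mean exp(lam'G_i)
    f = lambda l: np.mean(np.exp(G @ l))
    for j in range(2):
        e = np.zeros(2)
        e[j] = 1e-6
        fd = (f(lam + e) - f(lam - e)) / 2e-6
        assert score_lambda(lam, G)[j] == pytest.approx(fd, abs=1e-6)


def test_inner_solve_symmetric_zero():
    G = np.array([[1.0], [-1.0], [2.0], [-2.0]])
    res = inner_lambda_solve(G)
    assert res.converged
    assert res.lam == pytest.approx(0.0, abs=1e-8)


def test_inner_solve_never_above_origin(benign_system):
    theta = benign_system.theta_init()
    G = benign_system.moments(theta)
    res = inner_lambda_solve(G)
    assert log_et_ratio(res.lam, G) <= 1e-12


def test_inner_solve_matches_bisection_oracle():
    rng = np.random.default_rng(5)
    G = (rng.normal(size=50) + 0.4)[:, None]
    res = inner_lambda_solve(G, tol=1e-12)
    # 1-D oracle: bisect U_n1(lam) = mean exp(lam g) g on a bracket
    un1 = lambda l: float(np.mean(np.exp(G[:, 0] * l) * G[:, 0]))
    lo, hi = -10.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if un1(mid) > 0:
            hi = mid
        else:
            lo = mid
    assert res.lam[0] == pytest.approx(0.5 * (lo + hi), abs=1e-5)
    assert res.max_score < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    G=hnp.arrays(float, (7, 2), elements=finite_floats),
    lam=hnp.arrays(float, (2,), elements=finite_floats),
)
def test_weights_sum_to_one_and_nonnegative(G, lam):
    w = et_weights(lam, G)
    assert np.all(w >= 0)
    assert w.sum() == pytest.approx(1.0, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    G=hnp.arrays(float, (9, 2), elements=finite_floats),
    lam1=hnp.arrays(float, (2,), elements=finite_floats),
    lam2=hnp.arrays(float, (2,), elements=finite_floats),
)
def test_log_ratio_convex_in_lambda(G, lam1, lam2):
    mid = log_et_ratio(0.5 * (lam1 + lam2), G)
    avg = 0.5 * (log_et_ratio(lam1, G) + log_et_ratio(lam2, G))
    assert mid <= avg + 1e-8


class _PlainMomentSystem:
    """A moment system made of the outcome moments alone (no propensity)."""

    def __init__(self, dataset, model):
        self.model = model
        self.Y, self.U, self.Z = dataset.Y, dataset.U, dataset.Z
        self.n = dataset.n
        self.t = model.r
        self.s = model.p

    def moments(self, theta):
        return self.model.g(self.Y, self.U, self.Z, theta)

    def jacobian(self, theta):
        return self.model.dg(self.Y, self.U, self.Z, theta)


def test_et_estimate_just_identified_matches_normal_equations(benign_complete):
    """Fully observed, just-identified linear moments: the ET estimate is the
    least-squares root of the moment equations and the multiplier vanishes."""
    model = LinearIVModel(3, 3)
    system = _PlainMomentSystem(benign_complete, model)
    fit = et_estimate(system, np.zeros(model.p))
    D = np.hstack([np.ones((benign_complete.n, 1)), benign_complete.U, benign_complete.Z])
    beta_ls, *_ = np.linalg.lstsq(D, benign_complete.Y, rcond=None)
    np.testing.assert_allclose(fit.theta, beta_ls, atol=1e-6)
    assert np.max(np.abs(fit.lam)) < 1e-6
    assert fit.log_ratio == pytest.approx(0.0, abs=1e-10)
    assert fit.converged


def test_et_estimate_consistency_with_n():
    from tests.conftest import make_benign_linear

    errs = []
    for n in (300, 2000):
        ds = make_benign_linear(n, 2, seed=42)
        model = LinearIVModel(2, 2)
        system = StackedMomentSystem(ds, model)
        fit = et_estimate(system, system.theta_init())
        errs.append(np.max(np.abs(fit.theta[:5] - ds.meta["true_beta"])))
    assert errs[1] < errs[0]
    assert errs[1] < 0.15


def test_et_estimate_single_observation_root():
    from petlik.missing import MissingDataset

    ds = MissingDataset(Y=np.array([2.0]), U=np.zeros((1, 0)), Z=np.ones((1, 1)),
                        delta=np.array([1]))
    model = LinearIVModel(0, 1)
    system = _PlainMomentSystem(ds, model)
    fit = et_estimate(system, np.zeros(model.p))
    # residual 2 - (bc + bz) must vanish at the single-atom root
    assert fit.theta[0] + fit.theta[1] == pytest.approx(2.0, abs=1e-6)


def test_envelope_gradient_matches_finite_difference(benign_system):
    obj = ETObjective(benign_system, inner_tol=1e-12, value_tol=1e-12)
    theta = benign_system.theta_init() + 0.05
    _, grad, _, _ = obj.value_grad_curv(theta)
    for j in (0, 3, benign_system.p):  # a beta coord, another, a gamma coord
        e = np.zeros(benign_system.s)
        e[j] = 1e-6
        fd = (obj.value(theta + e) - obj.value(theta - e)) / 2e-6
        assert grad[j] == pytest.approx(fd, abs=2e-5)
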