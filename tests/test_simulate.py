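"""Generators, summary metrics and the replication harness."""

import numpy as np
import pytest

from petlik.simulate import (
    ExperimentConfig,
    accuracy_metrics,
    gen_experiment1,
    gen_experiment2,
    gen_experiment3,
    rep_rng,
    run_replications,
    selection_metrics,
    sem_sample_size,
)


def test_generator_determinism():
    a = gen_experiment1(100, 6, seed=4)
    b = gen_experiment1(100, 6, seed=4)
    np.testing.assert_array_equal(np.nan_to_num(a.Y), np.nan_to_num(b.Y))
    np.testing.assert_array_equal(a.delta, b.delta)
    np.testing.assert_array_equal(a.Z, b.Z)


def test_exp1_instrument_correlation_structure():
    ds = gen_experiment1(100000, 8, seed=5)
    corr = np.corrcoef(ds.Z.T)
    k = np.arange(4)
    target = 0.5 ** np.abs(k[:, None] - k[None, :])
    np.testing.assert_allclose(corr, target, atol=0.02)


def test_exp1_observed_fraction_matches_mechanism():
    from scipy.special import expit

    ds = gen_experiment1(100000, 8, mechanism="M1", seed=6)
    lp = ds.meta["true_gamma"][0] + ds.U @ ds.meta["true_gamma"][1:]
    assert ds.delta.mean() == pytest.approx(expit(lp).mean(), abs=0.01)


def test_exp2_u_variance():
    ds = gen_experiment2(100000, 8, seed=7)
    v = ds.U.var(axis=0)
    np.testing.assert_allclose(v, 101.0, rtol=0.05)


def test_exp2_response_rate():
    from scipy.special import expit

    ds = gen_experiment2(100000, 8, seed=8)
    beta0 = ds.meta["true_beta"]
    pr = expit(beta0[0] + ds.Z @ beta0[1:])
    y = np.nan_to_num(ds.Y)[ds.delta == 1]
    # compare against the population mean (selection is independent of Y|Z)
    assert y.mean() == pytest.approx(pr.mean(), abs=0.02)


@pytest.mark.parametrize("p, n", [(8, 117), (32, 241), (72, 602)])
def test_sem_sample_size_formula(p, n):
    assert sem_sample_size(p) == n


def test_sem_generator_dimensions():
    ds = gen_experiment3(2, 1, seed=9)
    assert ds.n == 117
    assert ds.Y.shape == (117, 4)
    assert ds.meta["true_B"].shape == (4, 2)
    assert np.sum(ds.meta["true_B"] != 0) == 3   # |j1 - j2| = 1 pattern


def test_sem_loading_pattern_f4():
    B = gen_experiment3(4, 2, n=10, seed=0).meta["true_B"]
    idx = {(j1, j2) for j1, j2 in zip(*np.nonzero(B))}
    expected = {(j1, j2) for j1 in range(8) for j2 in range(4) if abs(j1 - j2) == 1}
    assert idx == expected
    assert len(idx) == 7


def test_selection_metrics_hand_count():
    truth = np.array([1.0, 0.5, 0.0, 0.0])
    hats = np.array([
        [1.0, 0.4, 0.0, 0.0],    # CF
        [1.1, 0.0, 0.0, 0.0],    # OF: a signal zeroed, all zeros correct
        [0.9, 0.6, 0.2, 0.0],    # UF: one true zero kept
    ])
    m = selection_metrics(hats, truth)
    assert m["tp"] == pytest.approx((2 + 2 + 1) / 3)
    assert m["fp"] == pytest.approx((0 + 1 + 0) / 3)
    assert m["uf"] == pytest.approx(1 / 3)
    assert m["cf"] == pytest.approx(1 / 3)
    assert m["of"] == pytest.approx(1 / 3)
    assert m["uf"] + m["cf"] + m["of"] == pytest.approx(1.0, abs=1e-10)


def test_selection_metrics_perfect_recovery():
    truth = np.array([1.0, 0.0, 0.0])
    hats = np.tile([1.0, 0.0, 0.0], (5, 1))
    m = selection_metrics(hats, truth)
    assert m["tp"] == 2.0 and m["fp"] == 0.0 and m["cf"] == 1.0


def test_accuracy_metrics_hand_example():
    m = accuracy_metrics(np.array([[0.0], [2.0]]), np.array([0.0]))
    assert m["bias"][0] == pytest.approx(1.0)
    assert m["sd"][0] == pytest.approx(1.0)
    assert m["rmse"][0] == pytest.approx(np.sqrt(2.0))


def test_rmse_identity():
    rng = np.random.default_rng(10)
    hats = rng.normal(size=(40, 3)) + np.array([1.0, 0.0, -2.0])
    m = accuracy_metrics(hats, np.array([1.0, 0.0, -2.0]))
    np.testing.assert_allclose(m["rmse"] ** 2, m["bias"] ** 2 + m["sd"] ** 2, atol=1e-10)


def test_all_exact_estimates_give_zero_metrics():
    truth = np.array([0.3, -0.2])
    m = accuracy_metrics(np.tile(truth, (4, 1)), truth)
    for k in ("bias", "sd", "rmse"):
        np.testing.assert_allclose(m[k], 0.0, atol=1e-14)


def test_rep_rng_counter_scheme_independent_streams():
    a = rep_rng(3, 0).standard_normal(4)
    b = rep_rng(3, 1).standard_normal(4)
    a2 = rep_rng(3, 0).standard_normal(4)
    assert not np.allclose(a, b)
    np.testing.assert_array_equal(a, a2)


@pytest.fixture(scope="module")
def tiny_summary():
    cfg = ExperimentConfig(experiment="exp1_linear", n=120, p=6, q=3, reps=4,
                           seed=2, grid_num=5)
    return cfg, run_replications(cfg)


def test_harness_partition_identity(tiny_summary):
    _, s = tiny_summary
    for block in (s.beta_selection, s.gamma_selection):
        assert block["uf"] + block["cf"] + block["of"] == pytest.approx(1.0, abs=1e-10)


def test_harness_seed_stability_across_worker_counts():
    base = ExperimentConfig(experiment="exp1_linear", n=120, p=6, q=3, reps=3,
                            seed=13, grid_num=4)
    s1 = run_replications(base)
    base2 = ExperimentConfig(experiment="exp1_linear", n=120, p=6, q=3, reps=3,
                             seed=13, grid_num=4, n_jobs=2)
    s2 = run_replications(base2)
    np.testing.assert_allclose(s1.beta_accuracy["rmse"], s2.beta_accuracy["rmse"], atol=1e-12)
    assert s1.beta_selection == s2.beta_selection


def test_single_rep_summary_equals_single_fit(tiny_summary):
    cfg, _ = tiny_summary
    one = ExperimentConfig(**{**cfg.__dict__, "reps": 1})
    s = run_replications(one)
    assert s.reps_used == 1
    assert s.beta_accuracy["sd"] == pytest.approx(0.0, abs=1e-12)


def test_mechanism_misspecification_robustness():
    """Correct-fitting rates under a misspecified mechanism stay within 0.2
    of the correctly specified one (desk scale: n = 200, 80 replications)."""
    cfs = {}
    for mech in ("M1", "M3"):
        cfg = ExperimentConfig(experiment="exp1_linear", n=200, p=16, q=8,
                               mechanism=mech, reps=80, seed=17, grid_num=8)
        cfs[mech] = run_replications(cfg).beta_selection["cf"]
    assert abs(cfs["M3"] - cfs["M1"]) <= 0.2
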