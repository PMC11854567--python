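"""Penalty families, LQA fitting and BIC tuning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petlik.et import ETObjective, et_estimate
from petlik.fit import make_block_penalties, penalized_et_fit
from petlik.missing import StackedMomentSystem
from petlik.models import LinearIVModel
from petlik.penalties import (
    bic_select,
    lqa_weight,
    penalized_et_estimate,
    penalty_deriv,
    penalty_value,
)
from tests.conftest import make_benign_linear

A = 3.7


@pytest.mark.parametrize("family", ["scad", "lasso"])
def test_penalty_zero_at_origin(family):
    assert penalty_value(family, 0.0, nu=0.3) == 0.0


def test_lasso_value():
    assert penalty_value("lasso", 0.5, nu=0.2) == pytest.approx(0.1)


def test_scad_tail_constant():
    nu = 0.2
    tail = nu ** 2 * (A + 1) / 2
    assert penalty_value("scad", A * nu, nu=nu) == pytest.approx(tail, abs=1e-12)
    assert penalty_value("scad", 10.0, nu=nu) == pytest.approx(tail, abs=1e-12)
    # tail value equals the integral of the derivative
    xs = np.linspace(0, A * nu, 20001)
    integral = np.trapezoid(penalty_deriv("scad", xs, nu=nu), xs)
    assert integral == pytest.approx(tail, rel=1e-6)


@pytest.mark.parametrize(
    "x, expected",
    [(0.1, 0.2), (0.2, 0.2), (0.5, (A * 0.2 - 0.5) / (A - 1)), (A * 0.2 + 0.01, 0.0), (5.0, 0.0)],
)
def test_scad_deriv_pieces(x, expected):
    assert penalty_deriv("scad", x, nu=0.2) == pytest.approx(expected, abs=1e-12)


def test_penalty_deriv_matches_finite_difference():
    nu = 0.31
    for family in ("scad", "lasso"):
        for x in (0.05, 0.2, 0.5, 0.9, 2.0):
            if family == "scad" and (abs(x - nu) < 1e-3 or abs(x - A * nu) < 1e-3):
                continue
            fd = (penalty_value(family, x + 1e-7, nu=nu) - penalty_value(family, x - 1e-7, nu=nu)) / 2e-7
            assert penalty_deriv(family, x, nu=nu) == pytest.approx(fd, abs=1e-6)


def test_scad_continuity_at_knots():
    nu = 0.37
    for knot in (nu, A * nu):
        lo = penalty_value("scad", knot - 1e-9, nu=nu)
        hi = penalty_value("scad", knot + 1e-9, nu=nu)
        assert hi - lo == pytest.approx(0.0, abs=1e-8)
        dlo = penalty_deriv("scad", knot - 1e-9, nu=nu)
        dhi = penalty_deriv("scad", knot + 1e-9, nu=nu)
        assert dhi - dlo == pytest.approx(0.0, abs=1e-6)


def test_negative_argument_rejected():
    with pytest.raises(ValueError):
        penalty_value("scad", -0.1, nu=0.2)


@pytest.mark.parametrize(
    "family, theta, nu, expected",
    [
        ("lasso", 0.5, 0.2, 0.4),
        ("scad", 2.0, 0.2, 0.0),          # beyond a*nu: flat tail
        ("scad", 0.2, 0.2, 1.0),          # at the knot: pdot = nu, weight 1
    ],
)
def test_lqa_weight_examples(family, theta, nu, expected):
    assert lqa_weight(family, theta, nu) == pytest.approx(expected, abs=1e-12)


def test_lqa_weight_below_floor_is_a_deletion():
    with pytest.raises(ValueError):
        lqa_weight("scad", 1e-5, 0.2)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(x1=st.floats(0, 3), x2=st.floats(0, 3), nu=st.floats(0.01, 1.0))
def test_penalty_nondecreasing(x1, x2, nu):
    lo, hi = sorted((x1, x2))
    for family in ("scad", "lasso"):
        assert penalty_value(family, lo, nu=nu) <= penalty_value(family, hi, nu=nu) + 1e-12


def _system(seed=0, n=150, q=3):
    ds = make_benign_linear(n, q, seed=seed)
    model = LinearIVModel(q, q)
    return ds, StackedMomentSystem(ds, model)


def test_zero_penalty_reproduces_et_estimate():
    _, system = _system(seed=1)
    dense = et_estimate(system, system.theta_init())
    obj = ETObjective(system)
    pens = make_block_penalties(system.s, system.p, "scad", 0.0, 0.0,
                                unpenalized=(0, system.p))
    fit = penalized_et_estimate(obj, dense.theta, pens)
    np.testing.assert_allclose(fit.theta, dense.theta, atol=1e-6)


def test_dominant_penalty_zeroes_all_slopes():
    _, system = _system(seed=2)
    dense = et_estimate(system, system.theta_init())
    obj = ETObjective(system)
    pens = make_block_penalties(system.s, system.p, "scad", 50.0, 50.0,
                                unpenalized=(0, system.p))
    fit = penalized_et_estimate(obj, dense.theta, pens)
    slopes = np.delete(fit.theta, [0, system.p])
    assert np.all(slopes == 0.0)


def test_bic_single_point_grid_returns_it():
    ds, system = _system(seed=3)
    model = LinearIVModel(3, 3)
    res = penalized_et_fit(ds, model, grids=([0.12], [0.3]), standardize=False)
    assert res.fit.nu == (0.12, 0.3)


def test_bic_minimum_matches_brute_force_recomputation():
    _, system = _system(seed=4)
    dense = et_estimate(system, system.theta_init())
    obj = ETObjective(system)

    def make_pens(nu1, nu2):
        return make_block_penalties(system.s, system.p, "scad", nu1, nu2,
                                    unpenalized=(0, system.p))

    grid = np.array([0.05, 0.15, 0.4])
    sel = bic_select(obj, dense.theta, make_pens, grid, grid, n=system.n, s=system.s,
                     strategy="product", warm_paths=False, backward_polish=False)
    best_from_table = min(sel.table, key=lambda r: r[2])
    assert sel.fit.bic <= best_from_table[2] + 1e-9


def test_tie_broken_toward_larger_nu():
    """Two penalty levels yielding identical fits: the sparser (larger nu)
    wins.  Very large nus both give the intercept-only fit."""
    ds, system = _system(seed=5)
    model = LinearIVModel(3, 3)
    res = penalized_et_fit(ds, model, grids=([5.0, 10.0], [5.0, 10.0]),
                           strategy="product", standardize=False, backward_polish=False)
    assert res.fit.nu[0] == pytest.approx(10.0)


def test_monotone_sparsity_on_orthogonal_design():
    """Support size is nonincreasing in nu for an orthogonal complete-data
    linear design (no LQA path instabilities there)."""
    rng = np.random.default_rng(6)
    n = 200
    Z = rng.standard_normal((n, 4))
    Z = np.linalg.qr(Z)[0] * np.sqrt(n)     # orthonormal columns * sqrt(n)
    U = rng.standard_normal((n, 1))
    from petlik.missing import MissingDataset

    beta = np.array([0.0, 0.0, 0.8, 0.4, 0.0, 0.0])  # intercept, u1, z1..z4
    X = np.hstack([U, Z])
    Y = beta[0] + X @ beta[1:] + 0.5 * rng.standard_normal(n)
    ds = MissingDataset(Y=Y, U=U, Z=Z, delta=np.ones(n, dtype=int))
    model = LinearIVModel(1, 4)
    system = StackedMomentSystem(ds, model)
    dense = et_estimate(system, system.theta_init())
    obj = ETObjective(system)
    sizes = []
    for nu in (0.02, 0.1, 0.3, 1.0):
        pens = make_block_penalties(system.s, system.p, "scad", nu, nu,
                                    unpenalized=(0, system.p))
        fit = penalized_et_estimate(obj, dense.theta, pens)
        sizes.append(fit.support.size)
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
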