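"""Constrained penalized ET likelihood ratio tests and confidence intervals.

For a contrast hypothesis H0: Cn theta = c (Cn with orthonormal rows,
e = rank(Cn) fixed), the test statistic is

    ltilde(Cn) = 2 n [ lpn(theta_hat) - max_{Cn theta = c} lpn(theta) ]

with lpn the penalized profiled ET objective, both optimisations run at the
penalty levels tuned on the unconstrained problem.  The scaled statistic
ltilde * M is referred to the chi-squared distribution with e degrees of
freedom.  The scaling M compares the model-implied curvature covariance of
the contrast with its sandwich covariance (they coincide for correctly
specified moment systems, where M -> 1); when it cannot be estimated stably
M falls back to 1 with a warning.

Confidence intervals for scalar contrasts invert the scaled statistic by
bracketed root finding on the profile; a Wald interval from the sandwich
covariance is the documented fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .penalties import CoordinatePenalties, PenalizedFit, penalized_et_estimate

__all__ = [
    "ContrastTest",
    "SandwichCov",
    "constrained_pet_estimate",
    "pet_lr_statistic",
    "scaling_factor",
    "confidence_interval",
    "wald_sandwich",
]


@dataclass
class ContrastTest:
    Cn: np.ndarray
    statistic: float          # ltilde(Cn), unscaled
    scaling: float            # M
    df: int
    p_value: float
    method: str = "lr_scaled"
    constrained: PenalizedFit | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def scaled_statistic(self) -> float:
        return self.statistic * self.scaling


@dataclass
class SandwichCov:
    delta: np.ndarray
    omega: np.ndarray
    cov: np.ndarray            # s x s, zero off the evaluated coordinate set
    se: np.ndarray             # length s, NaN off the evaluated set
    idx: np.ndarray


def _check_contrast(Cn: np.ndarray, s: int) -> np.ndarray:
    Cn = np.atleast_2d(np.asarray(Cn, dtype=float))
    e = Cn.shape[0]
    if Cn.shape[1] != s:
        raise ValueError(f"contrast has {Cn.shape[1]} columns, expected {s}")
    if e >= s:
        raise ValueError("contrast rank must be smaller than the parameter dimension")
    if not np.allclose(Cn @ Cn.T, np.eye(e), atol=1e-8):
        raise ValueError("contrast rows must be orthonormal (Cn Cn' = I)")
    return Cn


def constrained_pet_estimate(
    objective,
    penalties: CoordinatePenalties,
    theta_init: np.ndarray,
    Cn: np.ndarray,
    value=0.0,
    **kwargs,
) -> PenalizedFit:
    """Maximise the penalized objective subject to Cn theta = value.

    The equality restriction enters each LQA quadratic step through its KKT
    system, so the iterates stay exactly feasible; coordinates that appear in
    the contrast are protected from deletion.
    """
    Cn = _check_contrast(Cn, objective.s)
    c = np.broadcast_to(np.atleast_1d(np.asarray(value, dtype=float)), (Cn.shape[0],))
    return penalized_et_estimate(
        objective, theta_init, penalties, constraint=(Cn, c), **kwargs
    )


def _joint_sandwich(system, theta: np.ndarray, lam: np.ndarray, idx: np.ndarray):
    """Sandwich covariance of sqrt(n)(lam, theta_idx) from the first-order
    system U_n1 = 0, U_n2 = 0 (second-derivative-of-G terms are dropped;
    exact at lam = 0, i.e. just-identified systems)."""
    G = system.moments(theta)
    J = system.jacobian(theta)[:, :, idx]
    n, t = G.shape
    k = idx.size
    u = np.clip(G @ lam, -500, 500)
    E = np.exp(u)
    m1 = E[:, None] * G
    Jl = np.einsum("itk,t->ik", J, lam)            # J_i' lam
    m2 = E[:, None] * Jl
    M = np.hstack([m1, m2])
    Omega = M.T @ M / n
    d11 = (G * E[:, None]).T @ G / n
    d12 = (G * E[:, None]).T @ Jl / n + np.einsum("i,itk->tk", E, J) / n
    d22 = (Jl * E[:, None]).T @ Jl / n
    Delta = np.block([[d11, d12], [d12.T, d22]])
    Dinv = np.linalg.pinv(Delta)
    cov = Dinv @ Omega @ Dinv.T
    return Delta, Omega, cov[t:, t:]


def wald_sandwich(system, fit, idx: np.ndarray | None = None, alpha: float = 0.05):
    """Sandwich covariance / standard errors on the selected support.

    Returns a :class:`SandwichCov` and the per-coordinate Wald intervals
    theta_j +/- z_{1-alpha/2} se_j (NaN off the evaluated set).
    """
    theta = np.asarray(fit.theta, dtype=float)
    lam = np.asarray(fit.lam, dtype=float)
    s = theta.size
    if idx is None:
        idx = np.asarray(fit.support, dtype=int)
        if idx.size == 0:
            idx = np.arange(s)
    Delta, Omega, cov_idx = _joint_sandwich(system, theta, lam, idx)
    cov = np.zeros((s, s))
    cov[np.ix_(idx, idx)] = cov_idx
    se = np.full(s, np.nan)
    d = np.diag(cov_idx)
    if np.any(d < -1e-8):
        warnings.warn("sandwich covariance not PSD; using absolute diagonal", RuntimeWarning)
    se[idx] = np.sqrt(np.abs(d) / system.n)
    z = stats.norm.ppf(1 - alpha / 2)
    intervals = np.column_stack([theta - z * se, theta + z * se])
    return SandwichCov(delta=Delta, omega=Omega, cov=cov, se=se, idx=idx), intervals


def scaling_factor(objective, fit, Cn: np.ndarray) -> float:
    """M = e / trace[(Cn Vmodel Cn')^{-1} (Cn Vsand Cn')].

    Vmodel is the inverse Gauss-Newton curvature (the efficient-ET covariance
    when the moments are correctly specified); Vsand the sandwich covariance
    of the first-order system.  Both are evaluated on the union of the
    selected support and the contrast coordinates.  Falls back to 1 with a
    warning when the pieces are numerically singular.
    """
    system = objective.system
    Cn = _check_contrast(Cn, system.s)
    e = Cn.shape[0]
    theta = np.asarray(fit.theta, dtype=float)
    support = np.asarray(fit.support, dtype=int)
    touched = np.flatnonzero(np.any(np.abs(Cn) > 0, axis=0))
    idx = np.unique(np.concatenate([support, touched]))
    try:
        _, _, A, aux = objective.value_grad_curv(theta)
        Ai = A[np.ix_(idx, idx)]
        Vm_idx = np.linalg.inv(Ai + 1e-10 * (np.trace(Ai) / idx.size + 1) * np.eye(idx.size))
        _, _, Vs_idx = _joint_sandwich(system, theta, aux["lam"], idx)
        Ci = Cn[:, idx]
        num = Ci @ Vs_idx @ Ci.T
        den = Ci @ Vm_idx @ Ci.T
        ratio = np.trace(np.linalg.solve(den, num))
        if not np.isfinite(ratio) or ratio <= 1e-8:
            raise np.linalg.LinAlgError
        return float(e / ratio)
    except np.linalg.LinAlgError:
        warnings.warn("scaling factor unstable; falling back to M=1", RuntimeWarning)
        return 1.0


def pet_lr_statistic(
    result,
    Cn: np.ndarray,
    value=0.0,
    scaling: float | None = None,
) -> ContrastTest:
    """Scaled constrained penalized ET likelihood ratio test of Cn theta = value.

    ``result`` is a :class:`~petlik.fit.PETLResult`; the penalties are held at
    the tuning selected on the unconstrained problem.
    """
    objective, penalties, fit = result.objective, result.penalties, result.fit
    system = result.system
    scales = getattr(result, "scales", None)
    if scales is not None and not np.allclose(scales, 1.0):
        # the contrast is stated on the raw coefficient scale; re-express it
        # on the internal (standardized) scale and re-orthonormalise
        Cn = np.atleast_2d(np.asarray(Cn, dtype=float))
        c = np.broadcast_to(np.atleast_1d(np.asarray(value, dtype=float)), (Cn.shape[0],))
        M = Cn / scales[None, :]
        Q, R = np.linalg.qr(M.T)
        Cn = Q.T
        value = np.linalg.solve(R.T, c)
    Cn = _check_contrast(Cn, system.s)
    e = Cn.shape[0]
    n = system.n
    bounds = getattr(result, "bounds", None)
    F_unc = objective.bic_value(fit.theta) - penalties.value(fit.theta)
    cfit = constrained_pet_estimate(objective, penalties, fit.theta, Cn, value=value,
                                    bounds=bounds)
    F_con = objective.bic_value(cfit.theta) - penalties.value(cfit.theta)
    if F_con > F_unc:
        # the constrained solve escaped a stall of the unconstrained fit;
        # polish the unconstrained optimum from the constrained point
        from .penalties import penalized_et_estimate

        refit = penalized_et_estimate(objective, cfit.theta, penalties, bounds=bounds)
        F_refit = objective.bic_value(refit.theta) - penalties.value(refit.theta)
        if F_refit > F_unc:
            F_unc = F_refit
            fit = refit
    stat = 2.0 * n * (F_unc - F_con)
    if stat < -0.5:
        raise RuntimeError(
            f"constrained optimum exceeds unconstrained ({stat=}); optimization failure"
        )
    stat = max(stat, 0.0)
    M = scaling_factor(objective, fit, Cn) if scaling is None else float(scaling)
    scaled = stat * M
    p = float(stats.chi2.sf(scaled, e))
    return ContrastTest(
        Cn=Cn, statistic=float(stat), scaling=float(M), df=e, p_value=p,
        constrained=cfit,
        diagnostics={"objective_unconstrained": F_unc, "objective_constrained": F_con},
    )


def confidence_interval(
    result,
    coord: int,
    alpha: float = 0.05,
    se_hint: float | None = None,
    max_doublings: int = 14,
) -> tuple[float, float]:
    """Profile confidence interval for a single coordinate by inverting the
    scaled constrained LR statistic at level alpha."""
    system = result.system
    s = system.s
    Cn = np.zeros((1, s))
    Cn[0, coord] = 1.0
    fit = result.fit
    scales = getattr(result, "scales", None)
    scale_j = 1.0 if scales is None else float(scales[coord])
    center = float(fit.theta[coord])   # internal scale throughout; the
    # returned interval is mapped back to the raw coefficient scale
    q = float(stats.chi2.ppf(1 - alpha, 1))
    if q <= 0:
        return (center, center)
    M = scaling_factor(result.objective, fit, Cn)
    if se_hint is None:
        try:
            sw, _ = wald_sandwich(system, fit, idx=np.unique(np.concatenate([fit.support, [coord]])))
            se_hint = float(sw.se[coord])
        except Exception:  # pragma: no cover
            se_hint = np.nan
    if not np.isfinite(se_hint) or se_hint <= 0:
        se_hint = max(0.1, 0.1 * abs(center))

    warm = {"theta": fit.theta.copy()}

    F_unc = result.objective.bic_value(fit.theta) - result.penalties.value(fit.theta)

    def profile_stat(value: float) -> float:
        init = warm["theta"].copy()
        init[coord] = value
        cfit = constrained_pet_estimate(result.objective, result.penalties, init, Cn, value=value,
                                        bounds=getattr(result, "bounds", None))
        warm["theta"] = cfit.theta.copy()
        F_con = result.objective.bic_value(cfit.theta) - result.penalties.value(cfit.theta)
        return max(2.0 * system.n * (F_unc - F_con), 0.0) * M

    if profile_stat(center) >= q:
        # the quantile is inside the numerical noise of the profile at the
        # point estimate (alpha -> 1): the interval degenerates
        return (center / scale_j, center / scale_j)

    def crossing(direction: float) -> float:
        step = se_hint
        prev = center
        for _ in range(max_doublings):
            cand = center + direction * step
            if profile_stat(cand) - q > 0:
                # manual bisection: the profile is recomputed at every probe
                # and can carry optimisation noise near the point estimate,
                # which brentq's strict sign bookkeeping does not tolerate
                warm["theta"] = fit.theta.copy()
                lo, hi = prev, cand
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if profile_stat(mid) - q > 0:
                        hi = mid
                    else:
                        lo = mid
                    if abs(hi - lo) < se_hint * 0.02:
                        break
                return 0.5 * (lo + hi)
            prev = cand
            step *= 2.0
        raise RuntimeError("confidence bound bracket not found; profile may be non-monotone")

    lo = crossing(-1.0)
    warm["theta"] = fit.theta.copy()
    hi = crossing(+1.0)
    return (float(lo) / scale_j, float(hi) / scale_j)
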