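"""Exponentially tilted (ET) likelihood engine.

The ET likelihood attaches probabilities ``w_i`` to observations ``D_i`` by
minimising the Kullback--Leibler divergence ``sum_i w_i log w_i`` subject to
``sum_i w_i = 1`` and the moment constraints ``sum_i w_i G(D_i; theta) = 0``.
The Lagrange dual gives ``w_i = exp(lam' G_i) / sum_j exp(lam' G_j)`` and the
profiled log-ET likelihood ratio

    ln(lam, theta) = log( (1/n) sum_i exp(lam' G_i(theta)) ),

which is convex in ``lam`` with value 0 at ``lam = 0``.  The ET estimator is
the saddle point ``theta_hat = argmax_theta inf_lam ln(lam, theta)``.

A *moment system* is any object exposing

    n, t, s            -- observations, moment dimension, parameter dimension
    moments(theta)     -- (n, t) array, row i = G(D_i; theta)
    jacobian(theta)    -- (n, t, s) array, d G(D_i; theta) / d theta

The inner problem is solved by damped Newton on the log-mean-exp form (so the
Hessian is a softmax-weighted covariance, immune to overflow); the outer
problem by a damped Gauss-Newton ascent using the envelope gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "ETFit",
    "InnerResult",
    "et_weights",
    "profile_log_et_ratio",
    "log_et_ratio",
    "score_lambda",
    "inner_lambda_solve",
    "ETObjective",
    "et_estimate",
]

#: exponents lam' G_i are kept inside [-EXP_CAP, EXP_CAP]; this realises the
#: domain restriction Lambda_n(theta) (an open set of multipliers keeping the
#: tilting representable) without clipping any computed value.  The cap must
#: be generous: a tight cap stops the inner infimum early on wild moment
#: configurations and overstates the profiled objective.
EXP_CAP = 500.0


def _check_finite(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x


def et_weights(lam: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Exponentially tilted probabilities w_i = exp(lam'G_i)/sum_j exp(lam'G_j).

    Computed as a softmax (max-subtraction) so that large exponents cannot
    overflow.  The result is nonnegative and sums to one.
    """
    lam = _check_finite("lam", lam)
    G = _check_finite("G", G)
    u = G @ lam
    return softmax(u)


def log_et_ratio(lam: np.ndarray, G: np.ndarray) -> float:
    """ln(lam, theta) = log((1/n) sum_i exp(lam'G_i)) via log-sum-exp."""
    lam = _check_finite("lam", lam)
    G = _check_finite("G", G)
    n = G.shape[0]
    u = G @ lam
    return float(logsumexp(u) - np.log(n))


def profile_log_et_ratio(lam, theta, system) -> float:
    """ln(lam, theta) for a moment system evaluated at ``theta``."""
    G = system.moments(np.asarray(theta, dtype=float))
    return log_et_ratio(lam, G)


def score_lambda(lam: np.ndarray, G: np.ndarray) -> np.ndarray:
    """U_n1(lam, theta) = (1/n) sum_i exp(lam'G_i) G_i.

    This is the lam-derivative of (1/n) sum_i exp(lam'G_i) = exp(ln); its root
    coincides with the root of the true gradient of ln itself (the two differ
    by the positive factor exp(ln)), and root finding targets U_n1 = 0.
    """
    lam = _check_finite("lam", lam)
    G = _check_finite("G", G)
    n = G.shape[0]
    u = G @ lam
    return (np.exp(u) @ G) / n


@dataclass
class InnerResult:
    lam: np.ndarray
    converged: bool
    iterations: int
    max_score: float  # ||U_n1||_inf at the returned multiplier


def _lse(u: np.ndarray, n: int) -> float:
    m = u.max()
    return float(m + np.log(np.exp(u - m).sum()) - np.log(n))


try:  # the inner Newton loop is the hot kernel; JIT it when numba is present
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _newton_core(Gs, lam, u, obj, tol, max_iter, cap, ridge):
    n, t = Gs.shape
    logn = np.log(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m = u.max()
        w = np.exp(u - m)
        w = w / w.sum()
        grad = w @ Gs
        if np.abs(grad).max() <= tol:
            converged = True
            break
        Gc = Gs - grad
        H = (Gc * w.reshape(-1, 1)).T @ Gc
        tr = 0.0
        for k in range(t):
            tr += H[k, k]
        for k in range(t):
            H[k, k] += ridge * tr / t + 1e-14
        step = np.linalg.solve(H, -grad)
        gs = grad @ step
        alpha = 1.0
        accepted = False
        for _ in range(30):
            cand = lam + alpha * step
            uc = Gs @ cand
            if np.abs(uc).max() <= cap + 1e-9:
                mx = uc.max()
                oc = mx + np.log(np.exp(uc - mx).sum()) - logn
                if oc < obj + 1e-4 * alpha * gs:
                    lam, u, obj = cand, uc, oc
                    accepted = True
                    break
            alpha *= 0.5
        if not accepted:
            break
    return lam, u, obj, it, converged


if _njit is not None:
    _newton_core = _njit(cache=True, nogil=True)(_newton_core)


def inner_lambda_solve(
    G: np.ndarray,
    lam0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 80,
    ridge: float = 1e-10,
) -> InnerResult:
    """Solve inf_lam ln(lam, theta) for fixed theta, i.e. U_n1(lam) = 0.

    Damped Newton on the convex log-mean-exp objective.  The Newton Hessian is
    the softmax-weighted covariance of the moment rows, so every quantity is
    computed after max-subtraction and cannot overflow.  The moment columns
    are rescaled to unit root-mean-square internally (ln is invariant: the
    multiplier absorbs any column scaling), which conditions the Hessian.
    Steps are kept inside max_i |lam'G_i| <= EXP_CAP.
    """
    G = _check_finite("G", G)
    n, t = G.shape
    col = np.sqrt(np.mean(G * G, axis=0))
    col[col < 1e-12] = 1.0
    Gs = G / col
    lam = np.zeros(t) if lam0 is None else np.array(lam0, dtype=float) * col
    u = Gs @ lam
    if np.max(np.abs(u)) > EXP_CAP:  # out-of-domain warm start
        lam = np.zeros(t)
        u = Gs @ lam
    obj = _lse(u, n)
    # damped Newton with backtracking on the convex objective; the cap on
    # |lam'G_i| keeps exponents representable (implicit Lambda_n domain)
    lam, u, obj, it, converged = _newton_core(
        np.ascontiguousarray(Gs), lam, u, obj, tol, max_iter, EXP_CAP, ridge
    )
    if obj > 1e-12 and lam0 is not None:
        # a warm start can strand the solve above the origin value; restart
        return inner_lambda_solve(G, None, tol=tol, max_iter=max_iter, ridge=ridge)
    m = u.max()
    w = np.exp(u - m)
    w /= w.sum()
    grad = w @ Gs
    max_score = float(np.max(np.abs((np.exp(u) @ G) / n)))  # U_n1 on raw columns
    converged = converged or np.max(np.abs(grad)) <= tol
    return InnerResult(lam=lam / col, converged=bool(converged), iterations=it, max_score=max_score)


@dataclass
class ETFit:
    """Saddle-point solution of the (unpenalized) ET likelihood."""

    theta: np.ndarray
    lam: np.ndarray
    weights: np.ndarray
    log_ratio: float
    converged: bool
    outer_iterations: int = 0
    inner_iterations: int = 0
    max_score_lambda: float = np.nan
    max_grad_theta: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("theta", "lam", "weights"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d)


class ETObjective:
    """Profiled ET objective psi(theta) = inf_lam ln(lam, theta).

    Supplies value / gradient / Gauss-Newton curvature for the outer
    maximisation, with the inner multiplier warm-started between calls.
    The envelope theorem gives

        grad psi = sum_i w_i J_i' lam_hat,      J_i = dG_i/dtheta,

    and the curvature model A = D' Omega^{-1} D with D = sum_i w_i J_i and
    Omega = sum_i w_i G_i G_i' (both at the tilted weights), the local
    quadratic of the dual near lam ~ -Omega^{-1} gbar.
    """

    def __init__(self, system, inner_tol: float = 1e-9, inner_max_iter: int = 200,
                 value_tol: float | None = None):
        self.system = system
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        #: looser tolerance for pure objective evaluations (line searches);
        #: gradients, curvatures and final states use ``inner_tol``
        self.value_tol = value_tol if value_tol is not None else max(inner_tol, 1e-6)
        self._lam = np.zeros(system.t)
        self.inner_iterations = 0
        self.last_inner: InnerResult | None = None

    @property
    def s(self) -> int:
        return self.system.s

    def inner(self, theta: np.ndarray, G: np.ndarray | None = None,
              tol: float | None = None) -> InnerResult:
        if G is None:
            G = self.system.moments(theta)
        res = inner_lambda_solve(G, lam0=self._lam, tol=tol or self.inner_tol,
                                 max_iter=self.inner_max_iter)
        self._lam = res.lam
        self.inner_iterations += res.iterations
        self.last_inner = res
        return res

    def value(self, theta: np.ndarray) -> float:
        G = self.system.moments(theta)
        res = self.inner(theta, G, tol=self.value_tol)
        return log_et_ratio(res.lam, G)

    def value_grad_curv(self, theta: np.ndarray):
        """Return (psi, grad, A, aux) at theta.  A is PSD."""
        G = self.system.moments(theta)
        res = self.inner(theta, G)
        lam = res.lam
        w = et_weights(lam, G)
        psi = log_et_ratio(lam, G)
        if hasattr(self.system, "weighted_mean_jacobian"):
            D = self.system.weighted_mean_jacobian(theta, w)
        else:
            J = self.system.jacobian(theta)      # (n, t, s)
            D = np.einsum("i,itk->tk", w, J)     # weighted mean Jacobian
        grad = D.T @ lam
        Omega = (G * w[:, None]).T @ G
        t = G.shape[1]
        Omega = Omega + (1e-10 * (np.trace(Omega) / t + 1.0)) * np.eye(t)
        A = D.T @ np.linalg.solve(Omega, D)
        aux = {"lam": lam, "weights": w, "D": D, "Omega": Omega, "G": G}
        return psi, grad, A, aux

    def bic_value(self, theta: np.ndarray) -> float:
        """ln at theta from a cold, deep inner solve.

        Model-comparison values must not inherit warm-start or loose-tolerance
        optimism: a badly fitting theta whose inner infimum is hard to reach
        would otherwise look better than it is.
        """
        G = self.system.moments(np.asarray(theta, dtype=float))
        res = inner_lambda_solve(G, None, tol=min(self.inner_tol, 1e-10), max_iter=400)
        return log_et_ratio(res.lam, G)

    def final_state(self, theta: np.ndarray) -> dict:
        G = self.system.moments(np.asarray(theta, dtype=float))
        res = self.inner(theta, G)
        return {
            "lam": res.lam.copy(),
            "weights": et_weights(res.lam, G),
            "log_ratio": log_et_ratio(res.lam, G),
        }

    def fit_at(self, theta: np.ndarray, converged: bool = True, outer: int = 0) -> ETFit:
        """Package an ETFit at a given theta (inner problem re-solved)."""
        theta = np.asarray(theta, dtype=float)
        G = self.system.moments(theta)
        res = self.inner(theta, G)
        return ETFit(
            theta=theta,
            lam=res.lam,
            weights=et_weights(res.lam, G),
            log_ratio=log_et_ratio(res.lam, G),
            converged=converged and res.converged,
            outer_iterations=outer,
            inner_iterations=self.inner_iterations,
            max_score_lambda=res.max_score,
        )


def et_estimate(
    system,
    theta_init: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 200,
    ridge: float = 1e-8,
    inner_tol: float = 1e-9,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> ETFit:
    """Unpenalized ET likelihood estimate: maximise psi(theta) = inf_lam ln.

    Damped Gauss-Newton with the envelope gradient; the inner multiplier is
    re-solved (warm-started) at every trial point.  Non-convergence is
    reported through ``converged=False``, never silently.
    """
    if system.t < system.s:
        raise ValueError(f"under-identified system: t={system.t} < s={system.s}")
    if system.n == 1:
        # single-atom distribution: the ET objective degenerates and the
        # estimator is the root of G(D_1; theta) = 0 (when solvable)
        theta = np.array(theta_init, dtype=float)
        for _ in range(200):
            g = system.moments(theta)[0]
            if np.max(np.abs(g)) < 1e-10:
                break
            J = system.jacobian(theta)[0]
            step, *_ = np.linalg.lstsq(J, -g, rcond=None)
            theta = theta + step
        g = system.moments(theta)[0]
        return ETFit(theta=theta, lam=np.zeros(system.t), weights=np.ones(1),
                     log_ratio=0.0, converged=bool(np.max(np.abs(g)) < 1e-8))
    obj = ETObjective(system, inner_tol=inner_tol)
    theta = np.array(theta_init, dtype=float)
    if theta.shape != (system.s,):
        raise ValueError(f"theta_init has shape {theta.shape}, expected ({system.s},)")
    psi = obj.value(theta)
    converged = False
    it = 0
    max_grad = np.nan
    for it in range(1, max_outer + 1):
        psi, grad, A, _ = obj.value_grad_curv(theta)
        max_grad = float(np.max(np.abs(grad)))
        if max_grad <= tol * (1.0 + abs(psi)):
            converged = True
            break
        s = system.s
        Areg = A + (ridge * (np.trace(A) / s + 1.0)) * np.eye(s)
        try:
            d = np.linalg.solve(Areg, grad)
        except np.linalg.LinAlgError:
            d = grad
        alpha, accepted = 1.0, False
        gd = float(grad @ d)
        if gd <= 0:  # fall back to steepest ascent
            d, gd = grad, float(grad @ grad)
        for _ in range(30):
            cand = theta + alpha * d
            if bounds is not None:
                cand = np.clip(cand, bounds[0], bounds[1])
            pc = obj.value(cand)
            if pc >= psi + 1e-4 * alpha * gd:
                theta, psi = cand, pc
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # stationary up to line-search resolution
            converged = max_grad <= 1e-5 * (1.0 + abs(psi))
            break
    fit = obj.fit_at(theta, converged=converged, outer=it)
    fit.max_grad_theta = max_grad
    return fit
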