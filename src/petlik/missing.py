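"""Propensity models, IPW moment weighting, calibration moments and the
stacked moment system for responses missing at random (MAR).

The response ``Y_i`` is observed iff ``delta_i = 1``; covariates
``X_i = (U_i', Z_i')'`` are always observed.  Missingness depends only on the
direct covariates ``U`` through a propensity ``pi(U; gamma)`` (logistic by
default; step and probit variants exist to *generate* misspecified
mechanisms).  Two moment blocks are stacked per observation:

* IPW outcome moments      g_ipw = (delta/pi) g(X, Y; beta)   (r of them)
* calibration moments      phi   = (delta/pi - 1) d(Z)        (m of them)

The calibration block has mean zero when the propensity is correctly
specified and identifies gamma; the instruments ``Z`` are excluded from the
propensity, which gives the calibration moments their leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "PropensityModel",
    "MissingDataset",
    "propensity",
    "calibration_moments",
    "ipw_moments",
    "StackedMomentSystem",
    "d_const_z",
]

PROPENSITY_FLOOR = 0.01  # Assumption-2(i)-style lower bound c0
_LIN_CAP = 500.0         # IEEE guard only, far outside any statistical range


@dataclass
class PropensityModel:
    """Parametric propensity pi(u; gamma) = Pr(delta = 1 | U = u).

    gamma = (gamma_c, gamma_u')' pairs an intercept with slopes on U.
    ``step`` is a two-level mechanism: level 1 when the linear predictor is
    <= step_cut, level 2 above it (used only to generate misspecified data).
    """

    family: str = "logistic"
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(1))
    step_levels: tuple[float, float] = (0.5, 0.9)
    step_cut: float = 0.0

    def __post_init__(self):
        if self.family not in ("logistic", "probit", "step"):
            raise ValueError(f"unknown propensity family {self.family!r}")
        self.gamma = np.asarray(self.gamma, dtype=float)
        lo, hi = self.step_levels
        if not (0 < lo <= 1 and 0 < hi <= 1):
            raise ValueError("step levels must lie in (0, 1]")


def _linpred(U: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    U = np.atleast_2d(np.asarray(U, dtype=float))
    gamma = np.asarray(gamma, dtype=float)
    if U.shape[1] != gamma.size - 1:
        raise ValueError(f"U has {U.shape[1]} columns but gamma has {gamma.size} entries (intercept + slopes)")
    return gamma[0] + U @ gamma[1:]


def propensity(U, model: PropensityModel) -> np.ndarray:
    """Evaluate pi(u; gamma) row-wise; scalar input gives a scalar."""
    one_row = np.asarray(U).ndim == 1
    lp = np.clip(_linpred(U, model.gamma), -_LIN_CAP, _LIN_CAP)
    if model.family == "logistic":
        pi = expit(lp)
    elif model.family == "probit":
        pi = norm.cdf(lp)
    else:
        lo, hi = model.step_levels
        pi = np.where(lp <= model.step_cut, lo, hi)
    return float(pi[0]) if one_row else pi


def calibration_moments(
    delta,
    U,
    Z,
    model: PropensityModel,
    d_fn=None,
    floor: float = PROPENSITY_FLOOR,
    on_floor: str = "raise",
):
    """phi(U_i, Z_i; gamma) = (delta_i / pi(U_i; gamma) - 1) d(Z_i).

    ``d_fn`` maps the instrument rows to an (n, m) array; the default
    prepends a constant to Z (so the propensity intercept is identified).
    Propensities below ``floor`` violate the overlap condition pi > c0
    (Assumption 2(i)); ``on_floor`` is "raise", "warn" or "ignore".
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    pi = np.atleast_1d(propensity(U, model))
    _handle_floor(pi, floor, on_floor)
    d = d_const_z(Z) if d_fn is None else np.atleast_2d(d_fn(Z))
    out = (delta / pi - 1.0)[:, None] * d
    return out[0] if np.asarray(delta).size == 1 and out.shape[0] == 1 else out


def _handle_floor(pi: np.ndarray, floor: float, on_floor: str) -> None:
    if np.any(pi <= 0):
        raise ValueError("propensity must be strictly positive")
    if floor is not None and np.any(pi < floor):
        msg = (f"propensity below the overlap floor c0={floor} "
               "(Assumption 2(i): pi(u; gamma) > c0)")
        if on_floor == "raise":
            raise ValueError(msg)
        if on_floor == "warn":
            import warnings

            warnings.warn(msg, RuntimeWarning, stacklevel=3)


def ipw_moments(delta_i: float, pi_i: float, g_i, r: int | None = None):
    """(delta/pi) g with the delta = 0 short-circuit.

    When the response is missing (delta = 0) the outcome moment g may be
    undefined, so ``g_i`` may be passed as a zero-argument callable that is
    only invoked when delta = 1; the delta = 0 result is a zero vector of
    length ``r`` (inferred from ``g_i`` when it is an array).
    """
    if pi_i <= 0:
        raise ValueError("propensity must be strictly positive")
    if delta_i == 0:
        if r is None:
            if callable(g_i):
                raise ValueError("pass r= to size the zero vector without evaluating g")
            r = np.asarray(g_i).shape[-1] if np.asarray(g_i).ndim else 1
        return np.zeros(r)
    g = np.asarray(g_i() if callable(g_i) else g_i, dtype=float)
    return (delta_i / pi_i) * g


def d_const_z(Z: np.ndarray) -> np.ndarray:
    """Default calibration map d(Z) = (1, Z)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return np.hstack([np.ones((Z.shape[0], 1)), Z])


def d_plain_z(Z: np.ndarray) -> np.ndarray:
    """d(Z) = Z, the form printed in the simulation designs."""
    return np.atleast_2d(np.asarray(Z, dtype=float))


@dataclass
class MissingDataset:
    """Tabular data with MAR responses.

    Y has shape (n,) or (n, e) with NaN on the missing rows; delta flags the
    observed rows (a single indicator governs the whole response vector).
    U are the direct covariates entering the propensity; Z the instruments.
    ``meta`` records the generating truth for synthetic data.
    """

    Y: np.ndarray
    U: np.ndarray
    Z: np.ndarray
    delta: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.delta = np.asarray(self.delta, dtype=int)
        n = self.delta.size
        if self.Y.shape[0] != n or self.U.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("Y, U, Z, delta must share their first dimension")
        if not np.all(np.isfinite(self.U)) or not np.all(np.isfinite(self.Z)):
            raise ValueError("covariates must be fully observed and finite")
        Ymat = self.Y if self.Y.ndim == 2 else self.Y[:, None]
        obs_missing = ~np.all(np.isfinite(Ymat), axis=1)
        if np.any(obs_missing != (self.delta == 0)):
            raise ValueError("delta must flag exactly the rows with missing Y")

    @property
    def n(self) -> int:
        return int(self.delta.size)

    @property
    def n_observed(self) -> int:
        return int(self.delta.sum())

    def observed(self):
        idx = np.flatnonzero(self.delta == 1)
        return idx, self.Y[idx], self.U[idx], self.Z[idx]


class StackedMomentSystem:
    """The n x t per-observation moment matrix G(D_i; theta) of the stacked
    system (IPW outcome block then calibration block) with its analytic
    Jacobian, for theta = (beta', gamma')'.

    The propensity is the logistic working model regardless of how the data
    were generated (robustness to mechanism misspecification is a property
    of the estimator, not an input).
    """

    def __init__(
        self,
        dataset: MissingDataset,
        model,
        d_fn=None,
        floor: float = PROPENSITY_FLOOR,
        on_floor: str = "warn",
        floor_mode: str = "clip",
    ):
        self.dataset = dataset
        self.model = model
        self.d_fn = d_fn or d_const_z
        self.floor = floor
        self.on_floor = on_floor
        if floor_mode not in ("clip", "none"):
            raise ValueError("floor_mode must be 'clip' or 'none'")
        self.floor_mode = floor_mode
        self.n = dataset.n
        self.p = model.p
        self.q = dataset.U.shape[1] + 1          # gamma = (gamma_c, gamma_u)
        self.s = self.p + self.q
        self.d_mat = np.atleast_2d(self.d_fn(dataset.Z))
        self.m = self.d_mat.shape[1]
        self.r = model.r
        self.t = self.r + self.m
        if self.t < self.s:
            raise ValueError(
                f"under-identified stacked system: t = r+m = {self.t} < s = p+q = {self.s}"
            )
        self._obs_idx, self._Yo, self._Uo, self._Zo = dataset.observed()
        self._U1 = np.hstack([np.ones((self.n, 1)), dataset.U])  # (1, U) design
        self._warned = False

    # -- helpers -------------------------------------------------------
    def split(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.s,):
            raise ValueError(f"theta has shape {theta.shape}, expected ({self.s},)")
        return theta[: self.p], theta[self.p:]

    def _pi_obs(self, gamma: np.ndarray) -> np.ndarray:
        """Evaluated propensity on observed rows, floored at the overlap
        bound c0 (Assumption 2(i)) so the inverse weights stay bounded."""
        lp = np.clip(self._U1[self._obs_idx] @ gamma, -_LIN_CAP, _LIN_CAP)
        pi = expit(lp)
        if self.floor_mode == "clip":
            pi = np.maximum(pi, self.floor)
        return pi

    def _pi_all(self, gamma: np.ndarray) -> np.ndarray:
        lp = np.clip(self._U1 @ gamma, -_LIN_CAP, _LIN_CAP)
        return expit(lp)

    # -- protocol ------------------------------------------------------
    def moments(self, theta: np.ndarray) -> np.ndarray:
        beta, gamma = self.split(theta)
        G = np.zeros((self.n, self.t))
        pi_obs = self._pi_obs(gamma)
        if self.floor_mode != "clip":
            self._floor_check(pi_obs)
        w = 1.0 / pi_obs                          # delta/pi on observed rows
        g = self.model.g(self._Yo, self._Uo, self._Zo, beta)
        G[self._obs_idx, : self.r] = w[:, None] * g
        # calibration block: (delta/pi - 1) d(Z); delta=0 rows give -d(Z)
        G[:, self.r:] = -self.d_mat
        G[self._obs_idx, self.r:] += w[:, None] * self.d_mat[self._obs_idx]
        return G

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        beta, gamma = self.split(theta)
        J = np.zeros((self.n, self.t, self.s))
        lp = np.clip(self._U1[self._obs_idx] @ gamma, -_LIN_CAP, _LIN_CAP)
        pi_raw = expit(lp)
        pi_obs = np.maximum(pi_raw, self.floor) if self.floor_mode == "clip" else pi_raw
        w = 1.0 / pi_obs
        g = self.model.g(self._Yo, self._Uo, self._Zo, beta)
        dg = self.model.dg(self._Yo, self._Uo, self._Zo, beta)
        # d g_ipw / d beta = (delta/pi) dg
        J[self._obs_idx, : self.r, : self.p] = w[:, None, None] * dg
        # d (delta/pi) / d gamma = -(delta/pi)(1 - pi) (1, U); zero where the
        # overlap floor is active (1/pi is constant there)
        u1o = self._U1[self._obs_idx]
        fac = -(w * (1.0 - pi_raw))               # per observed row
        if self.floor_mode == "clip":
            fac = np.where(pi_raw < self.floor, 0.0, fac)
        J[self._obs_idx, : self.r, self.p:] = fac[:, None, None] * g[:, :, None] * u1o[:, None, :]
        J[self._obs_idx, self.r:, self.p:] = (
            fac[:, None, None] * self.d_mat[self._obs_idx, :, None] * u1o[:, None, :]
        )
        return J

    def weighted_mean_jacobian(self, theta: np.ndarray, w: np.ndarray) -> np.ndarray:
        """sum_i w_i dG_i/dtheta as a t x s matrix, assembled blockwise
        (no n x t x s tensor; the blocks are small matrix products)."""
        beta, gamma = self.split(theta)
        D = np.zeros((self.t, self.s))
        lp = np.clip(self._U1[self._obs_idx] @ gamma, -_LIN_CAP, _LIN_CAP)
        pi_raw = expit(lp)
        pi_obs = np.maximum(pi_raw, self.floor) if self.floor_mode == "clip" else pi_raw
        ww = w[self._obs_idx] / pi_obs                       # w_i * delta/pi
        g = self.model.g(self._Yo, self._Uo, self._Zo, beta)
        if hasattr(self.model, "weighted_dg_sum"):
            D[: self.r, : self.p] = self.model.weighted_dg_sum(self._Yo, self._Uo, self._Zo, beta, ww)
        else:
            dg = self.model.dg(self._Yo, self._Uo, self._Zo, beta)
            D[: self.r, : self.p] = np.einsum("i,irp->rp", ww, dg, optimize=True)
        fac = -(ww * (1.0 - pi_raw))
        if self.floor_mode == "clip":
            fac = np.where(pi_raw < self.floor, 0.0, fac)
        u1o = self._U1[self._obs_idx]
        D[: self.r, self.p:] = (g * fac[:, None]).T @ u1o
        D[self.r:, self.p:] = (self.d_mat[self._obs_idx] * fac[:, None]).T @ u1o
        return D

    def _floor_check(self, pi_obs: np.ndarray) -> None:
        if self.on_floor == "ignore" or self._warned:
            return
        if np.any(pi_obs < self.floor):
            _handle_floor(pi_obs, self.floor, self.on_floor)
            self._warned = True

    # -- initial values ------------------------------------------------
    def theta_init(self, ridge: float = 1e-2) -> np.ndarray:
        """Complete-case initialiser for beta; ridge-logistic delta|U for gamma."""
        beta0 = self.model.init(self.dataset)
        gamma0 = ridge_logistic(self._U1, self.dataset.delta.astype(float), ridge=ridge)
        return np.concatenate([beta0, gamma0])


def ridge_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, max_iter: int = 60) -> np.ndarray:
    """Newton solver for logistic regression with a small ridge.

    The ridge keeps the solution finite under separation, which the extreme
    propensity designs here routinely produce.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    b = np.zeros(k)
    for _ in range(max_iter):
        lp = np.clip(X @ b, -_LIN_CAP, _LIN_CAP)
        p = expit(lp)
        grad = X.T @ (y - p) / n - ridge * b
        wdiag = np.maximum(p * (1 - p), 1e-10)
        H = (X * wdiag[:, None]).T @ X / n + ridge * np.eye(k)
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return b
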