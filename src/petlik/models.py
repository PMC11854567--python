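"""Concrete unconditional moment families g(X, Y; beta).

Three families cover the study designs:

* :class:`LinearIVModel`   -- linear regression moments a_i (Y_i - x_i' beta)
  with the instrument/premultiplier vector a_i equal to the full design
  (1, U, Z) by default (``residual="full_x"``); the literal Z-block-only form
  is available as ``residual="z_only"`` but identifies only an intercept and
  the Z coefficients.
* :class:`LogisticMomentModel` -- (1, Z)' (Y - expit(beta_c + Z'beta_x)).
* :class:`SEMMomentModel`  -- vech second-moment constraints of a structural
  equation model with latent X = (U', Z')': Y = B X + eps,
  U = Cu Z, Z = Cz^{-1} eps_z.  Only the factor loadings B are free
  parameters; the structural matrices and error variances are fixed.

Every model exposes ``r`` (moment dim), ``p`` (parameter dim), vectorised
``g(Y, U, Z, beta) -> (n, r)``, analytic ``dg(Y, U, Z, beta) -> (n, r, p)``
and a complete-case initialiser ``init(dataset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "LinearIVModel",
    "LogisticMomentModel",
    "SEMSpec",
    "SEMMomentModel",
    "linear_iv_moments",
    "logistic_moments",
    "sem_vech_moments",
    "vech",
]


def vech(M: np.ndarray) -> np.ndarray:
    """Half-vectorisation: column-major stack of the lower triangle
    (diagonal included), length e(e+1)/2."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("vech requires a square matrix")
    i, j = _vech_index(M.shape[0])
    return M[i, j]


def _vech_index(e: int):
    cols, rows = np.triu_indices(e)   # (col, row) pairs with col <= row ...
    return rows, cols                 # ... walked column by column


class LinearIVModel:
    """Moments a_i * (residual_i) for the linear outcome model.

    residual = Y - beta_c - x' beta_slopes where x is the full covariate
    (U, Z) under ``residual="full_x"`` or only Z under ``"z_only"``.
    ``intercept_moment`` prepends the moment 1 * residual so that the
    intercept is identified.
    """

    name = "linear_iv"

    def __init__(self, n_u: int, n_z: int, residual: str = "full_x", intercept_moment: bool = True):
        if residual not in ("full_x", "z_only"):
            raise ValueError("residual must be 'full_x' or 'z_only'")
        self.n_u, self.n_z = int(n_u), int(n_z)
        self.residual = residual
        self.intercept_moment = bool(intercept_moment)
        n_cov = self.n_u + self.n_z if residual == "full_x" else self.n_z
        self.p = 1 + n_cov
        self.r = n_cov + (1 if intercept_moment else 0)

    def _design(self, U: np.ndarray, Z: np.ndarray) -> np.ndarray:
        X = np.hstack([U, Z]) if self.residual == "full_x" else Z
        return np.hstack([np.ones((X.shape[0], 1)), X])

    def _instruments(self, D: np.ndarray) -> np.ndarray:
        return D if self.intercept_moment else D[:, 1:]

    def g(self, Y, U, Z, beta) -> np.ndarray:
        Y = np.asarray(Y, dtype=float).reshape(-1)
        D = self._design(U, Z)
        resid = Y - D @ beta
        return self._instruments(D) * resid[:, None]

    def dg(self, Y, U, Z, beta) -> np.ndarray:
        D = self._design(U, Z)
        A = self._instruments(D)
        return -A[:, :, None] * D[:, None, :]

    def weighted_dg_sum(self, Y, U, Z, beta, w) -> np.ndarray:
        D = self._design(U, Z)
        A = self._instruments(D)
        return -(A * w[:, None]).T @ D

    def coef_scales(self, su: np.ndarray, sz: np.ndarray) -> np.ndarray:
        """Per-coefficient covariate scales (1 for the intercept)."""
        if self.residual == "full_x":
            return np.concatenate([[1.0], su, sz])
        return np.concatenate([[1.0], sz])

    def init(self, dataset) -> np.ndarray:
        _, Yo, Uo, Zo = dataset.observed()
        D = self._design(Uo, Zo)
        beta, *_ = np.linalg.lstsq(D, np.asarray(Yo, dtype=float).reshape(-1), rcond=None)
        return beta


def linear_iv_moments(row_z, residual: float, intercept_moment: bool = True) -> np.ndarray:
    """Single-observation form Z_i * residual (optionally with the 1*residual
    intercept moment prepended)."""
    z = np.atleast_1d(np.asarray(row_z, dtype=float))
    g = z * residual
    return np.concatenate([[residual], g]) if intercept_moment else g


class LogisticMomentModel:
    """(1, Z)' (Y - expit(beta_c + Z' beta_x)) for binary Y."""

    name = "logistic"

    def __init__(self, n_z: int):
        self.n_z = int(n_z)
        self.p = self.n_z + 1
        self.r = self.n_z + 1

    def _design(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return np.hstack([np.ones((Z.shape[0], 1)), Z])

    def g(self, Y, U, Z, beta) -> np.ndarray:
        Y = np.asarray(Y, dtype=float).reshape(-1)
        if not np.all(np.isin(Y, (0.0, 1.0))):
            raise ValueError("logistic moments require Y in {0, 1}")
        D = self._design(Z)
        mu = expit(np.clip(D @ beta, -500, 500))
        return D * (Y - mu)[:, None]

    def dg(self, Y, U, Z, beta) -> np.ndarray:
        D = self._design(Z)
        mu = expit(np.clip(D @ beta, -500, 500))
        w = mu * (1.0 - mu)
        return -(D * w[:, None])[:, :, None] * D[:, None, :]

    def weighted_dg_sum(self, Y, U, Z, beta, w) -> np.ndarray:
        D = self._design(Z)
        mu = expit(np.clip(D @ beta, -500, 500))
        v = mu * (1.0 - mu) * w
        return -(D * v[:, None]).T @ D

    def coef_scales(self, su: np.ndarray, sz: np.ndarray) -> np.ndarray:
        return np.concatenate([[1.0], sz])

    def init(self, dataset) -> np.ndarray:
        from .missing import ridge_logistic

        _, Yo, _, Zo = dataset.observed()
        return ridge_logistic(self._design(Zo), np.asarray(Yo, dtype=float).reshape(-1), ridge=1e-4)


def logistic_moments(row_z, y: float, beta) -> np.ndarray:
    """Single-observation logistic moment (1, Z)' (y - expit(beta_c + Z'bx))."""
    z = np.atleast_1d(np.asarray(row_z, dtype=float))
    d = np.concatenate([[1.0], z])
    return d * (y - expit(float(d @ beta)))


@dataclass
class SEMSpec:
    """Structural equation model dimensions and fixed structure.

    Y (e = 2f manifest variables) loads on f latent variables X = (U', Z')'
    through the e x f loading matrix B; the h = f/2 direct latents are
    U = Cu Z and the instruments solve Cz Z = eps_z with eps_z ~ N(0, zeta I)
    (the latent U-innovations are identically zero).  Measurement errors are
    N(0, alpha I_e).  Cu and Cz default to the unit-diagonal tridiagonal
    coupling matrices with off-diagonals +/-0.5 and +/-0.8.
    """

    f: int
    h: int
    zeta: float = 0.8
    alpha: float = 0.8
    Cu: np.ndarray | None = None
    Cz: np.ndarray | None = None

    def __post_init__(self):
        if self.f != 2 * self.h:
            raise ValueError("SEM dimensions require f = 2h")
        k = self.f - self.h
        if self.Cu is None:
            self.Cu = _coupling(self.h, k, 0.5)
        if self.Cz is None:
            self.Cz = _coupling(k, k, 0.8)
        self.Cu = np.asarray(self.Cu, dtype=float)
        self.Cz = np.asarray(self.Cz, dtype=float)
        if abs(np.linalg.det(self.Cz)) < 1e-12:
            raise ValueError("singular instrument coupling matrix Cz")

    @property
    def e(self) -> int:
        return 2 * self.f

    @property
    def p(self) -> int:
        return self.e * self.f

    def sigma_z(self) -> np.ndarray:
        Czi = np.linalg.inv(self.Cz)
        return Czi @ (self.zeta * np.eye(self.f - self.h)) @ Czi.T

    def sigma_x(self) -> np.ndarray:
        Sz = self.sigma_z()
        Cu = self.Cu
        top = np.hstack([Cu @ Sz @ Cu.T, Cu @ Sz])
        bot = np.hstack([Sz @ Cu.T, Sz])
        return np.vstack([top, bot])

    def implied_cov(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=float).reshape(self.e, self.f)
        return B @ self.sigma_x() @ B.T + self.alpha * np.eye(self.e)

    def true_loadings(self, value: float = 0.6) -> np.ndarray:
        """Loadings `value` at |j1 - j2| = 1 (1-indexed), zero elsewhere."""
        B = np.zeros((self.e, self.f))
        for j1 in range(1, self.e + 1):
            for j2 in range(1, self.f + 1):
                if abs(j1 - j2) == 1:
                    B[j1 - 1, j2 - 1] = value
        return B


def _coupling(nrow: int, ncol: int, off: float) -> np.ndarray:
    M = np.eye(nrow, ncol)
    for i in range(nrow):
        if i + 1 < ncol:
            M[i, i + 1] = off
        if 0 <= i - 1 < ncol and i - 1 >= 0:
            M[i, i - 1] = -off
    return M


class SEMMomentModel:
    """vech(Y Y' - Sigma_Y(B)) with Sigma_Y(B) = B Sigma_X B' + alpha I.

    Parameters are the entries of B in row-major order (p = e*f = 2f^2);
    the structural pieces (Cu, Cz, zeta, alpha) are held fixed.
    """

    name = "sem_vech"

    def __init__(self, spec: SEMSpec):
        self.spec = spec
        self.e = spec.e
        self.f = spec.f
        self.p = spec.p
        self.r = self.e * (self.e + 1) // 2
        self._Sx = spec.sigma_x()
        self._vi, self._vj = _vech_index(self.e)

    def g(self, Y, U, Z, beta) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        B = np.asarray(beta, dtype=float).reshape(self.e, self.f)
        Sy = B @ self._Sx @ B.T + self.spec.alpha * np.eye(self.e)
        outer = Y[:, :, None] * Y[:, None, :]
        diff = outer - Sy[None, :, :]
        return diff[:, self._vi, self._vj]

    def dg(self, Y, U, Z, beta) -> np.ndarray:
        n = np.atleast_2d(np.asarray(Y, dtype=float)).shape[0]
        B = np.asarray(beta, dtype=float).reshape(self.e, self.f)
        Q = B @ self._Sx                     # e x f
        Dg = np.zeros((self.r, self.p))
        for k in range(self.e):
            for l in range(self.f):
                dS = np.zeros((self.e, self.e))
                dS[k, :] += Q[:, l]
                dS[:, k] += Q[:, l]
                Dg[:, k * self.f + l] = -dS[self._vi, self._vj]
        return np.broadcast_to(Dg, (n, self.r, self.p))

    def weighted_dg_sum(self, Y, U, Z, beta, w) -> np.ndarray:
        return float(np.sum(w)) * self.dg(Y[:1], None, None, beta)[0]

    def init(self, dataset) -> np.ndarray:
        """Spectral initialiser from the IPW-weighted second moment of Y.

        The latent covariance has rank f - h, so only the combination
        W = B T (T = [Cu; I]) is likelihood-identified; the top eigenpairs of
        the weighted second moment minus the measurement variance give W up
        to rotation/sign, and the minimum-norm B with B T = W starts the
        penalized fit.  Column signs are set so each factor's largest loading
        is positive (the usual loading-sign convention).
        """
        from .missing import ridge_logistic

        _, Yo, Uo, _ = dataset.observed()
        U1 = np.hstack([np.ones((dataset.n, 1)), dataset.U])
        gam = ridge_logistic(U1, dataset.delta.astype(float), ridge=1e-4)
        lp = np.clip(U1[dataset.delta == 1] @ gam, -500, 500)
        w = 1.0 / np.clip(expit(lp), 1e-3, 1.0)
        w = w / w.sum()
        S = (Yo * w[:, None]).T @ Yo - self.spec.alpha * np.eye(self.e)
        k = self.spec.f - self.spec.h
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1][:k]
        lam = np.clip(evals[order], 1e-6, None)
        W = evecs[:, order] * np.sqrt(lam)[None, :]
        for j in range(W.shape[1]):
            if W[np.argmax(np.abs(W[:, j])), j] < 0:
                W[:, j] = -W[:, j]
        # map the factor scale to the Sigma_Z metric: W ~ B T with
        # Var(T'X-space factor) = Sigma_Z; whiten accordingly
        T = np.vstack([self.spec.Cu, np.eye(k)])
        Sz = self.spec.sigma_z()
        Lz = np.linalg.cholesky(Sz + 1e-12 * np.eye(k))
        Wb = W @ np.linalg.inv(Lz)            # so that Wb Sz Wb' = W W'
        B0 = Wb @ np.linalg.pinv(T)
        return B0.ravel()


def sem_vech_moments(y_row: np.ndarray, spec: SEMSpec, B: np.ndarray) -> np.ndarray:
    """Single-observation SEM moment vech(y y' - Sigma_Y(B))."""
    y = np.asarray(y_row, dtype=float).reshape(-1)
    return vech(np.outer(y, y) - spec.implied_cov(B))
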