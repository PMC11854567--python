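"""High-level penalized ET likelihood fitting pipeline.

``penalized_et_fit`` wires a :class:`~petlik.missing.MissingDataset` and a
moment model into the stacked system, computes the dense (unpenalized) ET
estimate as the LQA starting point, and tunes the two penalty levels
(outcome block, propensity block) by the dimension-scaled BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .et import ETFit, ETObjective, et_estimate
from .missing import MissingDataset, StackedMomentSystem
from .penalties import (
    BICSelection,
    CoordinatePenalties,
    Penalty,
    PenalizedFit,
    bic_select,
    nu_grid,
    penalized_et_estimate,
)

__all__ = ["PETLResult", "penalized_et_fit", "make_block_penalties"]


def make_block_penalties(
    s: int,
    p: int,
    family: str,
    nu1: float,
    nu2: float,
    scad_a: float = 3.7,
    unpenalized: tuple[int, ...] = (),
    adaptive_ref: np.ndarray | None = None,
) -> CoordinatePenalties:
    """Penalties on the beta block (coords 0..p-1) and gamma block (p..s-1),
    skipping ``unpenalized`` coordinates (intercepts)."""
    beta_idx = np.array([j for j in range(p) if j not in unpenalized], dtype=int)
    gamma_idx = np.array([j for j in range(p, s) if j not in unpenalized], dtype=int)

    def block_pen(idx, nu):
        if family == "alasso":
            ref = np.abs(adaptive_ref[idx]) if adaptive_ref is not None else np.ones(idx.size)
            w = 1.0 / np.clip(ref, 1e-3, None)
            return Penalty("alasso", nu=nu, adaptive_weights=w)
        return Penalty(family, nu=nu, shape=scad_a)

    blocks = []
    if beta_idx.size:
        blocks.append((beta_idx, block_pen(beta_idx, nu1)))
    if gamma_idx.size:
        blocks.append((gamma_idx, block_pen(gamma_idx, nu2)))
    return CoordinatePenalties(s, blocks)


@dataclass
class PETLResult:
    """A tuned penalized ET fit with everything needed for inference."""

    fit: PenalizedFit
    dense: ETFit
    system: StackedMomentSystem
    objective: ETObjective
    selection: BICSelection | None = None
    penalties: CoordinatePenalties | None = None
    bounds: tuple | None = None
    scales: np.ndarray | None = None   # internal coord = raw coord * scale
    config: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        """Coefficients on the raw covariate scale."""
        if self.scales is None:
            return self.fit.theta
        return self.fit.theta / self.scales

    @property
    def beta(self) -> np.ndarray:
        return self.theta[: self.system.p]

    @property
    def gamma(self) -> np.ndarray:
        return self.theta[self.system.p:]

    @property
    def support(self) -> np.ndarray:
        return self.fit.support


def penalized_et_fit(
    dataset: MissingDataset,
    model,
    penalty: str = "scad",
    nu: tuple[float, float] | None = None,
    grids: tuple | None = None,
    grid_num: int = 8,
    grid_span: tuple[float, float] = (0.01, 2.0),
    strategy: str = "sequential",
    scad_a: float = 3.7,
    d_fn=None,
    penalize_intercepts: bool = False,
    fixed_dim: bool = False,
    lasso_stage: bool | str = False,
    warm_paths: bool = True,
    backward_polish: bool = True,
    sign_canonical: bool = False,
    inner_tol: float = 1e-9,
    floor: float | None = None,
    local_radius: float | None = 2.0,
    local_radius_abs: float | None = None,
    standardize: bool = True,
    theta_init: np.ndarray | None = None,
) -> PETLResult:
    """Fit the SCAD/Lasso/adaptive-Lasso penalized ET likelihood.

    With ``nu=None`` the pair (nu1, nu2) is tuned by BIC over geometric grids
    spanning ``grid_span * sqrt(log(s)/n)``.  Intercepts (the first beta
    coordinate when the model has one, and the propensity intercept) are
    excluded from the penalty unless ``penalize_intercepts``.

    ``local_radius`` anchors every fit inside the box
    |theta_j - theta_init_j| <= local_radius * (1 + |theta_init_j|) around the
    complete-case initialiser.  The estimator's asymptotic theory is local,
    and designs violating the overlap / moment-boundedness conditions admit
    spurious distant optima of the profiled ET objective; the box keeps the
    nested optimisation in the initialiser's basin.  Pass None to disable.

    ``lasso_stage`` prepends a short Lasso-weighted LQA pass to each fit,
    which resolves penalty-identified directions the likelihood leaves flat
    (the factor-loading model); ``sign_canonical`` flips the final estimate so
    its largest-magnitude coordinate is positive (the loadings sign
    convention; the B -> -B ambiguity is exactly penalty-invariant).
    """
    scales = None
    if standardize and hasattr(model, "coef_scales"):
        # penalties are applied on the standardized-coefficient scale, as is
        # standard for penalized regression; covariate columns are divided by
        # their sample standard deviations (no centring) and coefficients are
        # reported back on the raw scale
        su = dataset.U.std(axis=0)
        sz = dataset.Z.std(axis=0)
        su[su < 1e-12] = 1.0
        sz[sz < 1e-12] = 1.0
        dataset = MissingDataset(
            Y=dataset.Y, U=dataset.U / su, Z=dataset.Z / sz,
            delta=dataset.delta, meta=dataset.meta,
        )
        scales = np.concatenate([model.coef_scales(su, sz), [1.0], su])
    kw = {} if floor is None else {"floor": floor}
    system = StackedMomentSystem(dataset, model, d_fn=d_fn, **kw)
    if scales is None:
        scales = np.ones(system.s)
    if scales.size != system.s:
        raise ValueError("coefficient scale vector does not match parameter dimension")
    theta0 = system.theta_init() if theta_init is None else np.asarray(theta_init, dtype=float)
    bounds = None
    if local_radius_abs is not None:
        # fixed-width D_n-style neighbourhood of the initialiser (the local
        # solution the asymptotic theory describes); used where the moment
        # system has exactly flat directions resolved only by the penalty
        bounds = (theta0 - local_radius_abs, theta0 + local_radius_abs)
    elif local_radius is not None:
        half = local_radius * (1.0 + np.abs(theta0))
        bounds = (theta0 - half, theta0 + half)
    dense = et_estimate(system, theta0, inner_tol=inner_tol, bounds=bounds)
    objective = ETObjective(system, inner_tol=inner_tol)

    unpen: tuple[int, ...] = ()
    if not penalize_intercepts:
        unpen = (system.p,)  # gamma intercept
        if getattr(model, "name", "") in ("linear_iv", "logistic"):
            unpen = (0, system.p)

    adaptive_ref = dense.theta if penalty == "alasso" else None

    def make_pens(nu1, nu2):
        return make_block_penalties(
            system.s, system.p, penalty, nu1, nu2, scad_a=scad_a,
            unpenalized=unpen, adaptive_ref=adaptive_ref,
        )

    def adaptive_grid(base: np.ndarray, block: np.ndarray, pen_idx: np.ndarray) -> np.ndarray:
        """Extend a tuning grid so its top reaches the scale of the dense
        estimate's penalized coordinates (90th magnitude percentile); the
        default span can sit far below the coefficient scale when covariate
        scales are extreme."""
        vals = np.abs(block[pen_idx]) if pen_idx.size else np.array([0.0])
        hi = max(float(base[0]), float(np.quantile(vals, 0.9)))
        return np.geomspace(hi, float(base[-1]), base.size)

    selection = None
    if nu is not None:
        pens = make_pens(*nu)
        init = dense.theta
        if lasso_stage:
            lasso = make_block_penalties(system.s, system.p, "lasso", nu[0], nu[1], unpenalized=unpen)
            init = penalized_et_estimate(objective, init, lasso, max_iter=25,
                                         allow_deletion=False, bounds=bounds).theta
        fit = penalized_et_estimate(objective, init, pens, bounds=bounds)
        fit.nu = tuple(float(v) for v in nu)
    else:
        if grids is None:
            base = nu_grid(system.s, system.n, num=grid_num, span=grid_span)
            beta_pen = np.array([j for j in range(system.p) if j not in unpen], dtype=int)
            gamma_pen = np.array([j for j in range(system.p, system.s) if j not in unpen], dtype=int)
            g1 = adaptive_grid(base, dense.theta, beta_pen)
            g2 = adaptive_grid(base, dense.theta, gamma_pen)
        else:
            g1, g2 = grids
        selection = bic_select(
            objective, dense.theta, make_pens, g1, g2,
            n=system.n, s=system.s, fixed_dim=fixed_dim,
            strategy=strategy, lasso_stage=lasso_stage, warm_paths=warm_paths,
            backward_polish=backward_polish,
            fit_kwargs={"bounds": bounds},
        )
        fit = selection.fit
        pens = make_pens(*fit.nu)

    if sign_canonical and fit.theta[: system.p].size:
        beta = fit.theta[: system.p]
        j = int(np.argmax(np.abs(beta)))
        if beta[j] < 0:
            flipped = fit.theta.copy()
            flipped[: system.p] = -beta
            # the moment value is invariant under B -> -B for the vech model;
            # re-evaluate to keep the embedded diagnostics consistent
            fit.theta = flipped
            fit.support = np.flatnonzero(np.abs(flipped) > 0)

    return PETLResult(
        fit=fit, dense=dense, system=system, objective=objective,
        selection=selection, penalties=pens, bounds=bounds, scales=scales,
        config={"penalty": penalty, "strategy": strategy, "grid_num": grid_num},
    )
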