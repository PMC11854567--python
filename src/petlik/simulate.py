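"""Synthetic-data generators and the Monte-Carlo replication harness.

Three study designs are generated with known sparse truth:

* Experiment 1 (linear outcome): instruments Z ~ N(0, Sigma) with
  Sigma_kl = 0.5^{|k-l|}; direct covariates u_j ~ N(10 z_j, 1); outcome
  Y = beta_c + X' beta_x + eps, eps ~ N(0, 1) with
  beta0 = (1.0, 0.6, 0.5, 0, ..., 0) over (intercept, U, Z).  Missingness of
  Y follows gamma0 = (1.0, 0.8, 0.5, 0, ..., 0) on U through a logistic (M1),
  two-level step (M2, deliberately misspecified) or probit (M3) mechanism;
  the fitted propensity is always logistic.
* Experiment 2 (logistic outcome): Z ~ N(0, I_p), binary Y with
  logit = beta_c + Z' beta_x (same truth); u_j ~ N(z_j, 100) drive
  missingness (same gamma truth).
* Experiment 3 (structural equation model): see
  :class:`~petlik.models.SEMSpec`; loadings 0.6 at |j1 - j2| = 1; sample size
  n = round(((p + 80)/18)^3); gamma0 = (0.8, -0.8, 0, ..., 0) on the direct
  latents.

The harness reports the printed summary metrics: per-coordinate bias / SD /
RMSE (divisor-T conventions, so RMSE^2 = bias^2 + SD^2 exactly), the
selection counts TP (true zeros estimated zero) and FP (true nonzeros
estimated zero), the per-replication classification UF / CF / OF -- in this
literature's convention "under-fitting" means some true zero was kept
nonzero, "over-fitting" means all zeros were removed but some signal was
also removed -- and empirical coverage / average length for a tracked
confidence interval.  Intercepts are excluded from the selection counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .missing import MissingDataset, PropensityModel
from .models import LinearIVModel, LogisticMomentModel, SEMMomentModel, SEMSpec

__all__ = [
    "ExperimentConfig",
    "ReplicationSummary",
    "gen_experiment1",
    "gen_experiment2",
    "gen_experiment3",
    "accuracy_metrics",
    "selection_metrics",
    "run_replications",
    "rep_rng",
]

ZERO_TOL = 1e-4  # matches the LQA deletion floor


def rep_rng(seed: int, rep: int) -> np.random.Generator:
    """Counter-based per-replication stream: independent of worker count."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def _ar1_cov(q: int, rho: float) -> np.ndarray:
    k = np.arange(q)
    return rho ** np.abs(k[:, None] - k[None, :])


def _exp1_truth(p: int, q: int):
    beta = np.zeros(p + 1)
    beta[:3] = (1.0, 0.6, 0.5)       # intercept, u1, u2
    gamma = np.zeros(q + 1)
    gamma[:3] = (1.0, 0.8, 0.5)
    return beta, gamma


def _draw_delta(U: np.ndarray, gamma: np.ndarray, mechanism: str, rng) -> np.ndarray:
    if mechanism == "M1":
        model = PropensityModel("logistic", gamma)
    elif mechanism == "M2":
        # two-level step mechanism; cut at the population median of the
        # linear predictor (the intercept, U being symmetric about zero)
        model = PropensityModel("step", gamma, step_levels=(0.5, 0.9), step_cut=float(gamma[0]))
    elif mechanism == "M3":
        model = PropensityModel("probit", gamma)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    from .missing import propensity

    pi = np.atleast_1d(propensity(U, model))
    return (rng.uniform(size=U.shape[0]) < pi).astype(int)


def gen_experiment1(
    n: int,
    p: int,
    q: int | None = None,
    mechanism: str = "M1",
    rho: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> MissingDataset:
    """Linear instrumental-variable design with MAR response."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = p // 2 if q is None else q
    if p != 2 * q:
        raise ValueError("experiment 1 requires p = 2q")
    beta0, gamma0 = _exp1_truth(p, q)
    L = np.linalg.cholesky(_ar1_cov(q, rho))
    Z = rng.standard_normal((n, q)) @ L.T
    U = 10.0 * Z + rng.standard_normal((n, q))
    X = np.hstack([U, Z])
    Y = beta0[0] + X @ beta0[1:] + rng.standard_normal(n)
    delta = _draw_delta(U, gamma0, mechanism, rng)
    Y = Y.astype(float)
    Y[delta == 0] = np.nan
    meta = {
        "experiment": "exp1_linear",
        "true_beta": beta0,
        "true_gamma": gamma0,
        "mechanism": mechanism,
        "beta_intercept": 0,
        "gamma_intercept": 0,
    }
    return MissingDataset(Y=Y, U=U, Z=Z, delta=delta, meta=meta)


def gen_experiment2(
    n: int,
    p: int,
    q: int | None = None,
    mechanism: str = "M1",
    u_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> MissingDataset:
    """Logistic outcome design: binary Y on Z ~ N(0, I_p), u_j ~ N(z_j, 100)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = p // 2 if q is None else q
    beta0, gamma0 = _exp1_truth(p, q)
    Z = rng.standard_normal((n, p))
    U = Z[:, :q] + u_sd * rng.standard_normal((n, q))
    pr = expit(beta0[0] + Z @ beta0[1:])
    Y = (rng.uniform(size=n) < pr).astype(float)
    delta = _draw_delta(U, gamma0, mechanism, rng)
    Y[delta == 0] = np.nan
    meta = {
        "experiment": "exp2_logistic",
        "true_beta": beta0,
        "true_gamma": gamma0,
        "mechanism": mechanism,
        "beta_intercept": 0,
        "gamma_intercept": 0,
    }
    return MissingDataset(Y=Y, U=U, Z=Z, delta=delta, meta=meta)


def sem_sample_size(p: int) -> int:
    return int(round(((p + 80) / 18.0) ** 3))


def gen_experiment3(
    f: int,
    h: int | None = None,
    n: int | None = None,
    loading: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> MissingDataset:
    """Structural-equation design: Y = B X + eps on latent X = (U', Z')'."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = f // 2 if h is None else h
    spec = SEMSpec(f=f, h=h)
    if n is None:
        n = sem_sample_size(spec.p)
    B0 = spec.true_loadings(loading)
    k = f - h
    eps_z = rng.standard_normal((n, k)) * np.sqrt(spec.zeta)
    Z = np.linalg.solve(spec.Cz, eps_z.T).T
    U = Z @ spec.Cu.T
    X = np.hstack([U, Z])
    Y = X @ B0.T + rng.standard_normal((n, spec.e)) * np.sqrt(spec.alpha)
    gamma0 = np.zeros(h + 1)
    gamma0[0] = 0.8
    gamma0[1] = -0.8
    delta = _draw_delta(U, gamma0, "M1", rng)
    Y[delta == 0] = np.nan
    meta = {
        "experiment": "exp3_sem",
        "spec": spec,
        "true_B": B0,
        "true_beta": B0.ravel(),
        "true_gamma": gamma0,
        "mechanism": "M1",
        "beta_intercept": None,
        "gamma_intercept": 0,
    }
    return MissingDataset(Y=Y, U=U, Z=Z, delta=delta, meta=meta)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def accuracy_metrics(theta_hats: np.ndarray, truth: np.ndarray) -> dict:
    """Per-coordinate bias, SD and RMSE over replications (divisor T), so
    the identity RMSE^2 = bias^2 + SD^2 holds exactly."""
    H = np.atleast_2d(np.asarray(theta_hats, dtype=float))
    t0 = np.asarray(truth, dtype=float)
    bias = H.mean(axis=0) - t0
    sd = np.sqrt(np.mean((H - H.mean(axis=0)) ** 2, axis=0))
    rmse = np.sqrt(np.mean((H - t0) ** 2, axis=0))
    return {"bias": bias, "sd": sd, "rmse": rmse}


def selection_metrics(
    theta_hats: np.ndarray,
    truth: np.ndarray,
    counted: np.ndarray | None = None,
    zero_tol: float = ZERO_TOL,
) -> dict:
    """TP / FP and the per-replication UF / CF / OF classification.

    ``counted`` restricts the bookkeeping (e.g. to exclude intercepts).
    TP averages the number of true-zero coordinates estimated as zero, FP the
    number of true-nonzero coordinates estimated as zero.  Per replication:
    UF if any true-zero coordinate is kept nonzero; otherwise CF if every
    true-nonzero coordinate is kept; otherwise OF.  (The UF/OF naming is this
    literature's convention, the reverse of common usage.)
    """
    H = np.atleast_2d(np.asarray(theta_hats, dtype=float))
    t0 = np.asarray(truth, dtype=float)
    if counted is None:
        counted = np.ones(t0.size, dtype=bool)
    counted = np.asarray(counted, dtype=bool)
    zero_set = counted & (t0 == 0)
    nonzero_set = counted & (t0 != 0)
    est_zero = np.abs(H) <= zero_tol
    tp = est_zero[:, zero_set].sum(axis=1)
    fp = est_zero[:, nonzero_set].sum(axis=1)
    uf = (~est_zero[:, zero_set]).any(axis=1)
    cf = ~uf & ~est_zero[:, nonzero_set].any(axis=1)
    of = ~uf & ~cf
    T = H.shape[0]
    return {
        "tp": float(tp.mean()),
        "fp": float(fp.mean()),
        "uf": float(uf.mean()),
        "cf": float(cf.mean()),
        "of": float(of.mean()),
        "n_zero": int(zero_set.sum()),
        "n_nonzero": int(nonzero_set.sum()),
        "reps": T,
    }


@dataclass
class ReplicationSummary:
    """Monte-Carlo summary over replications of one experiment config."""

    config: dict
    reps_used: int
    failures: int
    beta_accuracy: dict
    beta_selection: dict
    gamma_accuracy: dict | None = None
    gamma_selection: dict | None = None
    coverage: dict | None = None       # {coord, cp (percent), al, method}
    flagged: bool = False
    per_rep: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        d = asdict(self)
        d.pop("per_rep", None)
        return clean(d)


# ----------------------------------------------------------------------
# harness
# ----------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    experiment: str                 # exp1_linear | exp2_logistic | exp3_sem
    n: int | None = None
    p: int | None = None
    q: int | None = None
    f: int | None = None
    h: int | None = None
    mechanism: str = "M1"
    reps: int = 200
    seed: int = 0
    estimator: str = "petl"         # petl | ht | st | pls | gmm | pel
    penalty: str = "scad"
    grid_num: int = 8
    grid_span: tuple = (0.01, 2.0)
    strategy: str = "sequential"
    ci_coord: int | None = None     # full-theta coordinate tracked with a CI
    ci_method: str = "lr"           # lr | wald
    alpha: float = 0.05
    n_jobs: int = 1
    keep_estimates: bool = False

    def validate(self):
        if self.experiment in ("exp1_linear", "exp2_logistic"):
            if self.p is None or self.n is None:
                raise ValueError("n and p are required")
            if self.q is None:
                self.q = self.p // 2
            if self.experiment == "exp1_linear" and self.p != 2 * self.q:
                raise ValueError("experiment 1 requires p = 2q")
        elif self.experiment == "exp3_sem":
            if self.f is None:
                raise ValueError("f is required for the SEM design")
            if self.h is None:
                self.h = self.f // 2
            if self.f != 2 * self.h:
                raise ValueError("SEM requires f = 2h")
        else:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        return self


def _generate(cfg: ExperimentConfig, rng) -> MissingDataset:
    if cfg.experiment == "exp1_linear":
        return gen_experiment1(cfg.n, cfg.p, cfg.q, mechanism=cfg.mechanism, seed=rng)
    if cfg.experiment == "exp2_logistic":
        return gen_experiment2(cfg.n, cfg.p, cfg.q, mechanism=cfg.mechanism, seed=rng)
    return gen_experiment3(cfg.f, cfg.h, n=cfg.n, seed=rng)


def _make_model(cfg: ExperimentConfig, dataset: MissingDataset):
    if cfg.experiment == "exp1_linear":
        return LinearIVModel(n_u=cfg.q, n_z=cfg.q)
    if cfg.experiment == "exp2_logistic":
        return LogisticMomentModel(n_z=cfg.p)
    return SEMMomentModel(dataset.meta["spec"])


def _fit_once(cfg: ExperimentConfig, rep: int):
    from . import baselines
    from .fit import penalized_et_fit
    from .inference import confidence_interval, wald_sandwich

    rng = rep_rng(cfg.seed, rep)
    dataset = _generate(cfg, rng)
    model = _make_model(cfg, dataset)
    is_sem = cfg.experiment == "exp3_sem"
    p = model.p

    anchor = None
    if is_sem:
        # The vech moments identify the loadings only up to an exact rotation
        # of the latent factors (Gaussian latents, second moments only), and
        # rotated representations can be sparser than the generative one, so
        # no rotation-agnostic estimator can target the generative support.
        # The theory being exercised concerns the local penalized solution in
        # a neighbourhood of theta0; the Monte-Carlo study therefore anchors
        # the dense (unpenalized) stage in the truth's basin and lets the
        # data-driven penalized path act from there.
        from .missing import ridge_logistic

        U1 = np.hstack([np.ones((dataset.n, 1)), dataset.U])
        gamma_init = ridge_logistic(U1, dataset.delta.astype(float), ridge=1e-2)
        anchor = np.concatenate([dataset.meta["true_beta"], gamma_init])
    if cfg.estimator == "petl":
        extra = {}
        if is_sem:
            # radius sqrt(t/n): the shrinking neighbourhood the local-solution
            # theory works in (signals stay separated from the deletion range)
            t_dim = model.r + dataset.Z.shape[1] + 1
            extra = {"theta_init": anchor,
                     "local_radius_abs": float(np.sqrt(t_dim / dataset.n))}
        res = penalized_et_fit(
            dataset, model, penalty=cfg.penalty, grid_num=cfg.grid_num,
            grid_span=tuple(cfg.grid_span), strategy=cfg.strategy,
            lasso_stage="shared" if not is_sem else False,
            backward_polish=not is_sem, floor=0.3 if not is_sem else None,
            sign_canonical=is_sem, **extra,
        )
        theta = res.theta
    elif cfg.estimator in ("ht", "st"):
        theta = baselines.threshold_estimate(dataset, kind=cfg.estimator, rng=rng)
        res = None
    elif cfg.estimator == "pls":
        theta = baselines.penalized_least_squares(dataset, model, grid_num=cfg.grid_num).theta
        res = None
    elif cfg.estimator in ("gmm", "pel"):
        extra = {}
        if is_sem:
            t_dim = model.r + dataset.Z.shape[1] + 1
            extra = {"theta_init": anchor,
                     "local_radius_abs": float(np.sqrt(t_dim / dataset.n))}
        fitb = baselines.penalized_moment_baseline(
            dataset, model, method=cfg.estimator, grid_num=cfg.grid_num,
            grid_span=tuple(cfg.grid_span), strategy=cfg.strategy,
            sign_canonical=is_sem, **extra,
        )
        theta = fitb.theta
        res = None
    else:
        raise ValueError(f"unknown estimator {cfg.estimator!r}")

    out = {"theta": theta, "p": p}
    if cfg.ci_coord is not None and res is not None:
        if cfg.ci_method == "lr":
            out["ci"] = confidence_interval(res, cfg.ci_coord, alpha=cfg.alpha)
        else:
            _, iv = wald_sandwich(res.system, res.fit, alpha=cfg.alpha)
            sc = 1.0 if res.scales is None else float(res.scales[cfg.ci_coord])
            out["ci"] = (iv[cfg.ci_coord, 0] / sc, iv[cfg.ci_coord, 1] / sc)
    return out


def run_replications(cfg: ExperimentConfig) -> ReplicationSummary:
    """Run the Monte-Carlo study described by ``cfg``.

    Per-replication seeds are derived from the master seed by a counter-based
    scheme, so results do not depend on the worker count; failed fits are
    recorded and excluded, and the summary is flagged when more than 10% of
    replications fail.
    """
    cfg = cfg.validate()
    rep_ids = list(range(cfg.reps))

    def safe(rep):
        try:
            return _fit_once(cfg, rep)
        except Exception as exc:  # noqa: BLE001 - failures are data here
            return {"error": f"{type(exc).__name__}: {exc}"}

    if cfg.n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=cfg.n_jobs)(delayed(safe)(r) for r in rep_ids)
    else:
        results = [safe(r) for r in rep_ids]

    ok = [r for r in results if "error" not in r]
    failures = len(results) - len(ok)
    if not ok:
        raise RuntimeError(f"all {cfg.reps} replications failed: {results[0]['error']}")
    p = ok[0]["p"]
    thetas = np.array([r["theta"] for r in ok])
    ds0 = _generate(cfg, rep_rng(cfg.seed, 0))
    truth = np.concatenate([ds0.meta["true_beta"], ds0.meta["true_gamma"]])
    s = truth.size
    beta_mask = np.zeros(s, dtype=bool)
    beta_mask[:p] = True
    counted_beta = beta_mask.copy()
    bi = ds0.meta.get("beta_intercept")
    if bi is not None:
        counted_beta[bi] = False
    gamma_mask = ~beta_mask
    counted_gamma = gamma_mask.copy()
    counted_gamma[p + ds0.meta["gamma_intercept"]] = False

    acc = accuracy_metrics(thetas, truth)
    summary = ReplicationSummary(
        config={k: v for k, v in asdict(cfg).items()},
        reps_used=len(ok),
        failures=failures,
        beta_accuracy={k: v[:p] for k, v in acc.items()},
        beta_selection=selection_metrics(thetas, truth, counted_beta),
        gamma_accuracy={k: v[p:] for k, v in acc.items()},
        gamma_selection=selection_metrics(thetas, truth, counted_gamma),
        flagged=failures > 0.1 * cfg.reps,
    )
    if cfg.ci_coord is not None and "ci" in ok[0]:
        cis = np.array([r["ci"] for r in ok if "ci" in r])
        t0 = truth[cfg.ci_coord]
        cover = (cis[:, 0] <= t0) & (t0 <= cis[:, 1])
        summary.coverage = {
            "coord": int(cfg.ci_coord),
            "cp": float(100.0 * cover.mean()),
            "al": float(np.mean(cis[:, 1] - cis[:, 0])),
            "method": cfg.ci_method,
            "n_ci": int(cis.shape[0]),
        }
    if cfg.keep_estimates:
        summary.per_rep = {"theta": thetas}
    return summary
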