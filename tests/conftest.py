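import numpy as np
import pytest
from scipy.special import expit

from petlik import MissingDataset, LinearIVModel
from petlik.missing import StackedMomentSystem


def make_benign_linear(n: int, q: int, seed: int = 0, missing: bool = True) -> MissingDataset:
    """A well-behaved MAR linear design: unit-scale covariates, overlap
    bounded away from zero.  Used to exercise the estimator where its
    assumptions hold."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, q))
    U = Z + rng.standard_normal((n, q))
    X = np.hstack([U, Z])
    beta = np.zeros(2 * q + 1)
    beta[:3] = (1.0, 0.6, 0.5)
    Y = beta[0] + X @ beta[1:] + rng.standard_normal(n)
    if missing:
        pi = expit(0.5 + 0.8 * U[:, 0] + 0.5 * U[:, 1])
        delta = (rng.uniform(size=n) < pi).astype(int)
    else:
        delta = np.ones(n, dtype=int)
    Y = Y.astype(float)
    Y[delta == 0] = np.nan
    meta = {"true_beta": beta, "true_gamma": np.array([0.5, 0.8, 0.5] + [0.0] * (q - 2))}
    return MissingDataset(Y=Y, U=U, Z=Z, delta=delta, meta=meta)


@pytest.fixture(scope="session")
def exp1_main_summary():
    """Experiment 1, mechanism M1, (n, p+1, q+1) = (500, 23, 12), SCAD + BIC,
    200 replications (shared by the acceptance checks and trend tests)."""
    from petlik.simulate import ExperimentConfig, run_replications

    cfg = ExperimentConfig(experiment="exp1_linear", n=500, p=22, q=11,
                           mechanism="M1", reps=200, seed=11, grid_num=8)
    return run_replications(cfg)


@pytest.fixture(scope="session")
def exp1_small_summary():
    """Experiment 1, (50, 9, 5), 300 replications."""
    from petlik.simulate import ExperimentConfig, run_replications

    cfg = ExperimentConfig(experiment="exp1_linear", n=50, p=8, q=4,
                           mechanism="M1", reps=300, seed=12, grid_num=8)
    return run_replications(cfg)


@pytest.fixture
def benign_small():
    return make_benign_linear(120, 3, seed=7)


@pytest.fixture
def benign_complete():
    return make_benign_linear(150, 3, seed=8, missing=False)


@pytest.fixture
def benign_system(benign_small):
    model = LinearIVModel(3, 3)
    return StackedMomentSystem(benign_small, model)
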