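import itertools

import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-truth cohort shared by read-only tests."""
    cfg = bs.default_ground_truth(n_subjects=8, n_timepoints=150, seed=11)
    return bs.simulate_behavior(bs.simulate_cohort(cfg))


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Trigger JIT compilation once so per-test timings stay honest."""
    cfg = bs.default_ground_truth(n_subjects=3, n_timepoints=60, seed=0)
    co = bs.simulate_cohort(cfg)
    bs.fit_hmm(co.series, 2, n_restarts=1, seed=0, max_iter=3)


def random_instance(rng, k, t_len, n=2):
    """A random Gaussian HMM instance plus one observation sequence."""
    means = rng.normal(size=(k, n)) * 2
    covs = np.stack([np.eye(n) * rng.uniform(0.5, 1.5) for _ in range(k)])
    a = rng.dirichlet(np.ones(k) * 2, size=k)
    pi = rng.dirichlet(np.ones(k) * 2)
    x = rng.normal(size=(t_len, n))
    return x, means, covs, a, pi


def enumerate_paths(x, means, covs, a, pi):
    """Exhaustive-path oracle: exact posterior, log-evidence and best path.

    Enumerates all k^T state paths; ties in the best path resolve to the
    lexicographically smallest (lower state indices first).
    """
    from scipy.stats import multivariate_normal

    t_len = x.shape[0]
    k = means.shape[0]
    logb = np.stack(
        [multivariate_normal.logpdf(x, means[j], covs[j]) for j in range(k)],
        axis=1,
    )
    if logb.ndim == 1:
        logb = logb[:, None]
    paths = np.array(list(itertools.product(range(k), repeat=t_len)))  # lex order
    logps = np.log(pi[paths[:, 0]]) + logb[0, paths[:, 0]]
    for t in range(1, t_len):
        logps = logps + np.log(a[paths[:, t - 1], paths[:, t]]) + logb[t, paths[:, t]]
    logz = np.logaddexp.reduce(logps)
    w = np.exp(logps - logz)
    post = np.zeros((t_len, k))
    for t in range(t_len):
        post[t] = np.bincount(paths[:, t], weights=w, minlength=k)
    best_path = paths[np.argmax(logps)]  # argmax takes the lex-smallest tie
    return post, logz, best_path
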