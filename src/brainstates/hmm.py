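"""Multivariate-Gaussian-emission hidden Markov models for network time series.

The observation model assumes that at each fMRI time point the brain occupies
one of ``k`` latent states, and that the vector of network activities is drawn
from a state-specific multivariate normal distribution (mean "activity
loadings" plus a full covariance, whose correlation form is the state-specific
functional-connectivity matrix).  The latent sequence follows a first-order
Markov chain.  Fitting uses maximum-likelihood EM (Baum-Welch) on the
concatenation of all subjects, with the forward recursion restarting from the
initial distribution at each subject's first time point so that no transition
is counted across subject boundaries.  Several restarts from different k-means
initialisations are run and the restart with the highest training
log-likelihood ("evidence") is kept.

State labels are 0-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "NetworkTimeSeries",
    "GaussianHMMModel",
    "StatePosterior",
    "standardize",
    "fit_hmm",
    "posterior_probs",
    "viterbi_path",
    "align_state_labels",
    "permute_model_states",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_COV_REG = 1e-6  # ridge added to covariance diagonals each M-step


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkTimeSeries:
    """One subject's T x N network-activity matrix sampled every ``tr`` seconds."""

    subject_id: str
    data: np.ndarray  # (T, N), z-units after standardize()
    tr: float = 2.0
    narrative: str | None = None
    condition: str = "task"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x network) array")
        if self.data.shape[0] < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in series {self.subject_id!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_networks(self) -> int:
        return self.data.shape[1]


@dataclass
class GaussianHMMModel:
    """A fitted k-state Gaussian HMM.

    ``means`` holds the per-state activity loadings on the N networks,
    ``covs`` the per-state full covariances, ``transition`` the row-stochastic
    between-state switching matrix and ``evidence`` the training
    log-likelihood of the selected restart.
    """

    k: int
    means: np.ndarray        # (k, N)
    covs: np.ndarray         # (k, N, N), SPD
    transition: np.ndarray   # (k, k), rows sum to 1
    initial: np.ndarray      # (k,), sums to 1
    evidence: float
    n_restarts: int = 1
    seed: int | None = None
    converged: bool = True
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_networks(self) -> int:
        return self.means.shape[1]

    def state_correlation(self, state: int) -> np.ndarray:
        """Correlation matrix implied by a state's covariance (per-state FC)."""
        c = self.covs[state]
        d = np.sqrt(np.diag(c))
        return c / np.outer(d, d)


@dataclass
class StatePosterior:
    """Per-time-point state expression probabilities and the Viterbi path."""

    gamma: np.ndarray  # (T, k), rows sum to 1
    path: np.ndarray   # (T,), int labels in {0..k-1}
    loglik: float


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(series: NetworkTimeSeries) -> NetworkTimeSeries:
    """Z-score each network's time course within the subject.

    Raises ``ValueError`` naming the offending column when a network has zero
    variance (no z-score exists for a constant signal).
    """
    x = series.data
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(
            f"zero-variance network column(s) {bad.tolist()} in series "
            f"{series.subject_id!r}"
        )
    return replace(series, data=(x - mu) / sd)


# ---------------------------------------------------------------------------
# numba kernels: scaled forward-backward, Viterbi
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fb_kernel(b, logbmax, A, pi, starts, ends):
    """Scaled forward-backward over concatenated segments.

    ``b`` holds emission likelihoods rescaled so the max per row is 1
    (``logbmax`` carries the subtracted per-row log maxima).  Returns the
    posterior ``gamma``, accumulated transition counts ``xi_sum``, the summed
    first-time-point posteriors and the total log-likelihood.
    """
    T, k = b.shape
    gamma = np.empty((T, k))
    xi_sum = np.zeros((k, k))
    start_sum = np.zeros(k)
    loglik = 0.0
    alpha = np.empty((T, k))
    c = np.empty(T)
    beta_next = np.empty(k)
    beta_cur = np.empty(k)
    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        # forward
        tot = 0.0
        for j in range(k):
            alpha[t0, j] = pi[j] * b[t0, j]
            tot += alpha[t0, j]
        c[t0] = tot
        for j in range(k):
            alpha[t0, j] /= tot
        for t in range(t0 + 1, t1):
            tot = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * b[t, j]
                tot += alpha[t, j]
            c[t] = tot
            for j in range(k):
                alpha[t, j] /= tot
        for t in range(t0, t1):
            loglik += np.log(c[t]) + logbmax[t]
        # backward + gamma + xi
        for j in range(k):
            beta_next[j] = 1.0
            gamma[t1 - 1, j] = alpha[t1 - 1, j]
        for t in range(t1 - 2, t0 - 1, -1):
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += A[i, j] * b[t + 1, j] * beta_next[j]
                beta_cur[i] = acc / c[t + 1]
            gsum = 0.0
            for i in range(k):
                gamma[t, i] = alpha[t, i] * beta_cur[i]
                gsum += gamma[t, i]
            for i in range(k):
                gamma[t, i] /= gsum
            for i in range(k):
                for j in range(k):
                    xi_sum[i, j] += (
                        alpha[t, i] * A[i, j] * b[t + 1, j] * beta_next[j]
                        / c[t + 1]
                    )
            for i in range(k):
                beta_next[i] = beta_cur[i]
        for j in range(k):
            start_sum[j] += gamma[t0, j]
    return gamma, xi_sum, start_sum, loglik


@njit(cache=False)
def _viterbi_kernel(logb, logA, logpi, starts, ends):
    """Most probable path per segment; ties resolved toward the lower index."""
    T, k = logb.shape
    path = np.empty(T, dtype=np.int64)
    best_total = 0.0
    delta = np.empty((T, k))
    psi = np.empty((T, k), dtype=np.int64)
    for s in range(starts.shape[0]):
        t0, t1 = starts[s], ends[s]
        for j in range(k):
            delta[t0, j] = logpi[j] + logb[t0, j]
        for t in range(t0 + 1, t1):
            for j in range(k):
                best = delta[t - 1, 0] + logA[0, j]
                arg = 0
                for i in range(1, k):
                    v = delta[t - 1, i] + logA[i, j]
                    if v > best:
                        best = v
                        arg = i
                delta[t, j] = best + logb[t, j]
                psi[t, j] = arg
        best = delta[t1 - 1, 0]
        arg = 0
        for j in range(1, k):
            if delta[t1 - 1, j] > best:
                best = delta[t1 - 1, j]
                arg = j
        best_total += best
        path[t1 - 1] = arg
        for t in range(t1 - 2, t0 - 1, -1):
            path[t] = psi[t + 1, path[t + 1]]
    return path, best_total


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------

def _emission_logprob(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log N(x_t | mu_j, Sigma_j) for every time point and state, via Cholesky."""
    t_tot, n = x.shape
    k = means.shape[0]
    out = np.empty((t_tot, k))
    for j in range(k):
        try:
            chol = np.linalg.cholesky(covs[j])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"state {j} covariance is not positive definite") from exc
        diff = x - means[j]
        y = solve_triangular(chol, diff.T, lower=True)
        out[:, j] = (
            -0.5 * (n * _LOG2PI + np.sum(y * y, axis=0))
            - np.sum(np.log(np.diag(chol)))
        )
    return out


def _segments(series_list: Sequence[NetworkTimeSeries]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = [s.n_timepoints for s in series_list]
    ends = np.cumsum(lengths)
    starts = ends - np.asarray(lengths)
    x = np.vstack([s.data for s in series_list])
    return x, starts.astype(np.int64), ends.astype(np.int64)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _init_params(x: np.ndarray, k: int, rs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if k == 1:
        means = x.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=1, max_iter=50, random_state=rs)
        km.fit(x)
        means = km.cluster_centers_
        # canonical ordering so restarts differ only through the rs stream
        order = np.lexsort(means.T[::-1])
        means = means[order]
    pooled = np.cov(x, rowvar=False)
    pooled = np.atleast_2d(pooled) + _COV_REG * np.eye(x.shape[1])
    covs = np.repeat(pooled[None, :, :], k, axis=0)
    if k == 1:
        trans = np.ones((1, 1))
    else:
        trans = np.full((k, k), 0.1 / (k - 1))
        np.fill_diagonal(trans, 0.9)
    initial = np.full(k, 1.0 / k)
    return means, covs, trans, initial


def _em_run(
    x: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    k: int,
    rs: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, bool, np.ndarray]:
    means, covs, trans, initial = _init_params(x, k, rs)
    n_seg = starts.shape[0]
    history = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        logb = _emission_logprob(x, means, covs)
        bmax = logb.max(axis=1)
        b = np.exp(logb - bmax[:, None])
        gamma, xi_sum, start_sum, ll = _fb_kernel(b, bmax, trans, initial, starts, ends)
        history.append(ll)
        if np.isfinite(prev_ll) and ll - prev_ll < tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M-step
        w = gamma.sum(axis=0)
        means = (gamma.T @ x) / w[:, None]
        for j in range(k):
            diff = x - means[j]
            covs[j] = (gamma[:, j][:, None] * diff).T @ diff / w[j]
            covs[j][np.diag_indices_from(covs[j])] += _COV_REG
        if k > 1:
            trans = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        initial = start_sum / n_seg
    return means, covs, trans, initial, history[-1], converged, np.asarray(history)


def fit_hmm(
    series_list: Sequence[NetworkTimeSeries],
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GaussianHMMModel:
    """Fit a k-state Gaussian HMM to the concatenated cohort by EM with restarts.

    The chain restarts from the initial distribution at each subject boundary,
    so transitions are never pooled across subjects.  Each restart initialises
    the means by a seeded k-means on the concatenated data; the restart with
    the highest training log-likelihood is returned.  Subjects are processed
    in sorted ``subject_id`` order, making the fit invariant to the order of
    ``series_list``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not series_list:
        raise ValueError("no series supplied")
    n_set = {s.n_networks for s in series_list}
    if len(n_set) > 1:
        raise ValueError(f"inconsistent network counts {sorted(n_set)}")
    ordered = sorted(series_list, key=lambda s: s.subject_id)
    x, starts, ends = _segments(ordered)
    if x.shape[0] <= k * x.shape[1]:
        raise ValueError(
            f"too few time points ({x.shape[0]}) for k={k} states in "
            f"{x.shape[1]} networks"
        )
    ss = np.random.SeedSequence([int(seed), k])
    restart_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_restarts)]
    best = None
    for rs in restart_seeds:
        res = _em_run(x, starts, ends, k, rs, max_iter, tol)
        if best is None or res[4] > best[4]:
            best = res
    means, covs, trans, initial, ll, converged, history = best
    return GaussianHMMModel(
        k=k,
        means=means,
        covs=covs,
        transition=trans,
        initial=initial,
        evidence=float(ll),
        n_restarts=n_restarts,
        seed=seed,
        converged=converged,
        loglik_history=history,
    )


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _check_dims(series: NetworkTimeSeries, model: GaussianHMMModel) -> None:
    if series.n_networks != model.n_networks:
        raise ValueError(
            f"series has {series.n_networks} networks but model expects "
            f"{model.n_networks}"
        )


def posterior_probs(series: NetworkTimeSeries, model: GaussianHMMModel) -> StatePosterior:
    """State expression probabilities (gamma) from scaled forward-backward,
    plus the Viterbi path, for one subject under a fitted model."""
    _check_dims(series, model)
    x = series.data
    t = x.shape[0]
    starts = np.array([0], dtype=np.int64)
    ends = np.array([t], dtype=np.int64)
    logb = _emission_logprob(x, model.means, model.covs)
    bmax = logb.max(axis=1)
    b = np.exp(logb - bmax[:, None])
    gamma, _, _, ll = _fb_kernel(b, bmax, model.transition, model.initial, starts, ends)
    with np.errstate(divide="ignore"):
        path, _ = _viterbi_kernel(
            logb, np.log(model.transition), np.log(model.initial), starts, ends
        )
    return StatePosterior(gamma=gamma, path=path, loglik=float(ll))


def viterbi_path(series: NetworkTimeSeries, model: GaussianHMMModel) -> StatePosterior:
    """Most probable joint state sequence (ties broken toward the lower state
    index); ``gamma`` and ``loglik`` are included for convenience."""
    return posterior_probs(series, model)


# ---------------------------------------------------------------------------
# label alignment between independently fitted models
# ---------------------------------------------------------------------------

def align_state_labels(candidate: GaussianHMMModel, reference: GaussianHMMModel) -> np.ndarray:
    """Permutation ``perm`` such that candidate state ``perm[i]`` matches
    reference state ``i``, maximising the summed Pearson correlation between
    matched mean vectors (optimal assignment).  Resolves HMM label switching
    before any recovery or cross-run comparison.
    """
    if candidate.k != reference.k:
        raise ValueError("models must have the same number of states")
    r = np.corrcoef(reference.means, candidate.means)[: reference.k, reference.k:]
    _, cols = linear_sum_assignment(-r)
    return cols


def permute_model_states(model: GaussianHMMModel, perm: np.ndarray) -> GaussianHMMModel:
    """Relabel model states so that new state ``i`` is old state ``perm[i]``."""
    perm = np.asarray(perm)
    return replace(
        model,
        means=model.means[perm],
        covs=model.covs[perm],
        transition=model.transition[np.ix_(perm, perm)],
        initial=model.initial[perm],
    )
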