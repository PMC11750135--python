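"""State dynamics summaries and circular-shift surrogate nulls.

Fractional occupancy and mean dwell time are computed from the Viterbi path.
The transition-hub statistic asks whether two states both prefer switching to
a third "hub" state over switching directly between themselves; its null
distribution is built by independently circular-shifting every network column
of every subject (which preserves each column's marginal and autocorrelation
while destroying between-network covariance) and refitting the HMM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hmm import GaussianHMMModel, NetworkTimeSeries, fit_hmm

__all__ = [
    "DynamicsSummary",
    "SurrogateNull",
    "fractional_occupancy",
    "mean_dwell_time",
    "hub_asymmetry",
    "detect_hub",
    "hub_statistic",
    "circular_shift_columns",
    "transition_surrogate_null",
    "occupancy_surrogate_percentile",
    "summarize_dynamics",
]


@dataclass
class DynamicsSummary:
    """Per-subject occupancy/dwell summaries plus the model's transition
    structure and hub asymmetries."""

    fo: np.ndarray            # (n_subjects, k), rows sum to 1
    mean_dwell_s: np.ndarray  # (n_subjects, k), NaN where a state is unvisited
    transition: np.ndarray    # (k, k) from the fitted model
    hub_state: int | None
    hub_asym: tuple[float, float, float] | None  # (d_a, d_b, mean)


@dataclass
class SurrogateNull:
    """An observed statistic against a surrogate null distribution."""

    n_perm: int
    values: np.ndarray
    observed: float
    empirical_p: float   # add-one convention, in (0, 1]
    percentile: float    # fraction of null strictly below observed
    seed: int
    n_refit_failures: int = 0


def fractional_occupancy(path: np.ndarray, k: int) -> np.ndarray:
    """Fraction of time points spent in each state (sums to 1)."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    if path.min() < 0 or path.max() >= k:
        raise ValueError("path labels outside {0..k-1}")
    return np.bincount(path, minlength=k) / path.size


def _run_lengths(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    return path[starts], ends - starts


def mean_dwell_time(path: np.ndarray, tr: float, k: int | None = None) -> np.ndarray:
    """Mean contiguous-run duration per state, in seconds.

    States never visited get NaN (a dwell time of zero would be misleading).
    """
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    if k is None:
        k = int(path.max()) + 1
    states, lengths = _run_lengths(path)
    out = np.full(k, np.nan)
    for s in range(k):
        mask = states == s
        if mask.any():
            out[s] = lengths[mask].mean() * tr
    return out


def hub_asymmetry(
    transition: np.ndarray, hub: int, peripheral: tuple[int, int]
) -> tuple[float, float, float]:
    """Transition-probability asymmetries toward a hub state.

    d_a = P(perA -> hub) - P(perA -> perB), d_b likewise from perB; returns
    (d_a, d_b, mean).
    """
    a, b = peripheral
    if len({hub, a, b}) != 3:
        raise ValueError("hub and peripheral indices must be distinct")
    rowsum = transition.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-6):
        raise ValueError("transition rows must sum to 1")
    d_a = float(transition[a, hub] - transition[a, b])
    d_b = float(transition[b, hub] - transition[b, a])
    return d_a, d_b, (d_a + d_b) / 2.0


def detect_hub(transition: np.ndarray) -> int | None:
    """Hub state of a 3-state transition matrix, if any.

    State h is a hub when both other states give it more transition mass than
    they give each other.  Returns None when no state qualifies.
    """
    k = transition.shape[0]
    if k != 3:
        raise ValueError("hub detection is defined for 3-state models")
    for h in range(3):
        i, j = [s for s in range(3) if s != h]
        if transition[i, h] > transition[i, j] and transition[j, h] > transition[j, i]:
            return h
    return None


def hub_statistic(transition: np.ndarray) -> float:
    """Mean hub asymmetry when a hub pattern exists, else 0 (instances with
    no hub-like switching pattern contribute zeros to the null)."""
    h = detect_hub(transition)
    if h is None:
        return 0.0
    i, j = [s for s in range(3) if s != h]
    _, _, mean_asym = hub_asymmetry(transition, h, (i, j))
    return mean_asym


def circular_shift_columns(
    data: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Circularly shift each column by an independent uniform offset in
    {1..T-1}; preserves every column's marginal exactly."""
    t_len, n = data.shape
    out = np.empty_like(data)
    shifts = rng.integers(1, t_len, size=n)
    for c in range(n):
        out[:, c] = np.roll(data[:, c], shifts[c])
    return out


def transition_surrogate_null(
    cohort: Sequence[NetworkTimeSeries],
    k: int,
    n_perm: int,
    n_restarts: int = 2,
    seed: int = 0,
    observed_model: GaussianHMMModel | None = None,
    max_redraws: int = 3,
) -> SurrogateNull:
    """Null distribution of the hub-asymmetry statistic from circular-shift
    surrogates.

    Per permutation every network column of every subject is shifted by an
    independent uniform offset and the HMM is refit at the same k; the hub
    statistic of the refit model (0 when no hub pattern appears) enters the
    null.  The observed statistic comes from ``observed_model`` (fitted here
    when not supplied).  Failed refits are redrawn and counted.
    """
    if n_perm < 1:
        raise ValueError("at least one permutation required")
    if observed_model is None:
        observed_model = fit_hmm(cohort, k, n_restarts=max(n_restarts, 5), seed=seed)
    observed = hub_statistic(observed_model.transition)
    ss = np.random.SeedSequence([int(seed), 77])
    children = ss.spawn(n_perm)
    values = np.empty(n_perm)
    failures = 0
    for p in range(n_perm):
        child = children[p]
        for attempt in range(max_redraws + 1):
            rng = np.random.default_rng(child)
            shifted = [
                NetworkTimeSeries(
                    subject_id=s.subject_id,
                    data=circular_shift_columns(s.data, rng),
                    tr=s.tr,
                    narrative=s.narrative,
                    condition=s.condition,
                )
                for s in cohort
            ]
            fit_seed = int(child.generate_state(1)[0] % (2**31 - 1)) + attempt
            try:
                model = fit_hmm(shifted, k, n_restarts=n_restarts, seed=fit_seed)
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
                child = child.spawn(1)[0]
                continue
            values[p] = hub_statistic(model.transition)
            break
        else:
            raise RuntimeError(f"permutation {p} failed after {max_redraws} redraws")
    empirical_p = (1 + int(np.sum(values >= observed))) / (1 + n_perm)
    percentile = float(np.mean(values < observed))
    return SurrogateNull(
        n_perm=n_perm,
        values=values,
        observed=float(observed),
        empirical_p=float(empirical_p),
        percentile=percentile,
        seed=seed,
        n_refit_failures=failures,
    )


def occupancy_surrogate_percentile(observed: float, null_values: np.ndarray) -> float:
    """Fraction of null values strictly below the observed value."""
    null_values = np.asarray(null_values)
    if null_values.size == 0:
        raise ValueError("empty null")
    return float(np.mean(null_values < observed))


def summarize_dynamics(
    paths: Sequence[np.ndarray], model: GaussianHMMModel, tr: float
) -> DynamicsSummary:
    """Cohort-level dynamics summary from per-subject Viterbi paths."""
    k = model.k
    fo = np.vstack([fractional_occupancy(p, k) for p in paths])
    dwell = np.vstack([mean_dwell_time(p, tr, k) for p in paths])
    hub = detect_hub(model.transition) if k == 3 else None
    asym = None
    if hub is not None:
        i, j = [s for s in range(3) if s != hub]
        asym = hub_asymmetry(model.transition, hub, (i, j))
    return DynamicsSummary(
        fo=fo,
        mean_dwell_s=dwell,
        transition=model.transition,
        hub_state=hub,
        hub_asym=asym,
    )
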