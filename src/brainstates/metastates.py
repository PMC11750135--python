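"""Metastate reconstruction and cross-run state matching.

Finer HMMs (more states than the target space) can be reduced by
agglomerative clustering of their transition matrix: states that
preferentially switch among themselves form a "metastate".  Merged states
are compared to a predefined (reference) state set spatially — Pearson
correlation of mean activity patterns with a greedy confusion-resolving
assignment (a "primed" candidate is one that lost its top match to a
stronger candidate) — and temporally, by Jaccard overlap of the relabelled
state sequences.  Circular-shift surrogates give a null for the matched
similarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .dynamics import circular_shift_columns
from .hmm import GaussianHMMModel, NetworkTimeSeries, fit_hmm

__all__ = [
    "StateCorrespondence",
    "cluster_transitions",
    "merge_cluster_states",
    "spatial_match",
    "temporal_match",
    "temporal_jaccard",
    "correspondence_null",
]


@dataclass
class StateCorrespondence:
    """Mapping from candidate states to predefined states.

    ``mapping[c]`` is the predefined state assigned to candidate c,
    ``similarity[c]`` the matched Pearson r, and ``primed[c]`` is True when
    the candidate did not get its own top-correlated predefined state (the
    confusion case marked with a prime symbol in reports).
    """

    mapping: np.ndarray
    similarity: np.ndarray
    primed: np.ndarray
    basis: str  # "spatial" | "temporal"
    r_matrix: np.ndarray


def cluster_transitions(transition: np.ndarray, n_clusters: int) -> np.ndarray:
    """Agglomerative clustering of HMM states from the transition matrix.

    States that exchange a lot of transition probability belong to the same
    metastate, so the pairwise similarity is the symmetrised off-diagonal
    transition mass (A_ij + A_ji)/2, turned into a distance (1 - similarity)
    for average-linkage agglomeration.  On block-structured matrices this
    recovers the blocks: within-cluster transition mass exceeds
    between-cluster mass.  Returns 0-based cluster labels.
    """
    k = transition.shape[0]
    if n_clusters >= k:
        raise ValueError("n_clusters must be smaller than the number of states")
    sim = (transition + transition.T) / 2.0
    dist = 1.0 - sim
    condensed = dist[np.triu_indices(k, 1)]
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    return labels


def merge_cluster_states(
    model: GaussianHMMModel,
    clusters: np.ndarray,
    paths: Sequence[np.ndarray],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Merge clustered states: the merged mean is the unweighted average of
    member means, and each path label is replaced by its cluster id."""
    clusters = np.asarray(clusters)
    if clusters.shape[0] != model.k:
        raise ValueError("clusters must label every state")
    ids = np.unique(clusters)
    merged_means = np.vstack(
        [model.means[clusters == c].mean(axis=0) for c in ids]
    )
    remap = np.empty(model.k, dtype=np.int64)
    for new, c in enumerate(ids):
        remap[clusters == c] = new
    merged_paths = [remap[np.asarray(p)] for p in paths]
    return merged_means, merged_paths


def _greedy_match(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_cand, n_pre = r.shape
    mapping = np.full(n_cand, -1, dtype=np.int64)
    primed = np.zeros(n_cand, dtype=bool)
    taken: set[int] = set()
    unassigned = set(range(n_cand))
    while unassigned:
        # each unassigned candidate's best still-available predefined state
        best_c, best_p, best_r = None, None, -np.inf
        for c in unassigned:
            avail = [p for p in range(n_pre) if p not in taken]
            p = max(avail, key=lambda j: r[c, j])
            if r[c, p] > best_r:
                best_c, best_p, best_r = c, p, r[c, p]
        mapping[best_c] = best_p
        primed[best_c] = best_p != int(np.argmax(r[best_c]))
        taken.add(best_p)
        unassigned.remove(best_c)
    similarity = r[np.arange(n_cand), mapping]
    return mapping, similarity, primed


def spatial_match(
    candidates: np.ndarray, predefined: np.ndarray
) -> StateCorrespondence:
    """Match candidate states to predefined states by activity-pattern
    correlation, with greedy confusion resolution.

    Every candidate's top-correlated predefined state is computed; when two
    candidates share a top match the stronger keeps it and the weaker takes
    its best *unassigned* predefined state and is flagged primed.
    Assignment proceeds in descending order of correlation strength.
    """
    candidates = np.atleast_2d(candidates)
    predefined = np.atleast_2d(predefined)
    if candidates.shape != predefined.shape:
        raise ValueError("candidate and predefined sets must have equal shape")
    n = candidates.shape[0]
    r = np.corrcoef(candidates, predefined)[:n, n:]
    mapping, similarity, primed = _greedy_match(r)
    return StateCorrespondence(
        mapping=mapping,
        similarity=similarity,
        primed=primed,
        basis="spatial",
        r_matrix=r,
    )


def temporal_match(
    candidate_gammas: Sequence[np.ndarray],
    predefined_gammas: Sequence[np.ndarray],
) -> StateCorrespondence:
    """Match states by correlating concatenated expression time courses
    (used when spatial layouts are not comparable, e.g. across atlases)."""
    cand = np.vstack([np.concatenate([g[:, s] for g in candidate_gammas])
                      for s in range(candidate_gammas[0].shape[1])])
    pre = np.vstack([np.concatenate([g[:, s] for g in predefined_gammas])
                     for s in range(predefined_gammas[0].shape[1])])
    corr = spatial_match(cand, pre)
    corr.basis = "temporal"
    return corr


def temporal_jaccard(
    seq_a: np.ndarray, seq_b: np.ndarray
) -> tuple[dict[int, float], float]:
    """Per-state Jaccard overlap of two state sequences plus the overall
    fraction of time points with identical labels."""
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    per_state: dict[int, float] = {}
    for s in np.union1d(np.unique(a), np.unique(b)):
        inter = np.sum((a == s) & (b == s))
        union = np.sum((a == s) | (b == s))
        per_state[int(s)] = float(inter / union) if union else np.nan
    overall = float(np.mean(a == b))
    return per_state, overall


def correspondence_null(
    cohort: Sequence[NetworkTimeSeries],
    k: int,
    n_perm: int,
    seed: int = 0,
    reference_means: np.ndarray | None = None,
    n_restarts: int = 2,
) -> np.ndarray:
    """Null distribution of matched spatial similarities.

    Per permutation, every subject's network columns are circularly shifted,
    the HMM is refit at k, and the refit state means are matched to the
    reference means with the same greedy strategy; all matched r values are
    collected.  Returns an array of shape (n_perm, k).
    """
    if n_perm < 1:
        raise ValueError("at least one permutation required")
    if reference_means is None:
        reference_means = fit_hmm(cohort, k, n_restarts=max(n_restarts, 5), seed=seed).means
    ss = np.random.SeedSequence([int(seed), 55])
    children = ss.spawn(n_perm)
    out = np.empty((n_perm, k))
    for p, child in enumerate(children):
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
        fit_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        model = fit_hmm(shifted, k, n_restarts=n_restarts, seed=fit_seed)
        match = spatial_match(model.means, reference_means)
        out[p] = match.similarity
    return out
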