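"""Selection of the number of latent states by a dual criterion.

For each candidate K, a leave-one-subject-out loop fits the HMM on all other
subjects and decodes the held-out subject.  Two per-subject quantities are
averaged over the cohort: the Calinski-Harabasz score of the decoded state
labels on that subject's network time series (clustering quality) and the
accuracy of a K-nearest-neighbor classifier at identifying which narrative
the subject heard from the decoded expression time courses (cognitive
sensibility).  Both curves are z-scored across the K grid and summed; the
grid value maximising the summed z-score is selected (ties go to the
smallest K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hmm import (
    GaussianHMMModel,
    NetworkTimeSeries,
    StatePosterior,
    align_state_labels,
    fit_hmm,
    posterior_probs,
)

__all__ = [
    "KSelectionResult",
    "loso_decode",
    "calinski_harabasz",
    "narrative_decoding_accuracy",
    "select_num_states",
]

CH_CAP = 1e12  # sentinel for zero within-cluster dispersion


@dataclass
class KSelectionResult:
    k_grid: np.ndarray
    ch_scores: np.ndarray
    decode_accuracy: np.ndarray
    z_ch: np.ndarray
    z_acc: np.ndarray
    z_sum: np.ndarray
    k_star: int


def loso_decode(
    cohort: Sequence[NetworkTimeSeries],
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    reference: GaussianHMMModel | None = None,
) -> list[StatePosterior]:
    """Leave-one-subject-out decoding.

    For each subject, an HMM is trained on the remaining subjects (best of
    ``n_restarts``) and used to decode the held-out subject's expression
    probabilities and Viterbi path.  Each fold's state labels are aligned to
    the full-cohort model so that decoded sequences are comparable across
    folds.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    if reference is None:
        reference = fit_hmm(cohort, k, n_restarts=n_restarts, seed=seed)
    out: list[StatePosterior] = []
    for i, held_out in enumerate(cohort):
        rest = [s for j, s in enumerate(cohort) if j != i]
        try:
            fold_model = fit_hmm(rest, k, n_restarts=n_restarts, seed=seed)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"HMM fit failed in fold {i}") from exc
        perm = align_state_labels(fold_model, reference)
        post = posterior_probs(held_out, fold_model)
        inv = np.empty(k, dtype=np.int64)
        inv[perm] = np.arange(k)
        out.append(
            StatePosterior(
                gamma=post.gamma[:, perm],
                path=inv[post.path],
                loglik=post.loglik,
            )
        )
    return out


def calinski_harabasz(series: NetworkTimeSeries, labels: np.ndarray) -> float:
    """Calinski-Harabasz score of the decoded state labels on the subject's
    T x N time series: between-cluster over within-cluster dispersion, each
    normalised by its degrees of freedom.  Capped at 1e12 when the
    within-cluster dispersion vanishes."""
    x = series.data
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("CH undefined for a single cluster")
    t_len = x.shape[0]
    k = uniq.size
    grand = x.mean(axis=0)
    between = 0.0
    within = 0.0
    for s in uniq:
        xs = x[labels == s]
        c = xs.mean(axis=0)
        between += xs.shape[0] * float(np.sum((c - grand) ** 2))
        within += float(np.sum((xs - c) ** 2))
    if within == 0.0:
        return CH_CAP
    return (between / (k - 1)) / (within / (t_len - k))


def narrative_decoding_accuracy(
    decoded: Sequence[StatePosterior],
    narratives: Sequence[str],
    k_neighbors: int = 5,
) -> float:
    """Leave-one-subject-out KNN classification of the narrative heard.

    Features are the flattened decoded gamma matrices; Euclidean distance,
    majority vote among the k nearest neighbours, vote ties resolved by the
    single nearest neighbour.  Returns mean accuracy over subjects.
    """
    labels = np.asarray(narratives)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two narratives")
    shapes = {p.gamma.shape for p in decoded}
    if len(shapes) > 1:
        raise ValueError("decoded sequences have unequal shapes")
    feats = np.vstack([p.gamma.ravel() for p in decoded])
    n = feats.shape[0]
    d2 = (
        np.sum(feats**2, axis=1)[:, None]
        + np.sum(feats**2, axis=1)[None, :]
        - 2 * feats @ feats.T
    )
    correct = 0
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")
        order = order[order != i][: min(k_neighbors, n - 1)]
        votes, counts = np.unique(labels[order], return_counts=True)
        top = counts.max()
        winners = votes[counts == top]
        if winners.size == 1:
            pred = winners[0]
        else:
            pred = next(lab for lab in labels[order] if lab in winners)
        correct += pred == labels[i]
    return correct / n


def select_num_states(
    cohort: Sequence[NetworkTimeSeries],
    narratives: Sequence[str],
    k_grid: Sequence[int] = range(2, 11),
    n_restarts: int = 10,
    seed: int = 0,
    k_neighbors: int = 5,
) -> KSelectionResult:
    """Dual-criterion selection of K over a grid (default 2..10)."""
    k_grid = np.asarray(list(k_grid), dtype=int)
    if k_grid.size < 2:
        raise ValueError("grid must contain at least 2 values")
    ch = np.empty(k_grid.size)
    acc = np.empty(k_grid.size)
    for idx, k in enumerate(k_grid):
        decoded = loso_decode(cohort, int(k), n_restarts=n_restarts, seed=seed)
        per_subj_ch = [
            calinski_harabasz(s, p.path) for s, p in zip(cohort, decoded)
        ]
        ch[idx] = float(np.mean(per_subj_ch))
        acc[idx] = narrative_decoding_accuracy(decoded, narratives, k_neighbors)
    z_ch = _zscore_grid(ch)
    z_acc = _zscore_grid(acc)
    z_sum = z_ch + z_acc
    k_star = int(k_grid[np.argmax(z_sum)])  # argmax takes the first (smallest K) tie
    return KSelectionResult(
        k_grid=k_grid,
        ch_scores=ch,
        decode_accuracy=acc,
        z_ch=z_ch,
        z_acc=z_acc,
        z_sum=z_sum,
        k_star=k_star,
    )


def _zscore_grid(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd
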