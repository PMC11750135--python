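"""Inter-subject alignment of state expression and comprehension behavior.

A subject's "alignment" is the Pearson correlation of their state-expression
time course with a reference: either the best performer(s) within the same
narrative group, or the leave-one-out group mean.  Alignments are pooled
across narratives and correlated with comprehension scores; head-motion
similarity (framewise displacement) can be partialled out by the residual
method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import pearsonr

__all__ = [
    "BehaviorCorrelation",
    "framewise_displacement",
    "alignment_to_best",
    "alignment_to_group",
    "behavior_correlation",
]


@dataclass
class BehaviorCorrelation:
    r: float
    p: float
    partial_r: float | None = None
    partial_p: float | None = None
    n: int = 0


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement from 6 rigid-body parameters (3 translations in
    mm, 3 rotations in radians): sum of absolute backward differences, with
    rotations converted to mm on a 50 mm sphere (Power convention).
    FD[0] = 0."""
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a T x 6 array")
    if motion.shape[0] < 2:
        raise ValueError("need at least two time points")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate(([0.0], fd))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def alignment_to_best(
    gammas: Sequence[np.ndarray],
    scores: np.ndarray,
    narrative_labels: Sequence[str],
    state: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Alignment of each non-best subject with the best performer(s) of their
    narrative group.

    Within each narrative, the best performer(s) are the subject(s) with the
    maximal comprehension score; every other subject's alignment is the mean
    Pearson correlation of their gamma column with each best performer's.
    Returns (alignments, subject indices), best performers excluded.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(narrative_labels)
    vals, idxs = [], []
    for narrative in np.unique(labels):
        members = np.flatnonzero(labels == narrative)
        if members.size < 2:
            raise ValueError(f"narrative {narrative!r} has fewer than 2 subjects")
        best = members[scores[members] == scores[members].max()]
        for i in members:
            if i in best:
                continue
            rs = [_corr(gammas[i][:, state], gammas[j][:, state]) for j in best]
            vals.append(float(np.mean(rs)))
            idxs.append(int(i))
    return np.asarray(vals), np.asarray(idxs)


def alignment_to_group(
    gammas: Sequence[np.ndarray],
    state: int,
    narrative_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Leave-one-out alignment: each subject's gamma column correlated with
    the mean column of the remaining subjects of the same narrative."""
    n = len(gammas)
    labels = (
        np.asarray(narrative_labels)
        if narrative_labels is not None
        else np.asarray(["all"] * n)
    )
    out = np.empty(n)
    cols = np.stack([g[:, state] for g in gammas])
    for narrative in np.unique(labels):
        members = np.flatnonzero(labels == narrative)
        if members.size < 3:
            raise ValueError(
                f"narrative {narrative!r} needs at least 3 subjects for "
                "leave-one-out alignment"
            )
        for i in members:
            rest = cols[members[members != i]].mean(axis=0)
            out[i] = _corr(cols[i], rest)
    return out


def _residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def behavior_correlation(
    alignment: np.ndarray,
    scores: np.ndarray,
    covariate: np.ndarray | None = None,
) -> BehaviorCorrelation:
    """Pearson correlation between alignments and comprehension scores, with
    an optional partial correlation controlling a covariate (correlation of
    the OLS residuals of both variables on the covariate)."""
    alignment = np.asarray(alignment, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if alignment.size != scores.size:
        raise ValueError("alignment and scores must have equal length")
    if alignment.size < 4:
        raise ValueError("need at least 4 subjects")
    if alignment.std() == 0 or scores.std() == 0:
        raise ValueError("constant vector")
    r, p = pearsonr(alignment, scores)
    res = BehaviorCorrelation(r=float(r), p=float(p), n=alignment.size)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=np.float64)
        rx = _residualize(alignment, covariate)
        ry = _residualize(scores, covariate)
        if rx.std() <= 1e-10 * alignment.std() or ry.std() <= 1e-10 * scores.std():
            raise ValueError("zero residual variance after removing covariate")
        pr = float(np.corrcoef(rx, ry)[0, 1])
        # two-tailed p on n - 3 df (one covariate removed)
        df = alignment.size - 3
        t = pr * np.sqrt(df / max(1.0 - pr**2, np.finfo(float).tiny))
        pp = float(2.0 * stats.t.sf(abs(t), df))
        res.partial_r, res.partial_p = pr, pp
    return res
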