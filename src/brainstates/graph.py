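"""Weighted graph analysis of network functional connectivity.

Per-state FC matrices (from the time points a state occupies, or from the
model covariances) are treated as weighted undirected graphs over the N
networks.  Functional integration is measured by weighted global efficiency
(edge length = 1/weight after zeroing negative weights) and segregation by
Louvain modularity.  A resolution sweep with a modularity-weighted z-Rand
consistency score supports the parcellation-style community analysis on a
supplied FC matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.stats import ttest_rel

from .hmm import GaussianHMMModel, NetworkTimeSeries, StatePosterior

__all__ = [
    "Partition",
    "StateGraph",
    "TopologyContrast",
    "group_fc",
    "zrand",
    "louvain_sweep",
    "state_specific_fc",
    "global_efficiency",
    "modularity_q",
    "state_topology_contrast",
]


@dataclass
class Partition:
    labels: np.ndarray
    gamma: float
    q: float
    zrand_mean: float
    weighted_score: float
    best: bool = False


@dataclass
class StateGraph:
    state: int
    fc: np.ndarray
    geff: float
    q: float
    source: str  # "subject" | "model"


@dataclass
class TopologyContrast:
    """Per-subject per-state graph metrics with paired between-state tests."""

    geff: np.ndarray          # (n_included, k)
    q: np.ndarray             # (n_included, k)
    included_subjects: list[str]
    excluded_subjects: list[str]
    tests: dict               # (metric, i, j) -> (t, p)
    model_geff: np.ndarray    # (k,) from model-derived FC
    model_q: np.ndarray


def group_fc(cohort: Sequence[NetworkTimeSeries]) -> np.ndarray:
    """Subject-wise Pearson FC matrices averaged entrywise; unit diagonal."""
    if not cohort:
        raise ValueError("empty cohort")
    mats = []
    for s in cohort:
        if np.any(s.data.std(axis=0) == 0):
            raise ValueError(f"zero-variance column in series {s.subject_id!r}")
        mats.append(np.corrcoef(s.data, rowvar=False))
    fc = np.mean(mats, axis=0)
    np.fill_diagonal(fc, 1.0)
    return fc


# ---------------------------------------------------------------------------
# partition agreement (z-Rand, Traud-Kelsic-Mucha-Porter)
# ---------------------------------------------------------------------------

def zrand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """z-scored Rand coefficient between two partitions.

    The pair-counting Rand statistic w (node pairs co-assigned in both
    partitions) is standardised by its mean and variance under random
    permutation of one partition's labels, following the Traud-Kelsic-
    Mucha-Porter formulation.  Degenerate cases with zero variance (e.g. a
    single community) return 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same nodes")
    n = a.size
    big_m = n * (n - 1) / 2.0
    _, a_inv = np.unique(a, return_inverse=True)
    _, b_inv = np.unique(b, return_inverse=True)
    na = np.bincount(a_inv).astype(float)
    nb = np.bincount(b_inv).astype(float)
    cont = np.zeros((na.size, nb.size))
    np.add.at(cont, (a_inv, b_inv), 1.0)
    m1 = float(np.sum(na * (na - 1) / 2.0))
    m2 = float(np.sum(nb * (nb - 1) / 2.0))
    w = float(np.sum(cont * (cont - 1) / 2.0))
    mu = m1 * m2 / big_m
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m1 + 4 * np.sum(na**3)
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m2 + 4 * np.sum(nb**3)
    a1 = 4 * m1 - 2 * big_m
    b1 = 4 * m2 - 2 * big_m
    var = (
        big_m / 16.0
        - (a1**2) * (b1**2) / (256.0 * big_m**2)
        + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
        + ((a1**2 - 4 * c1 - 4 * big_m) * (b1**2 - 4 * c2 - 4 * big_m))
        / (64.0 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var <= 0:
        return 0.0
    return (w - mu) / np.sqrt(var)


def _threshold_graph(fc: np.ndarray) -> nx.Graph:
    w = fc.copy()
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    if not np.any(w > 0):
        raise ValueError("no positive weights remain after thresholding")
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=w[i, j])
    return g


def _louvain_labels(g: nx.Graph, gamma: float, seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(g, resolution=gamma, seed=seed)
    labels = np.empty(g.number_of_nodes(), dtype=np.int64)
    for cid, nodes in enumerate(comms):
        for node in nodes:
            labels[node] = cid
    return labels


def louvain_sweep(
    fc: np.ndarray,
    gammas: Sequence[float] | None = None,
    n_runs: int = 100,
    seed: int = 0,
) -> list[Partition]:
    """Louvain community detection swept over resolution values.

    Per gamma: ``n_runs`` seeded Louvain runs; agreement between runs is the
    mean pairwise z-Rand; the representative partition is the medoid (the run
    most similar to all others); the modularity-weighted score is
    q * mean z-Rand.  The sweep's argmax is flagged ``best``.  Default grid
    1.2 to 2.5 in steps of 0.01.
    """
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC matrix must be symmetric")
    if gammas is None:
        gammas = np.arange(1.2, 2.5 + 1e-9, 0.01)
    g = _threshold_graph(fc)
    results: list[Partition] = []
    for gi, gamma in enumerate(gammas):
        seeds = [
            int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence([int(seed), 11, gi]).spawn(n_runs)
        ]
        runs = [_louvain_labels(g, float(gamma), s) for s in seeds]
        # collapse duplicate partitions for the pairwise z-Rand computation
        canon: dict[tuple, int] = {}
        uniq: list[np.ndarray] = []
        counts: list[int] = []
        assign = np.empty(n_runs, dtype=int)
        for r_idx, lab in enumerate(runs):
            key = tuple(_canonical(lab))
            if key not in canon:
                canon[key] = len(uniq)
                uniq.append(lab)
                counts.append(0)
            assign[r_idx] = canon[key]
            counts[canon[key]] += 1
        u = len(uniq)
        zmat = np.zeros((u, u))
        for i in range(u):
            zmat[i, i] = zrand(uniq[i], uniq[i])
            for j in range(i + 1, u):
                zmat[i, j] = zmat[j, i] = zrand(uniq[i], uniq[j])
        cnt = np.asarray(counts, dtype=float)
        # mean z-Rand of each unique partition to all *other* runs
        per_run_mean = (zmat @ cnt - np.diag(zmat) * 1.0) / (n_runs - 1) if n_runs > 1 else np.diag(zmat)
        medoid = int(np.argmax(per_run_mean))
        total_pairs = n_runs * (n_runs - 1) / 2.0
        if total_pairs > 0:
            pair_sum = 0.0
            for i in range(u):
                pair_sum += zmat[i, i] * cnt[i] * (cnt[i] - 1) / 2.0
                for j in range(i + 1, u):
                    pair_sum += zmat[i, j] * cnt[i] * cnt[j]
            zmean = pair_sum / total_pairs
        else:
            zmean = float(np.diag(zmat).mean())
        labels = uniq[medoid]
        q = nx.community.modularity(
            g,
            [set(np.flatnonzero(labels == c)) for c in np.unique(labels)],
            resolution=float(gamma),
            weight="weight",
        )
        results.append(
            Partition(
                labels=labels,
                gamma=float(gamma),
                q=float(q),
                zrand_mean=float(zmean),
                weighted_score=float(q * zmean),
            )
        )
    best = int(np.argmax([p.weighted_score for p in results]))
    results[best].best = True
    return results


def _canonical(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(inv)
    nxt = 0
    for i, v in enumerate(inv):
        if v not in first:
            first[v] = nxt
            nxt += 1
        out[i] = first[v]
    return out


# ---------------------------------------------------------------------------
# state-specific graphs
# ---------------------------------------------------------------------------

def state_specific_fc(
    series: NetworkTimeSeries, path: np.ndarray, state: int
) -> np.ndarray:
    """Pearson FC over the time points the Viterbi path assigns to a state.

    Requires at least N + 2 such time points for a stable correlation.
    """
    mask = np.asarray(path) == state
    n = series.n_networks
    if mask.sum() < n + 2:
        raise ValueError(
            f"insufficient occupancy: state {state} visited {int(mask.sum())} "
            f"time points (need >= {n + 2})"
        )
    return np.corrcoef(series.data[mask], rowvar=False)


def global_efficiency(fc: np.ndarray) -> float:
    """Weighted global efficiency: mean over ordered node pairs of the
    inverse shortest-path length, with edge length 1/weight and negative
    weights removed."""
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    n = fc.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    w = fc.copy().astype(float)
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    d = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d[off]), 1.0 / d[off], 0.0)
    return float(inv.mean())


def modularity_q(
    fc: np.ndarray, gamma: float = 1.0, n_runs: int = 100, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Best Louvain modularity over ``n_runs`` seeded runs (negative weights
    zeroed); returns (q, community labels)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g = _threshold_graph(fc)
    seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence([int(seed), 13]).spawn(n_runs)
    ]
    best_q, best_labels = -np.inf, None
    for s in seeds:
        labels = _louvain_labels(g, gamma, s)
        q = nx.community.modularity(
            g,
            [set(np.flatnonzero(labels == c)) for c in np.unique(labels)],
            resolution=gamma,
            weight="weight",
        )
        if q > best_q:
            best_q, best_labels = q, labels
    return float(best_q), best_labels


def state_topology_contrast(
    cohort: Sequence[NetworkTimeSeries],
    posteriors: Sequence[StatePosterior],
    model: GaussianHMMModel,
    gamma: float = 1.0,
    n_runs: int = 20,
    seed: int = 0,
) -> TopologyContrast:
    """Per-subject per-state global efficiency and modularity with paired
    two-tailed t-tests between states, plus the model-derived variant (state
    covariances converted to correlation matrices).

    Subjects in which any state lacks sufficient occupancy are excluded (and
    listed).
    """
    k = model.k
    geffs, qs, included, excluded = [], [], [], []
    for s, post in zip(cohort, posteriors):
        try:
            fcs = [state_specific_fc(s, post.path, st) for st in range(k)]
        except ValueError:
            excluded.append(s.subject_id)
            continue
        geffs.append([global_efficiency(fc) for fc in fcs])
        qs.append([modularity_q(fc, gamma, n_runs, seed)[0] for fc in fcs])
        included.append(s.subject_id)
    if len(included) < 3:
        raise ValueError("fewer than 3 subjects with all states visited")
    geff = np.asarray(geffs)
    q = np.asarray(qs)
    tests = {}
    for i in range(k):
        for j in range(i + 1, k):
            for name, arr in (("geff", geff), ("q", q)):
                t, p = ttest_rel(arr[:, i], arr[:, j])
                tests[(name, i, j)] = (float(t), float(p))
    model_fcs = [model.state_correlation(st) for st in range(k)]
    model_geff = np.array([global_efficiency(fc) for fc in model_fcs])
    model_q = np.array([modularity_q(fc, gamma, n_runs, seed)[0] for fc in model_fcs])
    return TopologyContrast(
        geff=geff,
        q=q,
        included_subjects=included,
        excluded_subjects=excluded,
        tests=tests,
        model_geff=model_geff,
        model_q=model_q,
    )
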