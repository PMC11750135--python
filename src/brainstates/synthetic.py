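"""Synthetic cohort generator with the statistical structure the analysis assumes.

Emulates a naturalistic-listening fMRI study: each subject's 9-network BOLD
time series (TR = 2 s, 300 time points) is generated by a 3-state Gaussian
HMM whose transition matrix has a hub structure (both peripheral states
prefer switching to the hub state over switching to each other).  Subjects
are split across narratives; within a narrative the chain's transition
log-odds are tilted by a shared smooth "narrative drive" (creating
inter-subject correlation) and by stimulus-feature regressors coupled to
specific states (creating testable stimulus modulation).  Comprehension
scores are generated from each subject's alignment with the narrative-group
mean of hub-state expression, and framewise-displacement traces carry a weak
engagement signal, so the downstream behavior analyses have known ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .hmm import NetworkTimeSeries
from .stimulus import StimulusRegressor, hrf_regressor

__all__ = [
    "NETWORK_NAMES",
    "FEATURE_NAMES",
    "GroundTruthConfig",
    "SimulatedCohort",
    "default_ground_truth",
    "stationary_distribution",
    "standardized_truth",
    "simulate_cohort",
    "simulate_behavior",
    "write_cohort",
]

NETWORK_NAMES = [
    "auditory",
    "visual",
    "somatomotor",
    "language",
    "medial_temporal",
    "frontal_parietal",
    "ventral_attention",
    "subcortical",
    "default_mode",
]

FEATURE_NAMES = ["envelope", "word_coherence", "clause_coherence"]

# Per-state activity loadings (z-units): a sensory-motor state, a
# language/frontal-parietal (hub) state, and a DMN/frontal-parietal state.
_DEFAULT_MEANS = np.array(
    [
        [1.0, 0.4, 1.0, -0.3, 0.0, -0.4, 0.3, 0.1, -0.9],
        [-0.7, -0.2, -0.6, 1.1, 0.3, 0.8, -0.1, 0.0, -0.3],
        [-0.5, 0.0, -0.3, -0.6, 0.4, 0.6, -0.2, 0.2, 1.1],
    ]
)

# Hub structure: P(0->1) > P(0->2) and P(2->1) > P(2->0), both by 0.06.
_DEFAULT_TRANSITION = np.array(
    [
        [0.90, 0.08, 0.02],
        [0.05, 0.90, 0.05],
        [0.02, 0.08, 0.90],
    ]
)

HUB_STATE = 1


def _default_covs() -> np.ndarray:
    """Compound-symmetric within-state noise; the hub state gets denser
    between-network correlation (higher integration when it is active)."""
    var = 0.5
    covs = np.empty((3, 9, 9))
    for j, rho in enumerate([0.10, 0.35, 0.10]):
        c = np.full((9, 9), rho * var)
        np.fill_diagonal(c, var)
        covs[j] = c
    return covs


@dataclass
class GroundTruthConfig:
    """Generating parameters of a synthetic cohort (the recovery targets)."""

    n_subjects: int = 64
    n_networks: int = 9
    n_timepoints: int = 300
    tr: float = 2.0
    k_true: int = 3
    state_means: np.ndarray = field(default_factory=lambda: _DEFAULT_MEANS.copy())
    state_covs: np.ndarray = field(default_factory=_default_covs)
    base_transition: np.ndarray = field(
        default_factory=lambda: _DEFAULT_TRANSITION.copy()
    )
    n_narratives: int = 3
    coupling_strength: np.ndarray | None = None  # (n_features, k_true)
    narrative_drive_strength: float = 0.25
    behavior_gain: float = 3.0
    behavior_noise_sd: float = 0.5
    fd_base: float = 0.2
    fd_noise_sd: float = 0.05
    fd_engagement_gain: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_means = np.asarray(self.state_means, dtype=np.float64)
        self.state_covs = np.asarray(self.state_covs, dtype=np.float64)
        self.base_transition = np.asarray(self.base_transition, dtype=np.float64)
        if self.coupling_strength is None:
            # selective default: feature f drives state f (envelope -> sensory
            # state, word coherence -> hub, clause coherence -> DMN state)
            c = np.zeros((len(FEATURE_NAMES), self.k_true))
            for f in range(min(len(FEATURE_NAMES), self.k_true)):
                c[f, f] = 1.0
            self.coupling_strength = c
        else:
            self.coupling_strength = np.asarray(self.coupling_strength, dtype=np.float64)
        rowsum = self.base_transition.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            raise ValueError("base_transition rows must sum to 1")
        if np.any(self.coupling_strength < 0) or self.narrative_drive_strength < 0:
            raise ValueError("coupling and drive strengths must be nonnegative")
        for j in range(self.k_true):
            c = self.state_covs[j]
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"state {j} covariance is not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"state {j} covariance is not positive definite")

    @property
    def duration_s(self) -> float:
        return self.n_timepoints * self.tr


@dataclass
class SimulatedCohort:
    """A generated cohort together with its ground truth."""

    series: list[NetworkTimeSeries]
    true_paths: list[np.ndarray]
    narrative_labels: list[str]
    regressors: dict[str, dict[str, StimulusRegressor]]
    scores: np.ndarray | None
    fd_traces: list[np.ndarray] | None
    truth: GroundTruthConfig
    alignments: np.ndarray | None = None


def default_ground_truth(**overrides) -> GroundTruthConfig:
    """The default generating configuration: 3 hub-structured Gaussian states
    over 9 networks, 300 time points at TR = 2 s, 3 narratives."""
    return GroundTruthConfig(**overrides)


def hierarchical_ground_truth(
    n_macro: int = 3,
    n_sub: int = 2,
    macro_separation: float = 3.0,
    sub_jitter: float = 1.2,
    within_self: float = 0.70,
    within_block: float = 0.18,
    noise_var: float = 0.6,
    seed: int = 0,
    **overrides,
) -> tuple[GroundTruthConfig, np.ndarray]:
    """A ground truth whose states nest inside macro-states (metastates).

    Each of ``n_macro`` macro-states owns ``n_sub`` sub-states: sub-state
    means are the macro mean plus Gaussian jitter (so sub-states are
    emission-separable but spatially similar within a macro-state), and the
    transition matrix keeps ``within_self + within_block`` probability inside
    a macro block.  Returns (config, macro label per sub-state); used to
    validate metastate reconstruction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    k = n_macro * n_sub
    n = overrides.get("n_networks", 9)
    macro = np.zeros((n_macro, n))
    width = max(1, n // n_macro)
    for m in range(n_macro):
        macro[m, m * width : (m + 1) * width] = macro_separation
    means = np.vstack(
        [
            macro[m] + sub_jitter * rng.standard_normal(n)
            for m in range(n_macro)
            for _ in range(n_sub)
        ]
    )
    a = np.zeros((k, k))
    between = 1.0 - within_self - within_block
    for m in range(n_macro):
        block = list(range(m * n_sub, (m + 1) * n_sub))
        outside = [j for j in range(k) if j not in block]
        for i in block:
            for j in block:
                if j == i:
                    a[i, j] = within_self + (within_block if n_sub == 1 else 0.0)
                else:
                    a[i, j] = within_block / (n_sub - 1)
            for j in outside:
                a[i, j] = between / len(outside)
    cfg = GroundTruthConfig(
        k_true=k,
        state_means=means,
        state_covs=np.stack([np.eye(n) * noise_var] * k),
        base_transition=a,
        coupling_strength=np.zeros((len(FEATURE_NAMES), k)),
        seed=seed,
        **overrides,
    )
    return cfg, np.repeat(np.arange(n_macro), n_sub)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi P = pi, by eigen-decomposition."""
    w, v = np.linalg.eig(transition.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def standardized_truth(cfg: GroundTruthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth means and covariances on the post-standardization scale.

    Column-wise z-scoring maps state means to (mu - m) / s and covariances to
    Sigma / (s s^T), where m and s are the stationary mixture mean and sd of
    each network.  Fitted models should be compared against these, not the
    raw generating values.
    """
    pi = stationary_distribution(cfg.base_transition)
    mu = cfg.state_means
    var_within = np.stack([np.diag(c) for c in cfg.state_covs])
    m = pi @ mu
    v = pi @ (var_within + mu**2) - m**2
    s = np.sqrt(v)
    means = (mu - m) / s
    covs = cfg.state_covs / np.outer(s, s)[None, :, :]
    return means, covs


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _narrative_drive(cfg: GroundTruthConfig, narrative_idx: int) -> np.ndarray:
    """Smooth shared drive g_m(t, k): a Gaussian random walk low-pass
    filtered and z-scored per state, fixed by the narrative's seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 101, narrative_idx])
    )
    walk = np.cumsum(rng.standard_normal((cfg.n_timepoints, cfg.k_true)), axis=0)
    smooth = gaussian_filter1d(walk, sigma=5.0, axis=0)
    smooth = smooth - smooth.mean(axis=0)
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    return smooth / sd


def _narrative_regressors(
    cfg: GroundTruthConfig, narrative_idx: int
) -> dict[str, StimulusRegressor]:
    """Per-narrative stimulus features: smooth native-rate signals passed
    through HRF convolution onto the TR grid, then z-scored."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 202, narrative_idx])
    )
    native_rate = 10.0
    n_native = int(round(cfg.duration_s * native_rate))
    out: dict[str, StimulusRegressor] = {}
    for name in FEATURE_NAMES:
        raw = gaussian_filter1d(rng.standard_normal(n_native), sigma=20.0)
        reg = hrf_regressor(
            raw,
            native_rate,
            n_timepoints=cfg.n_timepoints,
            tr=cfg.tr,
            name=name,
        )
        v = reg.values
        reg.values = (v - v.mean()) / v.std()
        out[name] = reg
    return out


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def simulate_cohort(cfg: GroundTruthConfig) -> SimulatedCohort:
    """Sample a cohort from the ground-truth model.

    Each subject's state path follows a time-inhomogeneous Markov chain whose
    transition log-odds at time t are the log of the base matrix row tilted
    by the narrative drive and by the coupled stimulus regressors; emissions
    are drawn from the active state's Gaussian and each network column is
    z-scored afterwards.  Bit-reproducible given ``cfg.seed``.
    """
    k, t_len, n = cfg.k_true, cfg.n_timepoints, cfg.n_networks
    pi0 = stationary_distribution(cfg.base_transition)
    log_a = np.log(cfg.base_transition)
    log_pi0 = np.log(pi0)
    chols = np.stack([np.linalg.cholesky(c) for c in cfg.state_covs])

    narratives = [f"narrative_{m}" for m in range(cfg.n_narratives)]
    regressors = {
        narratives[m]: _narrative_regressors(cfg, m) for m in range(cfg.n_narratives)
    }
    tilts = {}
    for m, label in enumerate(narratives):
        drive = cfg.narrative_drive_strength * _narrative_drive(cfg, m)
        reg_mat = np.stack(
            [regressors[label][name].values for name in FEATURE_NAMES], axis=1
        )  # (T, F)
        tilts[label] = drive + reg_mat @ cfg.coupling_strength  # (T, k)

    series: list[NetworkTimeSeries] = []
    paths: list[np.ndarray] = []
    labels: list[str] = []
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 303, i]))
        label = narratives[i % cfg.n_narratives]
        tilt = tilts[label]
        path = np.empty(t_len, dtype=np.int64)
        u = rng.random(t_len)
        p = _softmax_rows(log_pi0 + tilt[0])
        path[0] = np.searchsorted(np.cumsum(p), u[0])
        for t in range(1, t_len):
            p = _softmax_rows(log_a[path[t - 1]] + tilt[t])
            path[t] = min(np.searchsorted(np.cumsum(p), u[t]), k - 1)
        z = rng.standard_normal((t_len, n))
        x = cfg.state_means[path] + np.einsum("tij,tj->ti", chols[path], z)
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        series.append(
            NetworkTimeSeries(
                subject_id=f"sub-{i:03d}",
                data=x,
                tr=cfg.tr,
                narrative=label,
                condition="task",
            )
        )
        paths.append(path)
        labels.append(label)
    return SimulatedCohort(
        series=series,
        true_paths=paths,
        narrative_labels=labels,
        regressors=regressors,
        scores=None,
        fd_traces=None,
        truth=cfg,
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(
    cohort: SimulatedCohort, cfg: GroundTruthConfig | None = None
) -> SimulatedCohort:
    """Attach comprehension scores and framewise-displacement traces.

    A subject's score is 100 * logistic(a * alignment + noise), where
    alignment is the Pearson correlation between the subject's hub-state
    indicator time course (from the true path) and the leave-one-out mean of
    the same-narrative group.  FD traces are base + noise - b * engagement,
    with engagement a noisy copy of the same alignment, clipped at zero.
    """
    cfg = cfg or cohort.truth
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 404]))
    n_sub = len(cohort.series)
    t_len = cfg.n_timepoints
    hub = min(HUB_STATE, cfg.k_true - 1)
    ind = np.stack([(p == hub).astype(float) for p in cohort.true_paths])
    align = np.empty(n_sub)
    labels = np.asarray(cohort.narrative_labels)
    for i in range(n_sub):
        peers = (labels == labels[i]) & (np.arange(n_sub) != i)
        if not peers.any():
            align[i] = 0.0
            continue
        ref = ind[peers].mean(axis=0)
        a, b = ind[i], ref
        sa, sb = a.std(), b.std()
        align[i] = 0.0 if sa == 0 or sb == 0 else float(
            np.corrcoef(a, b)[0, 1]
        )
    noise = rng.standard_normal(n_sub) * cfg.behavior_noise_sd
    scores = 100.0 * _logistic(cfg.behavior_gain * align + noise)
    engagement = align + 0.5 * rng.standard_normal(n_sub)
    fd = []
    for i in range(n_sub):
        trace = (
            cfg.fd_base
            + cfg.fd_noise_sd * rng.standard_normal(t_len)
            - cfg.fd_engagement_gain * engagement[i]
        )
        fd.append(np.clip(trace, 0.0, None))
    cohort.scores = scores
    cohort.fd_traces = fd
    cohort.alignments = align
    return cohort


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    """Write the cohort as tab-delimited text plus a JSON manifest.

    One T x N TSV per subject (header = network names), regressors as
    two-column (time_s, value) TSVs per narrative, FD traces as TSVs, and a
    ``manifest.json`` tying everything together.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = NETWORK_NAMES[: cohort.truth.n_networks]
    if cohort.truth.n_networks > len(NETWORK_NAMES):
        names = names + [
            f"network_{i}" for i in range(len(NETWORK_NAMES), cohort.truth.n_networks)
        ]
    subjects = []
    for i, s in enumerate(cohort.series):
        ts_path = outdir / f"{s.subject_id}_timeseries.tsv"
        header = "\t".join(names)
        np.savetxt(ts_path, s.data, delimiter="\t", header=header, comments="")
        entry = {
            "subject_id": s.subject_id,
            "narrative": s.narrative,
            "condition": s.condition,
            "timeseries": ts_path.name,
        }
        if cohort.scores is not None:
            entry["score"] = float(cohort.scores[i])
        if cohort.fd_traces is not None:
            fd_path = outdir / f"{s.subject_id}_fd.tsv"
            np.savetxt(fd_path, cohort.fd_traces[i], delimiter="\t", header="fd_mm", comments="")
            entry["fd"] = fd_path.name
        subjects.append(entry)
    reg_index: dict[str, dict[str, str]] = {}
    tr = cohort.truth.tr
    for narrative, regs in cohort.regressors.items():
        reg_index[narrative] = {}
        for name, reg in regs.items():
            path = outdir / f"{narrative}_{name}.tsv"
            tgrid = np.arange(len(reg.values)) * tr
            np.savetxt(
                path,
                np.column_stack([tgrid, reg.values]),
                delimiter="\t",
                header="time_s\tvalue",
                comments="",
            )
            reg_index[narrative][name] = path.name
    manifest = {
        "n_subjects": len(cohort.series),
        "n_timepoints": cohort.truth.n_timepoints,
        "n_networks": cohort.truth.n_networks,
        "tr": tr,
        "networks": names,
        "subjects": subjects,
        "regressors": reg_index,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
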