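"""End-to-end pipeline: cohort loading, stage orchestration, JSON reports.

Stages run in method order — K selection, full-cohort fit, per-subject
decoding, dynamics and surrogate nulls, state-graph topology, metastate
reconstruction, stimulus modulation, behavior alignment — each drawing its
random stream from the master seed, and everything the analysis tabulates
lands in a single versioned JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import behavior as bhv
from . import dynamics as dyn
from . import graph as grf
from . import metastates as met
from . import selection as sel
from . import stimulus as stim
from .hmm import NetworkTimeSeries, fit_hmm, posterior_probs

__all__ = ["PipelineConfig", "load_cohort", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1.0"
logger = logging.getLogger("brainstates")


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; defaults follow the analysis
    protocol (10 restarts, K grid 2..10, 1000 transition surrogates, 5000
    modulation permutations, resolution grid 1.2:0.01:2.5, TR 2 s)."""

    manifest: str | None = None
    k_grid: list[int] = field(default_factory=lambda: list(range(2, 11)))
    n_restarts: int = 10
    n_perm_transition: int = 1000
    n_perm_modulation: int = 5000
    surrogate_restarts: int = 2
    gamma_grid: list[float] = field(
        default_factory=lambda: list(np.round(np.arange(1.2, 2.5 + 1e-9, 0.01), 2))
    )
    louvain_runs: int = 100
    metastate_k: int = 10
    tr: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def load_cohort(
    manifest_path: str | Path,
) -> tuple[list[NetworkTimeSeries], dict, dict]:
    """Load a cohort written by :func:`brainstates.synthetic.write_cohort`.

    Returns (series, per-subject metadata dict, regressors dict).  Shape
    mismatches, missing files and NaNs are reported with the offending
    subject id.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    t_len, n = manifest["n_timepoints"], manifest["n_networks"]
    series: list[NetworkTimeSeries] = []
    meta: dict[str, dict] = {}
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        path = root / entry["timeseries"]
        if not path.exists():
            raise FileNotFoundError(f"missing time-series file for subject {sid!r}")
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        if data.shape != (t_len, n):
            raise ValueError(
                f"subject {sid!r}: expected shape {(t_len, n)}, got {data.shape}"
            )
        if np.any(~np.isfinite(data)):
            raise ValueError(f"subject {sid!r}: NaN/inf values in time series")
        series.append(
            NetworkTimeSeries(
                subject_id=sid,
                data=data,
                tr=manifest["tr"],
                narrative=entry.get("narrative"),
                condition=entry.get("condition", "task"),
            )
        )
        meta[sid] = dict(entry)
        if "fd" in entry:
            meta[sid]["fd_trace"] = np.loadtxt(root / entry["fd"], skiprows=1)
    regressors: dict[str, dict[str, stim.StimulusRegressor]] = {}
    for narrative, files in manifest.get("regressors", {}).items():
        regressors[narrative] = {}
        for name, fname in files.items():
            tbl = np.loadtxt(root / fname, delimiter="\t", skiprows=1)
            regressors[narrative][name] = stim.StimulusRegressor(
                name=name,
                values=tbl[:, 1],
                native_rate=1.0 / manifest["tr"],
                hrf_applied=True,
                tr=manifest["tr"],
            )
    logger.info(
        "loaded cohort: %d subjects, T=%d, N=%d, narratives=%s",
        len(series),
        t_len,
        n,
        sorted({s.narrative for s in series}),
    )
    return series, meta, regressors


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(
    series: Sequence[NetworkTimeSeries],
    config: PipelineConfig,
    scores: np.ndarray | None = None,
    fd_traces: Sequence[np.ndarray] | None = None,
    regressors: dict[str, dict[str, stim.StimulusRegressor]] | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Run every stage on an already-loaded cohort and return (and optionally
    write) the JSON report."""
    narratives = [s.narrative for s in series]
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed}
    master = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ["selection", "fit", "surrogate", "graph", "metastates",
             "modulation", "behavior"],
            master.spawn(7),
        )
    }

    # --- stage 1: K selection (skipped for a singleton grid) ---------------
    if len(config.k_grid) == 1:
        k_star = int(config.k_grid[0])
        report["selection"] = {"k_star": k_star, "skipped": True}
        logger.info("selection skipped: singleton grid K=%d", k_star)
    else:
        res = sel.select_num_states(
            series,
            narratives,
            k_grid=config.k_grid,
            n_restarts=config.n_restarts,
            seed=stage_seed["selection"],
        )
        k_star = res.k_star
        report["selection"] = {
            "k_grid": list(map(int, res.k_grid)),
            "ch_scores": res.ch_scores,
            "decode_accuracy": res.decode_accuracy,
            "z_ch": res.z_ch,
            "z_acc": res.z_acc,
            "z_sum": res.z_sum,
            "k_star": int(k_star),
        }
        logger.info("selected K=%d", k_star)

    # --- stage 2: full-cohort fit and decoding -----------------------------
    model = fit_hmm(
        series, k_star, n_restarts=config.n_restarts, seed=stage_seed["fit"]
    )
    posteriors = [posterior_probs(s, model) for s in series]
    report["model"] = {
        "k": model.k,
        "means": model.means,
        "transition": model.transition,
        "initial": model.initial,
        "evidence": model.evidence,
        "converged": bool(model.converged),
        "state_correlations": [model.state_correlation(s) for s in range(model.k)],
    }

    # --- stage 3: dynamics and surrogate nulls -----------------------------
    summary = dyn.summarize_dynamics(
        [p.path for p in posteriors], model, config.tr
    )
    report["dynamics"] = {
        "fo_mean": np.nanmean(summary.fo, axis=0),
        "dwell_mean_s": np.nanmean(summary.mean_dwell_s, axis=0),
        "hub_state": summary.hub_state,
        "hub_asym": summary.hub_asym,
    }
    if config.n_perm_transition > 0 and k_star == 3:
        null = dyn.transition_surrogate_null(
            series,
            k_star,
            n_perm=config.n_perm_transition,
            n_restarts=config.surrogate_restarts,
            seed=stage_seed["surrogate"],
            observed_model=model,
        )
        report["dynamics"]["surrogate"] = {
            "observed": null.observed,
            "empirical_p": null.empirical_p,
            "percentile": null.percentile,
            "n_perm": null.n_perm,
        }

    # --- stage 4: graph topology -------------------------------------------
    fc = grf.group_fc(series)
    contrast = grf.state_topology_contrast(
        series,
        posteriors,
        model,
        n_runs=max(5, config.louvain_runs // 5),
        seed=stage_seed["graph"],
    )
    report["graph"] = {
        "group_fc": fc,
        "geff_mean": contrast.geff.mean(axis=0),
        "q_mean": contrast.q.mean(axis=0),
        "model_geff": contrast.model_geff,
        "model_q": contrast.model_q,
        "n_excluded": len(contrast.excluded_subjects),
        "tests": {
            f"{m}_{i}_{j}": tp for (m, i, j), tp in contrast.tests.items()
        },
    }

    # --- stage 5: metastate reconstruction ---------------------------------
    if config.metastate_k > k_star:
        fine = fit_hmm(
            series,
            config.metastate_k,
            n_restarts=max(2, config.n_restarts // 2),
            seed=stage_seed["metastates"],
        )
        clusters = met.cluster_transitions(fine.transition, k_star)
        fine_paths = [posterior_probs(s, fine).path for s in series]
        merged_means, merged_paths = met.merge_cluster_states(
            fine, clusters, fine_paths
        )
        corr = met.spatial_match(merged_means, model.means)
        overlaps = [
            met.temporal_jaccard(corr.mapping[mp], p.path)[1]
            for mp, p in zip(merged_paths, posteriors)
        ]
        report["metastates"] = {
            "fine_k": config.metastate_k,
            "clusters": clusters,
            "spatial_r": corr.similarity,
            "primed": corr.primed,
            "mapping": corr.mapping,
            "temporal_overlap": float(np.mean(overlaps)),
        }

    # --- stage 6: stimulus modulation ---------------------------------------
    if regressors:
        mod_results = []
        feature_names = sorted({f for d in regressors.values() for f in d})
        for f_idx, fname in enumerate(feature_names):
            for state in range(model.k):
                pooled = []
                for narrative in sorted(regressors):
                    if fname not in regressors[narrative]:
                        continue
                    members = [
                        i for i, s in enumerate(series) if s.narrative == narrative
                    ]
                    if not members:
                        continue
                    r = stim.modulation_test(
                        regressors[narrative][fname],
                        [posteriors[i].gamma for i in members],
                        state,
                        n_perm=config.n_perm_modulation,
                        seed=stage_seed["modulation"] + 1000 * f_idx,
                    )
                    pooled.append(r)
                per_subject = np.concatenate([r.per_subject_r for r in pooled])
                mean_r = float(per_subject.mean())
                emp = float(np.mean([r.empirical_p for r in pooled]))
                mod_results.append(
                    {
                        "feature": fname,
                        "state": state,
                        "mean_r": mean_r,
                        "empirical_p": emp,
                    }
                )
        pvals = np.array(
            [max(m["empirical_p"], 1.0 / (config.n_perm_modulation + 1))
             for m in mod_results]
        )
        from statsmodels.stats.multitest import multipletests

        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for m, qv in zip(mod_results, qvals):
            m["fdr_q"] = float(qv)
        report["modulation"] = mod_results

    # --- stage 7: behavior ---------------------------------------------------
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        gammas = [p.gamma for p in posteriors]
        fd_isc = None
        if fd_traces is not None:
            fd_cols = [np.asarray(f)[:, None] for f in fd_traces]
            fd_isc = bhv.alignment_to_group(fd_cols, 0, narratives)
        states_out = []
        for state in range(model.k):
            to_best, idx = bhv.alignment_to_best(gammas, scores, narratives, state)
            to_group = bhv.alignment_to_group(gammas, state, narratives)
            best_corr = bhv.behavior_correlation(
                to_best,
                scores[idx],
                covariate=fd_isc[idx] if fd_isc is not None else None,
            )
            group_corr = bhv.behavior_correlation(
                to_group,
                scores,
                covariate=fd_isc if fd_isc is not None else None,
            )
            fo_corr = bhv.behavior_correlation(summary.fo[:, state], scores)
            states_out.append(
                {
                    "state": state,
                    "best_r": best_corr.r,
                    "best_p": best_corr.p,
                    "best_partial_r": best_corr.partial_r,
                    "best_partial_p": best_corr.partial_p,
                    "group_r": group_corr.r,
                    "group_p": group_corr.p,
                    "group_partial_r": group_corr.partial_r,
                    "fo_r": fo_corr.r,
                    "fo_p": fo_corr.p,
                }
            )
        report["behavior"] = states_out

    report = _jsonable(report)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        logger.info("report written to %s", out_path)
    return report
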