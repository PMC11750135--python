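# brainstates

Latent brain-state analysis of naturalistic fMRI network time series.

During continuous tasks such as listening to a spoken narrative, whole-brain
activity can be modelled as switching among a small number of latent states,
each with its own pattern of network activity and connectivity. This package
implements that analysis end to end for researchers working with
network-by-time BOLD matrices:

- **Gaussian hidden Markov models** — emissions x_t | s_t = j ~ N(mu_j,
  Sigma_j), latent chain with transition matrix A — fitted by EM
  (Baum-Welch) on concatenated subjects with per-subject chain resets,
  multiple seeded restarts, and selection of the restart with the highest
  log-likelihood. Posterior state expression gamma_t(j) comes from scaled
  forward-backward; the state sequence from Viterbi decoding.
- **Model-order selection** by a dual criterion under leave-one-subject-out
  cross-validation: the Calinski-Harabasz score of decoded labels
  (statistical robustness) and K-nearest-neighbour narrative decoding from
  the decoded expression time courses (cognitive sensibility), each
  z-scored across the K grid and summed.
- **State dynamics**: fractional occupancy, mean dwell time, and a
  transition-hub statistic (does one state receive more switching
  probability from both others than they exchange directly?) tested against
  circular-shift surrogate nulls with HMM refits.
- **Per-state network topology**: weighted global efficiency and Louvain
  modularity of state-specific FC graphs, subject-level and model-derived,
  with paired contrasts; plus a resolution-swept Louvain community analysis
  with modularity-weighted z-Rand consistency.
- **Metastate reconstruction**: agglomerative clustering of a finer model's
  transition matrix into metastates, state merging, and greedy
  correlation-based matching of states across runs/conditions (with the
  "primed" confusion convention) in space or time.
- **Stimulus modulation**: speech-envelope and word/clause semantic-
  coherence regressors (Hilbert envelope, PCA + cosine coherence, canonical
  double-gamma HRF convolution, TR resampling) correlated with state
  expression, with circular-shift permutation nulls and FDR.
- **Behavior**: inter-subject alignment of state expression (to best
  performers and to the leave-one-out group mean) correlated with
  comprehension scores, controlling head-motion similarity (framewise
  displacement) by partial correlation.
- **A synthetic cohort generator** with full ground truth (true state
  paths, coupling strengths, score model), so every stage is testable
  without any data download.

## Worked example

```python
import brainstates as bs

# a synthetic cohort with known ground truth: 12 subjects x 300 TRs x 9
# networks from a 3-state hub-structured HMM, 3 narratives, behaviour
cfg = bs.default_ground_truth(n_subjects=12, seed=1)
cohort = bs.simulate_behavior(bs.simulate_cohort(cfg))

model = bs.fit_hmm(cohort.series, k=3, n_restarts=10, seed=0)
posts = [bs.posterior_probs(s, model) for s in cohort.series]
summary = bs.summarize_dynamics([p.path for p in posts], model, cfg.tr)

print("fractional occupancy (mean):", summary.fo.mean(axis=0).round(3))
print("hub state:", summary.hub_state)
print("hub asymmetries:", None if summary.hub_asym is None
      else [round(v, 3) for v in summary.hub_asym])
```

Output from this exact run:

```
fractional occupancy (mean): [0.438 0.26  0.302]
hub state: 0
hub asymmetries: [0.065, 0.05, 0.058]
```

The cohort spends the largest fraction of time (~44%) in the state detected
as the transitional hub: both other states send more transition probability
to it (asymmetries 0.065 and 0.05, mean 0.058; the generating value is 0.06
for both). Fitted state labels are arbitrary — here the hub landed on label
0; `align_state_labels` maps them onto a reference model's labels (the
generator's hub is the language/frontal-parietal-loaded state).

A shell interface wraps the same stages:

```bash
brainstates simulate --seed 1 --n-subjects 12 --out cohort/
brainstates select-k --manifest cohort/manifest.json --k-min 2 --k-max 6 --out select.json
brainstates run-all --manifest cohort/manifest.json --seed 1 --out report.json
```

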