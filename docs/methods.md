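# Methods

## Model

`brainstates` analyses multi-network BOLD time series with a hidden Markov
model whose emissions are multivariate Gaussian: at each TR the brain
occupies one of K latent states; state j emits an N-dimensional activity
vector from N(mu_j, Sigma_j), and the state sequence follows a first-order
chain with row-stochastic transition matrix A. The mean vectors are the
states' network activity loadings; the correlation form of Sigma_j is the
state-specific functional-connectivity matrix. Time series are z-scored
within subject and network before fitting, so loadings are in z-units.

Fitting is maximum-likelihood EM (Baum-Welch) on the concatenation of all
subjects, with the forward recursion restarting from the initial
distribution at every subject boundary so transitions are never pooled
across subjects. The chain is treated as shared across subjects (one A, one
set of states), which is what "concatenated" fitting assumes. We run
several restarts (default 10) from k-means initialisations and keep the
restart with the highest training log-likelihood, which plays the role of
the model evidence. This is a deliberate design choice: a variational-Bayes
treatment (as in the HMM-MAR family of toolboxes) would supply a free
energy; plain EM with likelihood-based restart selection preserves the same
contract (Gaussian states, restarts, evidence-based selection) while being
fully specifiable and exactly testable against path enumeration.

Numerical choices:

- Scaled (normalised) forward-backward in linear space with per-row
  emission rescaling; log-likelihood recovered from the scaling constants.
  Inner recursions are numba-compiled. Exactness is verified against
  exhaustive path enumeration (k <= 3, T <= 8) to 1e-10.
- Covariances are full and per-state, with 1e-6 added to the diagonal each
  M-step.
- Initialisation: seeded k-means centers for the means (centers sorted
  lexicographically so restarts differ only through their seed), pooled
  covariance for every state, transition 0.9 on the diagonal, uniform
  initial distribution.
- Convergence: relative log-likelihood change below 1e-6, cap 500
  iterations; non-convergence returns the best-so-far model with a flag.
- Viterbi ties break toward the lower state index.
- Subjects are internally sorted by id before concatenation, making the fit
  invariant to the order in which series are supplied.
- Label switching between independently fitted models is resolved by
  optimal assignment maximising summed Pearson correlation between matched
  mean vectors.

State labels are 0-based everywhere in the package.

## Choosing the number of states

For each K in a grid (default 2..10), a leave-one-subject-out loop fits the
model on the remaining subjects and decodes the held-out subject. Two
quantities are averaged over subjects: the Calinski-Harabasz score of the
decoded labels on the subject's own time series (clustering quality,
normalised between/within dispersion; capped at 1e12 when the within
dispersion vanishes) and the accuracy of a K-nearest-neighbour classifier
(k = 5, Euclidean distance on the flattened decoded gamma matrix, vote ties
resolved by the single nearest neighbour) at identifying the narrative the
subject heard. Both curves are z-scored across the grid and summed; the K
maximising the sum wins, ties to the smallest K. Per-fold labels are
aligned to the full-cohort model before feature construction — without
this, KNN features would not be comparable across folds. The KNN
parameters and the use of gamma (rather than the hard path) as features are
package choices; gamma retains more information and is deterministic given
the model.

## State dynamics and surrogate nulls

Fractional occupancy and mean dwell time are computed from the Viterbi
path (not thresholded gamma); unvisited states get NaN dwell rather than
zero. The transition-hub statistic asks whether one state receives more
transition probability from both other states than they exchange directly;
when such a hub exists the statistic is the mean of the two asymmetries,
otherwise 0. The null is built by circularly shifting every network column
of every subject by an independent uniform offset in {1..T-1} (preserving
each column's marginal and autocorrelation while destroying between-network
covariance), refitting the HMM, and recording the hub statistic. Empirical
p-values use the add-one convention (1 + #{null >= obs}) / (1 + n_perm);
the raw percentile is also reported.

A caveat this package's synthetic experiments make explicit: HMM refits on
column-shifted surrogates inherit the uneven state occupancies of the
original columns and therefore carry a systematic hub-like asymmetry of
their own (about 0.044 under the default generator, with seed-to-seed
spread ~0.005 at n = 48). A true hub asymmetry of 0.06 — further flattened
to ~0.05 by the stimulus tilts of the generator — is therefore only
marginally detectable against this null at any cohort size we simulate.
Detecting hubness with this surrogate scheme requires asymmetry well in
excess of what occupancy imbalance alone produces.

## Graph analysis

Per-state FC matrices come either from the time points the Viterbi path
assigns to the state (requiring at least N + 2 such points) or from the
model covariance converted to correlation. Both are analysed as weighted
undirected graphs: negative weights are set to zero (stated convention),
edge length is 1/weight, weighted global efficiency is the mean inverse
shortest-path length over ordered pairs (disconnected pairs contribute 0),
and modularity uses Louvain (networkx implementation) with resolution 1 by
default, best of n seeded runs. Between-state contrasts use paired
two-tailed t-tests over subjects that visited all states.

The resolution sweep for community analysis of a supplied FC matrix runs
Louvain n times per gamma (default grid 1.2:0.01:2.5), measures run-to-run
consistency by the mean pairwise z-Rand score (Traud-Kelsic-Mucha-Porter
pair-counting formulation, hand-implemented since no installed package
provides it), picks the medoid run as the representative partition, and
flags the gamma maximising modularity x mean z-Rand.

## Metastates and state matching

A finer HMM (more states than the target space) is reduced by agglomerative
clustering of its transition matrix. The pairwise similarity between states
is the symmetrised off-diagonal transition mass (A_ij + A_ji)/2, converted
to distance 1 - sim for average linkage. We chose transition mass over
correlation of transition profiles deliberately: two states of the same
metastate exchange probability directly, so each one's profile peaks at the
*other's* column — their profiles are complementary, not similar — and
profile-correlation clustering demonstrably fails to recover planted blocks
that mass-based clustering recovers exactly. Merged state means are
unweighted averages of member means; paths are relabelled by cluster.

Candidate states are matched to a predefined set by Pearson correlation of
mean activity patterns with a greedy confusion rule: candidates claim
predefined states in descending order of correlation; a candidate that
loses its top match to a stronger candidate takes its best unassigned state
and is flagged "primed". Temporal agreement uses per-state Jaccard overlap
and the overall fraction of identically labelled time points. Matching on
expression time courses (for cross-parcellation comparisons) reuses the
same machinery with concatenated gamma columns as the vectors.

## Stimulus features and modulation

The acoustic envelope is |Hilbert transform| smoothed by a 50 ms moving
average. Event- or series-valued features are convolved with a canonical
double-gamma HRF (response gamma shape 6, undershoot shape 16, ratio 6,
32 s support, unit area) on the native grid and resampled to the TR grid by
within-TR averaging (robust to the native rate; decimation is not).
Semantic coherence is the cosine similarity between consecutive items'
embeddings after projection onto the first n PCs (default 50); clause
embeddings average the member words' vectors. PCA is fit per narrative.

The modulation test correlates a feature regressor with each subject's
state expression column, tests the group mean against zero (two-tailed
one-sample t) and against a circular-shift permutation null (independent
uniform shifts per subject; the correlation at every shift is obtained at
once via FFT cross-correlation, so the default 5000 permutations are
cheap). The empirical p is one-sided (proportion of permuted group means at
least as large as observed), matching the directional hypothesis;
Benjamini-Hochberg FDR is applied across the feature-by-state family.

## Behavior

Framewise displacement uses the Power convention (sum of absolute
backward-differenced translations plus 50 mm times rotations). Alignment is
the Pearson correlation of a subject's expression column with the best
performer(s) of the same narrative (ties averaged, best performers excluded
from the sample) or with the leave-one-out group mean. Alignment samples
are pooled across narratives before correlating with comprehension scores.
Partial correlation controls head-motion similarity by the residual method
(correlation of OLS residuals; two-tailed p on n - 3 degrees of freedom).

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: 64 subjects
(default) x 300 time points at TR = 2 s x 9 networks, generated by a
3-state Gaussian HMM. Defaults, with reasons:

- State means load on sensory-motor, language/frontal-parietal, and
  DMN/frontal-parietal groups respectively, pairwise correlation < 0.5, and
  are scaled so the stationary mixture is approximately zero-mean,
  unit-variance per network (per-subject z-scoring then changes the truth
  only slightly; `standardized_truth` supplies the exact post-scaling
  truth for recovery comparisons).
- Transition matrix rows (0.90, 0.08, 0.02), (0.05, 0.90, 0.05),
  (0.02, 0.08, 0.90): state 1 is a transitional hub with both asymmetries
  0.06, and the stationary distribution puts its largest mass (0.44) on the
  hub.
- State covariances are compound-symmetric with variance 0.5; the hub state
  gets denser between-network correlation (0.35 vs 0.10), so per-state
  graph contrasts have a known direction.
- Three narratives. Each narrative owns three smooth stimulus features
  (white noise low-passed, HRF-convolved, z-scored) and a smooth "drive"
  g(t, k) (low-passed Gaussian random walk, z-scored per state). A
  subject's chain is time-inhomogeneous: the transition log-odds at time t
  are log A[prev] + drive_strength * g(t, :) + regressors(t) @ coupling.
  Coupling is selective by default (envelope -> sensory state, word
  coherence -> hub, clause coherence -> DMN state, strength 1.0), which
  makes stimulus modulation an emergent property of the sampled paths
  rather than something painted onto emissions.
- drive_strength = 0.25, calibrated once so the generator satisfies its
  contracted properties jointly: within-narrative ISC exists and grows with
  drive strength, and — critically — narrative decoding from a 2-state
  model is hard while a 3-state model succeeds, reproducing the qualitative
  shape of the dual-criterion selection curve (accuracy low at K = 2,
  peaking at K = 3, with the Calinski-Harabasz score monotonically
  decreasing in K). A stronger drive saturates decoding accuracy at K = 2
  and the selection collapses to the CH term.
- Comprehension scores: 100 * logistic(3 * alignment + noise), where
  alignment is the correlation of the subject's hub-state indicator with
  the leave-one-out narrative-group mean; the logistic link keeps scores in
  [0, 100] as percentage scores are. Noise sd 0.5. FD traces are
  base 0.2 mm + 0.05 mm noise minus 0.1 x a noisy engagement copy of the
  same alignment, clipped at zero.

What the generator does *not* emulate: realistic fMRI autocorrelated noise,
inter-subject anatomical/functional variability, narrative-specific
durations, or the tiny effect sizes of real stimulus-brain coupling (real
group-mean correlations are ~0.03; the generator uses couplings an order of
magnitude stronger so that desk-scale cohorts have statistical power).
Passing tests therefore demonstrate correctness and calibration of the
machinery, not that real data would yield the same effect sizes.

A mechanical side-effect worth knowing: because scores derive from timing
alignment of the hub indicator, and subjects with longer hub dwell track
the shared drive better, dwell time retains a weak positive correlation
with scores (median r ~ 0.1-0.2 at the calibrated drive) even though no
direct dwell-score coupling exists. Fractional occupancy shows no such
leakage.

`hierarchical_ground_truth` builds a nested variant — macro-states each
split into emission-separable sub-states with block-structured transitions
— used to validate metastate reconstruction (a 10-state fit clustered back
to 3 macro-states recovers spatial patterns at r > 0.9 and > 90% temporal
overlap under the default construction).

## Problem sizes used in validation

The test suite and the acceptance script run entirely on synthetic cohorts
sized for a single CPU: parameter recovery at n = 20 x T = 300, selection
recovery at n = 12 over K in {2..6} with 5 restarts, surrogate calibration
on 100 null cohorts (n = 4, T = 100, 50 surrogates each), surrogate power
on 10 cohorts (n = 12, 100 surrogates), modulation calibration on 100
cohorts and power on 10 cohorts of n = 16, behavior on cohorts of n = 60,
and metastate reconstruction at n = 12 with a 10-state fit. These sizes
are the package's chosen validation conditions; the full-scale protocol
defaults (10 restarts, 1000 transition surrogates, 5000 modulation
permutations, gamma grid 1.2:0.01:2.5) remain the pipeline defaults.

## Known limitations

- EM with likelihood restarts can still land in local optima at large K;
  the K-selection loop partially absorbs this through restarts and
  cross-validation, but fits at K well above the true order fragment
  states in seed-dependent ways.
- The surrogate transition null is conservative for hub detection (see
  above): occupancy imbalance alone generates hub-like asymmetry in
  refits, so weak hubs are not detectable by this scheme.
- The decoding-based selection criterion needs narratives to differ in
  ways a coarse model cannot see; when between-narrative signal is strong
  enough to classify from a 2-state decomposition, the composite score
  favours small K.
- Circular-shift nulls assume approximate stationarity of each column;
  strongly non-stationary columns would weaken exchangeability.
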