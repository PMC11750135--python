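import itertools

import numpy as np
import pytest

import brainstates as bs
from brainstates.hmm import GaussianHMMModel


def _model(means, transition=None):
    k, n = means.shape
    if transition is None:
        transition = np.full((k, k), 1.0 / k)
    return GaussianHMMModel(
        k=k,
        means=np.asarray(means, float),
        covs=np.stack([np.eye(n)] * k),
        transition=np.asarray(transition, float),
        initial=np.full(k, 1.0 / k),
        evidence=0.0,
    )


def _block_transition(blocks, within=0.9):
    """Row-stochastic matrix with planted block structure."""
    k = sum(len(b) for b in blocks)
    a = np.zeros((k, k))
    for b in blocks:
        for i in b:
            inside = [j for j in b]
            outside = [j for j in range(k) if j not in b]
            for j in inside:
                a[i, j] = within / len(inside)
            for j in outside:
                a[i, j] = (1 - within) / len(outside)
    return a


class TestClusterTransitions:
    def test_planted_blocks_recovered(self):
        blocks = [[0, 1], [2, 3], [4, 5]]
        a = _block_transition(blocks)
        labels = bs.cluster_transitions(a, 3)
        for b in blocks:
            assert len(set(labels[b])) == 1
        assert len(np.unique(labels)) == 3

    def test_singleton_hub_isolated(self):
        # states 0-2 swap among themselves; state 3 is a distinct hub profile
        a = _block_transition([[0, 1, 2], [3]], within=0.92)
        labels = bs.cluster_transitions(a, 2)
        assert len(np.unique(labels)) == 2
        assert np.sum(labels == labels[3]) == 1

    def test_too_many_clusters_rejected(self):
        a = np.full((3, 3), 1 / 3)
        with pytest.raises(ValueError, match="smaller"):
            bs.cluster_transitions(a, 3)


class TestMergeClusterStates:
    def test_identity_merge_with_singletons(self):
        m = _model(np.arange(12.0).reshape(3, 4))
        means, paths = bs.merge_cluster_states(
            m, np.array([0, 1, 2]), [np.array([0, 1, 2, 2])]
        )
        assert np.array_equal(means, m.means)
        assert np.array_equal(paths[0], [0, 1, 2, 2])

    def test_hand_average(self):
        m = _model(np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]]))
        means, paths = bs.merge_cluster_states(
            m, np.array([0, 0, 1]), [np.array([0, 1, 2])]
        )
        assert np.allclose(means[0], [0.5, 0.5])
        assert np.allclose(means[1], [5.0, 5.0])
        assert np.array_equal(paths[0], [0, 0, 1])

    def test_incomplete_cluster_labels_rejected(self):
        m = _model(np.eye(3))
        with pytest.raises(ValueError, match="every state"):
            bs.merge_cluster_states(m, np.array([0, 1]), [])


class TestSpatialMatch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 9))
        corr = bs.spatial_match(v, v)
        assert np.array_equal(corr.mapping, [0, 1, 2])
        assert not corr.primed.any()
        assert np.allclose(corr.similarity, 1.0)

    def test_confusion_resolved_with_prime(self):
        """Two candidates share a top match; the stronger keeps it, the other
        takes the next-best unassigned state and is flagged primed."""
        rng = np.random.default_rng(5)
        pre = rng.normal(size=(3, 9))
        # candidate 0 strongly resembles predefined 1; candidate 1 weakly so
        c0 = pre[1] + 0.3 * rng.normal(size=9)
        c1 = pre[1] + 1.2 * rng.normal(size=9) + 0.5 * pre[2]
        c2 = pre[0] + 0.3 * rng.normal(size=9)
        cand = np.vstack([c0, c1, c2])
        r = np.corrcoef(cand, pre)[:3, 3:]
        assert np.argmax(r[0]) == 1 and np.argmax(r[1]) == 1  # planted confusion
        corr = bs.spatial_match(cand, pre)
        assert corr.mapping[0] == 1 and not corr.primed[0]
        assert corr.mapping[1] != 1 and corr.primed[1]
        assert corr.mapping[2] == 0 and not corr.primed[2]

    def test_matches_greedy_bruteforce(self):
        """The greedy rule (strongest candidate first, next-best unassigned
        for losers) reproduced by explicit enumeration."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            cand = rng.normal(size=(3, 7))
            pre = rng.normal(size=(3, 7))
            r = np.corrcoef(cand, pre)[:3, 3:]
            # brute-force greedy: repeatedly take the globally best available pair
            mapping = {}
            taken = set()
            remaining = {0, 1, 2}
            while remaining:
                c, p = max(
                    ((c, p) for c in remaining for p in range(3) if p not in taken),
                    key=lambda cp: r[cp],
                )
                mapping[c] = p
                taken.add(p)
                remaining.remove(c)
            corr = bs.spatial_match(cand, pre)
            assert {c: corr.mapping[c] for c in range(3)} == mapping

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        cand = rng.normal(size=(3, 8))
        pre = rng.normal(size=(3, 8))
        base = bs.spatial_match(cand, pre)
        perm = np.array([2, 0, 1])
        permuted = bs.spatial_match(cand, pre[perm])
        # predefined state j is now at position inv[j]
        inv = np.empty(3, dtype=int)
        inv[perm] = np.arange(3)
        assert np.array_equal(permuted.mapping, inv[base.mapping])

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bs.spatial_match(np.zeros((2, 4)), np.zeros((3, 4)))


class TestTemporalJaccard:
    def test_hand_case(self):
        per_state, overall = bs.temporal_jaccard(
            np.array([0, 0, 1, 2]), np.array([0, 1, 1, 2])
        )
        assert per_state[0] == pytest.approx(0.5)
        assert per_state[1] == pytest.approx(0.5)
        assert per_state[2] == pytest.approx(1.0)
        assert overall == pytest.approx(0.75)

    def test_identical_and_disjoint(self):
        a = np.array([0, 1, 1, 2])
        per_state, overall = bs.temporal_jaccard(a, a)
        assert all(v == 1.0 for v in per_state.values()) and overall == 1.0
        per_state, _ = bs.temporal_jaccard(np.array([0, 0, 1, 1]), np.array([1, 1, 0, 0]))
        assert per_state[0] == 0.0 and per_state[1] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bs.temporal_jaccard(np.zeros(3), np.zeros(4))


class TestTemporalMatch:
    def test_identity_on_shared_gammas(self):
        rng = np.random.default_rng(2)
        gammas = [rng.dirichlet(np.ones(3), size=50) for _ in range(4)]
        corr = bs.temporal_match(gammas, gammas)
        assert corr.basis == "temporal"
        assert np.array_equal(corr.mapping, [0, 1, 2])
        assert np.allclose(corr.similarity, 1.0)


class TestMetastateRecovery:
    def test_fine_hmm_reduces_to_macrostates(self):
        """A 10-state fit to a cohort with 3 macro-states (3 sub-states
        each) clusters back to the macro space with high spatial correlation
        and temporal overlap."""
        cfg, _ = bs.hierarchical_ground_truth(
            n_sub=3,
            within_self=0.65,
            within_block=0.25,
            macro_separation=3.5,
            sub_jitter=1.4,
            seed=31,
            n_subjects=8,
            n_timepoints=250,
        )
        co = bs.simulate_cohort(cfg)
        target = bs.fit_hmm(co.series, 3, n_restarts=3, seed=1)
        fine = bs.fit_hmm(co.series, 10, n_restarts=3, seed=1)
        clusters = bs.cluster_transitions(fine.transition, 3)
        fine_paths = [bs.posterior_probs(s, fine).path for s in co.series]
        merged_means, merged_paths = bs.merge_cluster_states(fine, clusters, fine_paths)
        corr = bs.spatial_match(merged_means, target.means)
        assert np.min(corr.similarity) > 0.9
        overlaps = [
            bs.temporal_jaccard(corr.mapping[mp], bs.posterior_probs(s, target).path)[1]
            for mp, s in zip(merged_paths, co.series)
        ]
        assert np.mean(overlaps) > 0.9


class TestCorrespondenceNull:
    def test_null_centered_for_noise_cohorts(self):
        rng = np.random.default_rng(8)
        series = [
            bs.NetworkTimeSeries(subject_id=f"s{i}", data=rng.normal(size=(120, 5)))
            for i in range(4)
        ]
        ref_means = rng.normal(size=(2, 5))
        null = bs.correspondence_null(
            series, 2, n_perm=10, seed=0, reference_means=ref_means, n_restarts=1
        )
        assert null.shape == (10, 2)
        assert abs(null.mean()) < 0.5  # matched maxima are biased up but bounded

    def test_reproducible(self, small_cohort):
        kwargs = dict(
            k=3,
            n_perm=2,
            seed=4,
            reference_means=np.asarray(small_cohort.truth.state_means),
            n_restarts=1,
        )
        a = bs.correspondence_null(small_cohort.series[:4], **kwargs)
        b = bs.correspondence_null(small_cohort.series[:4], **kwargs)
        assert np.array_equal(a, b)

    def test_zero_perms_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            bs.correspondence_null(small_cohort.series, 3, n_perm=0)
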