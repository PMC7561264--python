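"""Group construction, cluster permutation machinery, effect sizes."""

import numpy as np
import pytest
from scipy import stats

from imagentrain.groupstats import (
    StatMap,
    between_baseline,
    build_between_groups,
    cluster_permutation,
    conjunction,
    find_clusters,
    minimal_detectable_dz,
    paired_t_map,
    required_effect_size,
    _components,
)


def chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestBetweenGroups:
    TRIALS = {f"song{j}": tuple(range(100 * j, 100 * j + 24)) for j in range(3)}

    def test_partition_of_72_trials(self):
        groups = build_between_groups(self.TRIALS, k=8, n_groups=3, seed=1)
        all_ids = [t for g in groups for s in self.TRIALS for t in g.indices[(0, s)]]
        assert len(all_ids) == 72
        assert len(set(all_ids)) == 72  # no trial reused
        for g in groups:
            assert sum(len(g.indices[(0, s)]) for s in self.TRIALS) == 24

    def test_k_all_single_group_is_within_group(self):
        groups = build_between_groups({"song0": tuple(range(24))}, k=24, n_groups=1, seed=0)
        assert sorted(groups[0].indices[(0, "song0")]) == list(range(24))

    def test_seeded_determinism(self):
        a = build_between_groups(self.TRIALS, seed=3)
        b = build_between_groups(self.TRIALS, seed=3)
        assert all(ga.indices == gb.indices for ga, gb in zip(a, b))

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            build_between_groups(self.TRIALS, k=9, n_groups=3)


class TestBetweenBaseline:
    def test_identical_phases_baseline_one(self):
        phases = np.full((72, 2, 5, 3), 1.2)  # trials, ch, frames, freqs(1-3Hz)
        rows = {f"s{j}": tuple(range(24 * j, 24 * (j + 1))) for j in range(3)}

        class P:  # minimal PhaseTensor stand-in
            pass

        from imagentrain.spectral import PhaseTensor

        pt = PhaseTensor(phases=phases, frame_centers=np.arange(5) * 0.2,
                         freqs=np.array([1.0, 2.0, 3.0]))
        res = between_baseline(pt, rows, band="delta", time_window=(0, 1), seed=0)
        assert np.allclose(res.baseline, 1.0)

    def test_uniform_phases_match_monte_carlo_oracle(self):
        # the 50th percentile of mean-of-3-groups band ITC under uniform phases
        rng = np.random.default_rng(0)
        from imagentrain.spectral import PhaseTensor

        phases = rng.uniform(-np.pi, np.pi, (72, 1, 4, 3))
        rows = {f"s{j}": tuple(range(24 * j, 24 * (j + 1))) for j in range(3)}
        pt = PhaseTensor(phases=phases, frame_centers=np.arange(4) * 0.2,
                         freqs=np.array([1.0, 2.0, 3.0]))
        res = between_baseline(pt, rows, band="delta", time_window=(0, 1),
                               n_repeats=200, seed=1)
        # oracle: direct simulation of the same statistic
        draws = []
        for _ in range(2000):
            sub = rng.permutation(72)
            vals = []
            for g in range(3):
                p = phases[sub[g * 24 : (g + 1) * 24], 0]
                vals.append(np.abs(np.exp(1j * p).mean(axis=0)).mean())
            draws.append(np.mean(vals))
        assert res.baseline[0] == pytest.approx(np.median(draws), rel=0.02)

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(2)
        from imagentrain.spectral import PhaseTensor

        phases = rng.uniform(-np.pi, np.pi, (72, 2, 3, 3))
        rows = {f"s{j}": tuple(range(24 * j, 24 * (j + 1))) for j in range(3)}
        pt = PhaseTensor(phases=phases, frame_centers=np.arange(3) * 0.2,
                         freqs=np.array([1.0, 2.0, 3.0]))
        a = between_baseline(pt, rows, n_repeats=20, time_window=(0, 0.4), seed=5)
        b = between_baseline(pt, rows, n_repeats=20, time_window=(0, 0.4), seed=5)
        assert np.array_equal(a.baseline, b.baseline)


class TestPairedT:
    def test_equal_conditions_zero(self):
        a = np.random.default_rng(0).normal(size=(6, 4))
        sm = paired_t_map(a, a.copy())
        assert np.allclose(sm.t, 0.0)

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(1)
        sm = paired_t_map(rng.normal(size=(16, 3)), rng.normal(size=(16, 3)))
        assert sm.df == 15

    def test_matches_formula_and_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        sm = paired_t_map(a, b)
        d = a - b
        direct = d.mean(0) / (d.std(0, ddof=1) / 2)
        assert np.allclose(sm.t, direct, atol=1e-12)
        ref = stats.ttest_rel(a, b, axis=0)
        assert np.allclose(sm.t, ref.statistic, atol=1e-10)

    def test_zero_variance_flagging(self):
        a = np.ones((4, 2))
        b = np.ones((4, 2))
        b[:, 1] = 0.5
        sm = paired_t_map(a, b)
        assert sm.t[0] == 0.0
        assert np.isinf(sm.t[1]) and sm.t[1] > 0

    def test_swap_negates(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        assert np.allclose(paired_t_map(a, b).t, -paired_t_map(b, a).t, atol=1e-12)


def brute_force_components(nodes, adj):
    """Union-find oracle for connected components."""
    parent = {int(n): int(n) for n in nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for u in parent:
        for v in parent:
            if u < v and adj[u, v]:
                parent[find(u)] = find(v)
    comps = {}
    for n in parent:
        comps.setdefault(find(n), []).append(n)
    return sorted(sorted(c) for c in comps.values())


class TestFindClusters:
    def test_no_suprathreshold_channels(self):
        sm = StatMap(t=np.zeros(6), df=7)
        assert find_clusters(sm, chain_adjacency(6)) == []

    def test_adjacent_pair_forms_cluster_nonadjacent_does_not(self):
        t = np.zeros(6)
        t[[2, 3]] = 8.0
        sm = StatMap(t=t, df=7)
        res = find_clusters(sm, chain_adjacency(6))
        assert len(res) == 1
        assert list(res[0].channels) == [2, 3]
        assert res[0].mass == pytest.approx(16.0)
        t2 = np.zeros(6)
        t2[[0, 3]] = 8.0  # not adjacent in a chain
        assert find_clusters(StatMap(t=t2, df=7), chain_adjacency(6)) == []

    def test_signs_kept_separate(self):
        t = np.array([8.0, -8.0, -8.0, 0.0, 0.0, 0.0])
        res = find_clusters(StatMap(t=t, df=7), chain_adjacency(6))
        # channel 0 (positive) is alone -> dropped; 1,2 form a negative cluster
        assert len(res) == 1
        assert list(res[0].channels) == [1, 2]
        assert res[0].mass == pytest.approx(-16.0)

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = 6
            adj = rng.random((n, n)) < 0.3
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            nodes = np.flatnonzero(rng.random(n) < 0.7)
            if len(nodes) == 0:
                continue
            mine = sorted(sorted(c.tolist()) for c in _components(nodes, adj))
            assert mine == brute_force_components(nodes, adj)


def brute_force_bh(pvals, alpha):
    """Direct Benjamini-Hochberg: largest k with p_(k) <= k*alpha/m."""
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            thresh = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:thresh]] = True
    return reject


class TestClusterPermutation:
    def test_identical_conditions_nothing_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 10))
        res = cluster_permutation(a, a.copy(), chain_adjacency(10), n_perm=200, seed=0)
        assert len(res.significant_channels) == 0

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(1)
        n_subj, n_ch = 16, 12
        b = rng.normal(0, 0.05, size=(n_subj, n_ch))
        a = b.copy()
        a[:, 4:8] += 0.15  # dz = 3 on channels 4-7
        res = cluster_permutation(a, b, chain_adjacency(n_ch), n_perm=500, seed=1)
        sig = set(res.significant_channels.tolist())
        assert {4, 5, 6, 7} <= sig

    def test_swap_negates_masses(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 0.05, size=(10, 8))
        a = b + rng.normal(0.1, 0.02, size=b.shape)
        r1 = cluster_permutation(a, b, chain_adjacency(8), n_perm=120, seed=3)
        r2 = cluster_permutation(b, a, chain_adjacency(8), n_perm=120, seed=3)
        m1 = sorted(c.mass for c in r1.clusters)
        m2 = sorted(-c.mass for c in r2.clusters)
        assert np.allclose(m1, m2, atol=1e-10)

    def test_add_one_p_estimator_bounds(self):
        rng = np.random.default_rng(3)
        b = rng.normal(0, 0.05, size=(12, 6))
        a = b + 0.2
        res = cluster_permutation(a, b, chain_adjacency(6), n_perm=150, seed=4)
        for c in res.clusters:
            assert 1 / 151 <= c.p <= 1.0

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 4))
        with pytest.warns(UserWarning, match="unstable"):
            cluster_permutation(a, a, chain_adjacency(4), n_perm=50, seed=0)

    def test_fdr_matches_brute_force(self):
        rng = np.random.default_rng(5)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            ps = rng.uniform(0, 0.3, size=rng.integers(1, 7))
            reject, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
            assert np.array_equal(reject, brute_force_bh(ps, 0.05))

    def test_fdr_monotone_in_added_cluster(self):
        # appending a weaker p-value never turns a significant one off
        from statsmodels.stats.multitest import multipletests

        ps = [0.001, 0.004, 0.02]
        r1, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
        r2, *_ = multipletests(ps + [0.9], alpha=0.05, method="fdr_bh")
        assert np.all(r2[:3] >= r1)

    def test_matches_mne_observed_clusters(self):
        mne = pytest.importorskip("mne")
        from scipy import sparse

        rng = np.random.default_rng(6)
        n_subj, n_ch = 12, 10
        b = rng.normal(0, 0.05, size=(n_subj, n_ch))
        a = b + rng.normal(0, 0.03, size=(n_subj, n_ch))
        a[:, 2:6] += 0.12
        diffs = a - b
        df = n_subj - 1
        t_crit = stats.t.ppf(1 - 0.001 / 2, df)
        t_obs, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
            diffs, threshold=t_crit, adjacency=sparse.coo_matrix(chain_adjacency(n_ch)),
            n_permutations=100, tail=0, seed=0, out_type="indices", verbose=False,
        )
        mine = find_clusters(paired_t_map(a, b), chain_adjacency(n_ch),
                             pre_alpha=0.001, min_size=1)
        mne_sets = sorted(sorted(c[0].tolist()) for c in clusters)
        my_sets = sorted(c.channels.tolist() for c in mine)
        assert my_sets == mne_sets
        assert np.allclose(paired_t_map(a, b).t, t_obs, atol=1e-10)


class TestConjunction:
    def _result(self, sig_sets, n_ch=8):
        from imagentrain.groupstats import Cluster, ClusterResult

        clusters = [
            Cluster(channels=np.array(s), mass=5.0 * len(s), p=0.01, p_fdr=0.01,
                    significant=True)
            for s in sig_sets
        ]
        return ClusterResult(
            clusters=clusters, null_distribution=np.zeros(10),
            stat_map=StatMap(t=np.zeros(n_ch), df=7), pre_cluster_alpha=0.001,
            min_size=2, n_permutations=10, cluster_alpha=0.05,
        )

    def test_disjoint_sets_empty(self):
        assert len(conjunction(self._result([[0, 1]]), self._result([[4, 5]]))) == 0

    def test_identical_results_give_the_set(self):
        r = self._result([[2, 3, 4]])
        assert conjunction(r, r).tolist() == [2, 3, 4]

    def test_partial_overlap(self):
        out = conjunction(self._result([[1, 2, 3]]), self._result([[3, 4]]))
        assert out.tolist() == [3]

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError):
            conjunction(self._result([[0]]), self._result([[0]], n_ch=5))


class TestEffectSizes:
    def test_minimal_dz_printed_value(self):
        assert minimal_detectable_dz(0.001, 16).effect == pytest.approx(1.02, abs=0.005)

    def test_minimal_dz_critical_value_oracle(self):
        res = minimal_detectable_dz(0.05, 10)
        assert res.effect == pytest.approx(stats.t.ppf(0.975, 9) / np.sqrt(10), abs=1e-12)

    def test_large_n_normal_limit(self):
        n = 100_000
        assert minimal_detectable_dz(0.05, n).effect == pytest.approx(1.96 / np.sqrt(n), rel=1e-3)

    def test_required_paired_80_power(self):
        res = required_effect_size(0.80, 0.05, 16, "paired")
        assert res.effect == pytest.approx(0.75, abs=0.005)

    def test_required_two_sample_80_power(self):
        res = required_effect_size(0.80, 0.05, 16, "two_sample")
        assert res.effect == pytest.approx(1.02, abs=0.01)
        assert set(res.alternatives) == {"paired", "two_sample"}

    def test_half_power_reduces_to_critical_ratio(self):
        # at 50% power the noncentrality ~ critical value (median of nct)
        res = required_effect_size(0.50, 0.05, 16, "paired")
        assert res.effect == pytest.approx(minimal_detectable_dz(0.05, 16).effect, rel=0.02)

    def test_solution_achieves_requested_power(self):
        from imagentrain.groupstats import _noncentral_t_power

        for design in ("paired", "two_sample"):
            res = required_effect_size(0.80, 0.05, 16, design)
            assert _noncentral_t_power(res.effect, 16, 0.05, design) == pytest.approx(0.80, abs=1e-6)
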