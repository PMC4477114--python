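import numpy as np
import pytest
from scipy import stats as sps

from netsync.dualreg import SubjectNetworkTimecourses
from netsync.stats import (
    EdgeStat,
    behavior_edge_correlation,
    chi_square_2x2,
    edge_group_test,
    fisher_z,
    inter_network_correlation,
    mc_cluster_correction,
    summary_ttest,
    voxelwise_group_test,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(21)


def _tcs(values):
    return SubjectNetworkTimecourses(
        values=values,
        component_ids=[f"IC{k}" for k in range(values.shape[1])],
        subject_id="s",
    )


class TestInterNetworkCorrelation:
    def test_unit_diagonal(self, rng):
        inc = inter_network_correlation(_tcs(rng.standard_normal((30, 3))))
        np.testing.assert_allclose(np.diag(inc.r), 1.0)

    def test_identical_and_negated_columns(self, rng):
        x = rng.standard_normal(50)
        inc = inter_network_correlation(_tcs(np.column_stack([x, x, -x])))
        assert inc.r[0, 1] == pytest.approx(1.0)
        assert inc.r[0, 2] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        inc = inter_network_correlation(_tcs(rng.standard_normal((10000, 2))))
        assert abs(inc.r[0, 1]) < 0.05

    def test_constant_column_rejected(self, rng):
        vals = rng.standard_normal((20, 2))
        vals[:, 1] = 3.0
        with pytest.raises(ValueError, match="constant"):
            inter_network_correlation(_tcs(vals))

    def test_fisher_stored_when_requested(self, rng):
        inc = inter_network_correlation(
            _tcs(rng.standard_normal((30, 3))), store_fisher=True
        )
        assert inc.z is not None
        np.testing.assert_allclose(inc.z[0, 1], np.arctanh(inc.r[0, 1]), atol=1e-10)


class TestSummaryTtest:
    def test_printed_age_row(self):
        _, df, p = summary_ttest(68.3, 6.5, 32, 71.8, 8.2, 32)
        assert df == 62
        assert round(p, 2) == 0.06

    def test_printed_executive_row(self):
        _, _, p = summary_ttest(-0.10, 0.82, 32, 0.24, 0.71, 32)
        assert round(p, 2) == 0.08

    def test_equal_means(self):
        t, _, p = summary_ttest(1.0, 1.0, 10, 1.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 2.0, size=2)
            n1, n2 = rng.integers(3, 40, size=2)
            t, df, p = summary_ttest(m1, s1, int(n1), m2, s2, int(n2))
            ot, op = sps.ttest_ind_from_stats(
                m1, s1, n1, m2, s2, n2, equal_var=True
            )
            assert t == pytest.approx(ot, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)

    @pytest.mark.parametrize(
        "args", [(1, 1, 1, 0, 1, 10), (1, -1, 5, 0, 1, 10), (1, 0, 5, 0, 0, 10)]
    )
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            summary_ttest(*args)


class TestChiSquare:
    def test_printed_sex_table(self):
        _, p = chi_square_2x2(18, 14, 19, 13)
        assert round(p, 2) == 0.80

    def test_proportional_table(self):
        chi2, p = chi_square_2x2(10, 10, 10, 10)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed(self):
        chi2, p = chi_square_2x2(20, 10, 10, 20)
        assert chi2 == pytest.approx(20 / 3, abs=1e-10)
        assert p == pytest.approx(0.0098, abs=5e-4)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(1, 50, size=4)
            chi2, p = chi_square_2x2(int(a), int(b), int(c), int(d))
            res = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(res.statistic, abs=1e-10)
            assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)


def _sample_with_stats(rng, mean, sd, n):
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestEdgeGroupTest:
    def test_identical_groups(self, rng):
        x = rng.standard_normal(10)
        st = edge_group_test(x, x.copy())
        assert st.t == pytest.approx(0.0)
        assert st.p == pytest.approx(1.0)

    def test_printed_edge_effect(self, rng):
        a = _sample_with_stats(rng, 0.30, 0.28, 32)
        b = _sample_with_stats(rng, 0.15, 0.26, 32)
        st = edge_group_test(a, b)
        assert round(st.p, 2) == 0.03

    def test_matches_scipy_oracle(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 0.5
        st = edge_group_test(a, b)
        ot, op = sps.ttest_ind(a, b, equal_var=True)
        assert st.t == pytest.approx(ot, abs=1e-10)
        assert st.p == pytest.approx(op, abs=1e-10)
        assert st.df == 18

    def test_agrees_with_own_summary_stats(self, rng):
        a = rng.standard_normal(15) * 2 + 1
        b = rng.standard_normal(12) - 0.5
        st = edge_group_test(a, b)
        t2, df2, p2 = summary_ttest(
            a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 12
        )
        assert st.t == pytest.approx(t2, abs=1e-12)
        assert st.p == pytest.approx(p2, abs=1e-12)

    def test_age_adjustment_removes_age_driven_difference(self, rng):
        # group difference entirely explained by a shared age slope
        age_a = rng.uniform(60, 70, 40)
        age_b = rng.uniform(70, 80, 40)
        noise = 0.01 * rng.standard_normal(80)
        vals = 0.05 * np.concatenate([age_a, age_b]) + noise
        raw = edge_group_test(vals[:40], vals[40:])
        adj = edge_group_test(
            vals[:40], vals[40:], age_a=age_a, age_b=age_b
        )
        assert raw.p < 0.001
        assert adj.p > 0.05
        assert adj.covariate_adjusted

    def test_age_adjustment_preserves_true_group_difference(self, rng):
        age = rng.uniform(60, 80, 30)
        a = 0.3 + 0.02 * (age[:15] - 70) + 0.01 * rng.standard_normal(15)
        b = -0.3 + 0.02 * (age[15:] - 70) + 0.01 * rng.standard_normal(15)
        adj = edge_group_test(a, b, age_a=age[:15], age_b=age[15:])
        assert adj.p < 1e-6
        assert adj.mean_a - adj.mean_b == pytest.approx(0.6, abs=0.05)

    def test_ages_for_one_group_only_rejected(self, rng):
        with pytest.raises(ValueError, match="both"):
            edge_group_test(
                rng.standard_normal(5), rng.standard_normal(5), age_a=np.ones(5)
            )

    def test_zero_pooled_variance(self):
        with pytest.raises(ValueError, match="pooled variance"):
            edge_group_test(np.ones(5), np.full(5, 2.0))

    def test_fisher_flag_decision_region_bound(self, rng):
        # transforming r -> atanh(r) moves p by < 0.01 wherever p < 0.1
        worst = 0.0
        for _ in range(300):
            a = np.clip(rng.normal(rng.uniform(-0.3, 0.3), 0.2, 32), -0.4, 0.4)
            b = np.clip(rng.normal(rng.uniform(-0.3, 0.3), 0.2, 32), -0.4, 0.4)
            p_raw = edge_group_test(a, b).p
            p_fish = edge_group_test(fisher_z(a), fisher_z(b)).p
            if min(p_raw, p_fish) < 0.1:
                worst = max(worst, abs(p_raw - p_fish))
        assert worst < 0.01


def _edge_stats_from_values(vals, labels_a, edges):
    return [
        edge_group_test(vals[labels_a, e], vals[~labels_a, e], edge=edges[e])
        for e in range(len(edges))
    ]


class TestMcClusterCorrection:
    EDGES = [(i, j) for i in range(5) for j in range(i + 1, 5)]

    def test_no_suprathreshold_edges_gives_empty(self, rng):
        n = 20
        base = rng.normal(0, 0.3, (10, len(self.EDGES)))
        vals = np.vstack([base, base])  # groups identical -> every t = 0
        labels = np.zeros(n, bool)
        labels[:10] = True
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        assert all(s.p >= 0.05 for s in stats)
        out = mc_cluster_correction(
            stats, vals, labels, n_sims=200, edge_alpha=0.05, seed=0
        )
        assert out == []

    def test_planted_three_edge_cluster_significant(self, rng):
        # strong difference on the 3 edges sharing node 4
        n = 64
        labels = np.zeros(n, bool)
        labels[:32] = True
        vals = rng.normal(0, 0.2, (n, len(self.EDGES)))
        target = [e for e, (i, j) in enumerate(self.EDGES) if 4 in (i, j)][:3]
        for e in target:
            vals[labels, e] += 0.30
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        out = mc_cluster_correction(
            stats, vals, labels, n_sims=1000, edge_alpha=0.05, seed=1
        )
        big = [c for c in out if c.size >= 3]
        assert big and big[0].p_corrected < 0.05
        cluster_edges = set(big[0].edges)
        assert {self.EDGES[e] for e in target} <= cluster_edges

    def test_corrected_p_monotone_in_size(self, rng):
        n = 40
        labels = np.zeros(n, bool)
        labels[:20] = True
        vals = rng.normal(0, 0.2, (n, len(self.EDGES)))
        # an isolated strong edge (0,1) plus a disjoint 2-edge cluster
        # sharing node 4 only through nodes 2 and 3
        for e, (i, j) in enumerate(self.EDGES):
            if (i, j) in {(0, 1), (2, 4), (3, 4)}:
                vals[labels, e] += 0.5
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        out = mc_cluster_correction(
            stats, vals, labels, n_sims=500, edge_alpha=0.05, seed=2
        )
        by_size = {c.size: c.p_corrected for c in out}
        sizes = sorted(by_size)
        assert len(sizes) >= 2
        for small, large in zip(sizes, sizes[1:]):
            assert by_size[large] <= by_size[small]

    def test_deterministic(self, rng):
        n = 20
        labels = np.zeros(n, bool)
        labels[:10] = True
        vals = rng.normal(0, 0.3, (n, len(self.EDGES)))
        vals[labels, :3] += 0.6
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        a = mc_cluster_correction(stats, vals, labels, n_sims=300, seed=5)
        b = mc_cluster_correction(stats, vals, labels, n_sims=300, seed=5)
        assert [(c.size, c.p_corrected) for c in a] == [
            (c.size, c.p_corrected) for c in b
        ]

    def test_smoothed_p_never_zero(self, rng):
        n = 30
        labels = np.zeros(n, bool)
        labels[:15] = True
        vals = rng.normal(0, 0.1, (n, len(self.EDGES)))
        vals[labels] += 2.0  # all edges wildly significant
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        out = mc_cluster_correction(stats, vals, labels, n_sims=200, seed=0)
        assert out and all(c.p_corrected >= 1.0 / 201 for c in out)

    def test_too_few_sims_rejected(self, rng):
        n = 10
        labels = np.zeros(n, bool)
        labels[:5] = True
        vals = rng.normal(size=(n, len(self.EDGES)))
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        with pytest.raises(ValueError, match="n_sims"):
            mc_cluster_correction(stats, vals, labels, n_sims=50, seed=0)

    def test_small_sims_warns(self, rng):
        n = 10
        labels = np.zeros(n, bool)
        labels[:5] = True
        vals = rng.normal(size=(n, len(self.EDGES)))
        stats = _edge_stats_from_values(vals, labels, self.EDGES)
        with pytest.warns(UserWarning, match="coarse"):
            mc_cluster_correction(
                stats, vals, labels, n_sims=100, edge_alpha=0.005, seed=0
            )


class TestVoxelwiseGroupTest:
    GRID = (8, 8, 8)

    def _null_maps(self, rng, n=6):
        return [rng.standard_normal(self.GRID) for _ in range(n)]

    def test_label_swap_negates_t_map(self, rng):
        mask = np.ones(self.GRID, bool)
        a = self._null_maps(rng)
        b = self._null_maps(rng)
        r1 = voxelwise_group_test(a, b, mask, n_perm=100, seed=0)
        r2 = voxelwise_group_test(b, a, mask, n_perm=100, seed=0)
        np.testing.assert_allclose(r1.t_map, -r2.t_map, atol=1e-10)
        np.testing.assert_allclose(r1.z_map, -r2.z_map, atol=1e-10)

    def test_planted_blob_detected(self, rng):
        mask = np.ones(self.GRID, bool)
        blob = np.zeros(self.GRID, bool)
        blob[2:5, 2:5, 2:5] = True
        a = [rng.standard_normal(self.GRID) + 5.0 * blob for _ in range(8)]
        b = [rng.standard_normal(self.GRID) for _ in range(8)]
        res = voxelwise_group_test(
            a, b, mask, n_perm=500, cluster_z=2.3, alpha=0.05, seed=3
        )
        assert len(res.clusters) == 1
        voxels = res.clusters[0]["voxels"]
        # the significant cluster covers most of the blob and little else
        assert (voxels & blob).sum() >= 0.5 * blob.sum()
        assert (voxels & ~blob).sum() <= 0.5 * voxels.sum()

    def test_deterministic(self, rng):
        mask = np.ones(self.GRID, bool)
        a, b = self._null_maps(rng), self._null_maps(rng)
        r1 = voxelwise_group_test(a, b, mask, n_perm=100, seed=7)
        r2 = voxelwise_group_test(a, b, mask, n_perm=100, seed=7)
        np.testing.assert_array_equal(r1.null_max_extent, r2.null_max_extent)

    def test_degenerate_variance_warns(self, rng):
        mask = np.ones(self.GRID, bool)
        a = [np.zeros(self.GRID) for _ in range(3)]
        b = [np.zeros(self.GRID) for _ in range(3)]
        a[0][0, 0, 0] = 1.0  # only one voxel varies
        with pytest.warns(UserWarning, match="degenerate"):
            voxelwise_group_test(a, b, mask, n_perm=100, seed=0)


class TestBehaviorCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(20)
        r, p = behavior_edge_correlation(x, x.copy())
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            r, p = behavior_edge_correlation(x, y)
            res = sps.pearsonr(x, y)
            assert r == pytest.approx(res.statistic, abs=1e-12)
            assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_planted_negative_association_sign_recovery(self, rng):
        hits = 0
        for _ in range(100):
            edge = rng.normal(0.2, 0.25, 32)
            score = -1.0 * edge + 0.2 * rng.standard_normal(32)
            r, _ = behavior_edge_correlation(edge, score)
            hits += r < 0
        assert hits >= 95

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            ps.append(behavior_edge_correlation(x, y)[1])
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_constant_input_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            behavior_edge_correlation(np.ones(10), rng.standard_normal(10))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            behavior_edge_correlation(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


class TestEdgeStatInvariants:
    def test_edge_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            EdgeStat(
                edge=(2, 1), mean_a=0, sd_a=1, mean_b=0, sd_b=1, t=0.0, df=10, p=0.5
            )

    def test_p_range_enforced(self):
        with pytest.raises(ValueError, match="p out of"):
            EdgeStat(
                edge=(0, 1), mean_a=0, sd_a=1, mean_b=0, sd_b=1, t=0.0, df=10, p=1.5
            )
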