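import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedgca import group_stats as gs


class TestFdrThreshold:
    def test_hand_worked_step_up(self):
        cutoff, flags = gs.fdr_threshold([0.01, 0.02, 0.03, 0.2, 0.5], q=0.05)
        assert cutoff == pytest.approx(0.03)
        assert flags.sum() == 3

    def test_no_rejections_when_all_one(self):
        cutoff, flags = gs.fdr_threshold(np.ones(20), q=0.05)
        assert cutoff == 0.0 and not flags.any()

    def test_matches_statsmodels_and_bruteforce_oracles(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(31)
        for _ in range(200):
            m = rng.integers(1, 51)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            cutoff, flags = gs.fdr_threshold(p, q=0.05)
            sm_flags = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(flags, sm_flags)
            # brute force: try every observed p as the cutoff
            best = 0.0
            srt = np.sort(p)
            for i, cand in enumerate(srt, start=1):
                if cand <= 0.05 * i / m:
                    best = cand
            assert cutoff == pytest.approx(best)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            gs.fdr_threshold([], 0.05)
        with pytest.raises(ValueError):
            gs.fdr_threshold([0.5, 1.2], 0.05)


class TestClusterFiltering:
    def test_min_cluster_size_boundary(self):
        grid = np.zeros((20, 5, 5), bool)
        grid[0:9, 0, 0] = True  # 9-voxel line: removed
        grid[10:20, 2, 2] = True  # 10-voxel line: kept
        out = gs.filter_clusters(grid, min_cluster_size=10)
        assert not out[0:9, 0, 0].any()
        assert out[10:20, 2, 2].all()

    def test_corner_touching_voxels_connectivity(self):
        grid = np.zeros((4, 4, 4), bool)
        grid[1, 1, 1] = grid[2, 2, 2] = True  # touch only at a corner
        assert gs.filter_clusters(grid, 2, connectivity=26).sum() == 2
        assert gs.filter_clusters(grid, 2, connectivity=6).sum() == 0

    def test_monotone_in_cluster_size(self):
        rng = np.random.default_rng(32)
        grid = rng.random((12, 12, 6)) < 0.3
        prev = gs.filter_clusters(grid, 1)
        for size in (3, 6, 10, 20):
            cur = gs.filter_clusters(grid, size)
            assert not (cur & ~prev).any()  # raising the size never adds voxels
            prev = cur


class TestGroupMeanMap:
    def test_identical_maps(self):
        m = np.random.default_rng(33).standard_normal((4, 4, 2))
        mean, cov = gs.group_mean_map([m, m, m])
        np.testing.assert_allclose(mean, m)
        assert (cov == 3).all()

    def test_missing_voxel_excluded_with_coverage(self):
        maps = [np.full((2, 2, 1), float(i)) for i in range(5)]
        maps[0][0, 0, 0] = np.nan
        mean, cov = gs.group_mean_map(maps)
        assert mean[0, 0, 0] == pytest.approx(np.mean([1, 2, 3, 4]))
        assert cov[0, 0, 0] == 4 and cov[1, 1, 0] == 5

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            gs.group_mean_map([np.zeros((2, 2, 2))])


class TestTwoSampleTMap:
    def _stacks(self, delta=0.0, seed=34, n1=10, n2=10, shape=(6, 6, 3)):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n1,) + shape)
        b = rng.standard_normal((n2,) + shape) + delta
        return a, b

    def test_group_swap_negates_t(self):
        a, b = self._stacks(delta=0.5)
        mask = np.ones(a.shape[1:], bool)
        ab = gs.two_sample_t_map(a, b, mask)
        ba = gs.two_sample_t_map(b, a, mask)
        np.testing.assert_allclose(ab.t_values, -ba.t_values, atol=1e-12)

    def test_matches_scipy_at_single_voxel(self):
        a, b = self._stacks(delta=0.8)
        mask = np.ones(a.shape[1:], bool)
        out = gs.two_sample_t_map(a, b, mask)
        t_ref, p_ref = stats.ttest_ind(a[:, 0, 0, 0], b[:, 0, 0, 0])
        assert out.t_values[0, 0, 0] == pytest.approx(t_ref)
        assert out.p_values[0, 0, 0] == pytest.approx(p_ref)

    def test_zero_variance_voxel_flagged(self):
        a, b = self._stacks()
        a[:, 0, 0, 0] = 1.0
        b[:, 0, 0, 0] = 1.0
        out = gs.two_sample_t_map(a, b, np.ones(a.shape[1:], bool))
        assert np.isnan(out.t_values[0, 0, 0])

    def test_planted_block_power_at_population_t_four(self):
        """A block whose group shift gives a per-voxel population t of ~4
        (independent subject noise) survives FDR + cluster extent in at
        least 90% of 20 replicate map stacks."""
        n1, n2 = 22, 21
        shape = (12, 12, 6)
        delta = 4.0 * np.sqrt(1.0 / n1 + 1.0 / n2)  # unit subject noise
        rng = np.random.default_rng(39)
        hits = 0
        for _ in range(20):
            a = rng.standard_normal((n1,) + shape)
            b = rng.standard_normal((n2,) + shape)
            a[:, 3:7, 3:7, 1:4] += delta  # planted block, population t = 4
            mask = np.ones(shape, bool)
            out = gs.two_sample_t_map(a, b, mask, q=0.05)
            clusters = gs.extract_clusters(out, min_cluster_size=10)
            block = np.zeros(shape, bool)
            block[3:7, 3:7, 1:4] = True
            hits += any(
                c.direction == "increased" and block[tuple(c.voxels.T)].any()
                for c in clusters
            )
        assert hits >= 18

    def test_significance_restricted_to_analysis_mask(self):
        a, b = self._stacks(delta=3.0)
        mask = np.zeros(a.shape[1:], bool)
        mask[0:3] = True
        out = gs.two_sample_t_map(a, b, mask)
        assert not (out.significance_mask & ~mask).any()
        assert out.significance_mask.any()


class TestSummaryStatistics:
    def test_pooled_t_zero_for_equal_groups(self):
        t, p, df = gs.pooled_t_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0) and df == 20

    def test_pooled_t_matches_scipy_from_raw_data(self):
        rng = np.random.default_rng(35)
        a, b = rng.standard_normal(22) + 1.0, rng.standard_normal(21)
        t_ref, p_ref = stats.ttest_ind(a, b)
        t, p, _ = gs.pooled_t_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_kruskal_wallis_matches_scipy_oracle(self):
        for (a_counts, b_counts) in [((16, 6), (15, 6)), ((10, 5), (3, 12)), ((8, 1), (2, 7))]:
            h, p = gs.kruskal_wallis_binary(a_counts, b_counts)
            a = np.repeat([0, 1], a_counts)
            b = np.repeat([0, 1], b_counts)
            h_ref, p_ref = stats.kruskal(a, b)
            assert h == pytest.approx(h_ref)
            assert p == pytest.approx(p_ref)

    def test_kruskal_wallis_identical_groups(self):
        h, p = gs.kruskal_wallis_binary((10, 5), (10, 5))
        assert h == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_kruskal_wallis_degenerate_category(self):
        with pytest.warns(UserWarning, match="degenerate"):
            h, p = gs.kruskal_wallis_binary((5, 0), (7, 0))
        assert p == 1.0


class TestClusterCorrelation:
    def _cluster(self, shape=(3, 3, 1)):
        voxels = np.argwhere(np.ones(shape, bool))[:4]
        return gs.ClusterResult(
            voxels=voxels, size=4, direction="increased", peak_index=(0, 0, 0)
        )

    def _records(self, scores, group="SAD"):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(scores))],
                "group": group,
                "lsas_avoidance": scores,
            }
        )

    def test_perfectly_linear_scores(self):
        cluster = self._cluster()
        maps = [np.full((3, 3, 1), float(i)) for i in range(10)]
        res = gs.cluster_correlation(
            cluster, maps, self._records(2.0 * np.arange(10) + 1), "lsas_avoidance"
        )
        assert res["SAD"]["r"] == pytest.approx(1.0)
        assert res["SAD"]["p"] < 1e-6

    def test_orthogonal_contrast_gives_zero(self):
        cluster = self._cluster()
        maps = [np.full((3, 3, 1), v) for v in (-1.0, 0.0, 1.0)]
        res = gs.cluster_correlation(
            cluster, maps, self._records([1.0, -2.0, 1.0]), "lsas_avoidance"
        )
        assert res["SAD"]["r"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_scores_undefined(self):
        cluster = self._cluster()
        maps = [np.full((3, 3, 1), float(i)) for i in range(5)]
        res = gs.cluster_correlation(
            cluster, maps, self._records(np.ones(5)), "lsas_avoidance"
        )
        assert np.isnan(res["SAD"]["r"])


class TestGroupSignificanceMask:
    def test_planted_block_survives_and_background_does_not(self):
        rng = np.random.default_rng(36)
        shape = (10, 10, 5)
        stack = rng.standard_normal((15,) + shape) * 0.005 + 0.005
        stack[:, 2:5, 2:5, 1:4] += 0.05  # strong consistent influence block
        mask = gs.significance_mask_for_group(stack, q=0.05, min_cluster_size=10,
                                              null_mean=0.005)
        assert mask[2:5, 2:5, 1:4].mean() > 0.9
        assert mask[6:, 6:, :].sum() == 0

    def test_fisher_variant(self):
        rng = np.random.default_rng(37)
        shape = (8, 8, 4)
        p_maps = rng.uniform(size=(12,) + shape)
        p_maps[:, 0:3, 0:3, 0:3] = rng.uniform(0.0005, 0.005, size=(12, 3, 3, 3))
        mask = gs.significance_mask_for_group(
            None, method="fisher", subject_p_maps=p_maps, min_cluster_size=5
        )
        assert mask[0:3, 0:3, 0:3].mean() > 0.9

    def test_empty_result_for_pure_null(self):
        rng = np.random.default_rng(38)
        stack = rng.standard_normal((10, 6, 6, 3))
        mask = gs.significance_mask_for_group(stack, q=0.05, null_mean=0.0)
        assert mask.sum() == 0  # nothing consistently above the null mean


class TestTable1Summary:
    def test_summary_structure(self, tiny_cohort):
        table = gs.table1_summary(tiny_cohort.records_frame())
        assert "sex (male/female)" in table["measure"].values
        assert {"lsas_total", "lsas_avoidance"} <= set(table["measure"])
        row = table[table["measure"] == "lsas_fear"].iloc[0]
        assert np.isfinite(row["t"]) and 0 <= row["p"] <= 1
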