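"""Group-inference tests: ANOVA/cluster/permutation machinery vs oracles."""

import numpy as np
import pytest
from scipy import stats

import dynfc
from dynfc import inference
from dynfc.summary_stats import moment_exact_sample


def three_group_design(n=10):
    return inference.GroupDesign(("FOG",) * n + ("NFOG",) * n + ("HC",) * n)


class TestGroupDesign:
    def test_requires_three_groups_of_two(self):
        with pytest.raises(ValueError):
            inference.GroupDesign(("A", "A", "B", "B"))
        with pytest.raises(ValueError):
            inference.GroupDesign(("A", "A", "B", "B", "C"))


class TestVoxelwiseAnova:
    def test_reproduces_summary_statistic_on_moment_exact_samples(self):
        # groups constructed to the printed age summaries give F = 0.267
        rows = [(65.320, 8.385), (65.240, 6.796), (63.880, 8.212)]
        vals = np.concatenate([moment_exact_sample(m, s, 25, rng=k)
                               for k, (m, s) in enumerate(rows)])
        F, df = inference.voxelwise_oneway_anova(vals[:, None],
                                                three_group_design(25))
        assert df == (2, 72)
        assert F[0] == pytest.approx(0.267, abs=5e-4)

    def test_identical_groups_give_zero(self):
        maps = np.ones((30, 2, 2, 2)) * 1.7
        F, _ = inference.voxelwise_oneway_anova(maps, three_group_design(10))
        assert np.all(F == 0)

    def test_matches_sum_of_squares_oracle_and_scipy(self, rng):
        maps = rng.standard_normal((30, 3, 2, 1))
        design = three_group_design(10)
        F, _ = inference.voxelwise_oneway_anova(maps, design)
        flat = maps.reshape(30, -1)
        for v in range(flat.shape[1]):
            groups = [flat[design.indices(g), v] for g in design.group_names]
            # direct sum-of-squares computation
            grand = np.concatenate(groups).mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            expected = (ssb / 2) / (ssw / 27)
            assert F.reshape(-1)[v] == pytest.approx(expected, abs=1e-10)
            assert F.reshape(-1)[v] == pytest.approx(
                stats.f_oneway(*groups).statistic, abs=1e-10)

    def test_misaligned_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.voxelwise_oneway_anova(rng.standard_normal((7, 2, 2, 2)),
                                             three_group_design(2))


class TestClusterLabel:
    def test_empty_and_two_blobs(self):
        grid = np.zeros((6, 6, 6))
        assert inference.cluster_label(grid, 1.0) == []
        grid[0, 0, 0:3] = 5.0
        grid[4, 4, 2:5] = 7.0
        clusters = inference.cluster_label(grid, 1.0)
        assert [c.size for c in clusters] == [3, 3]
        peaks = {c.peak_f for c in clusters}
        assert peaks == {5.0, 7.0}

    def test_diagonal_touching_depends_on_connectivity(self):
        grid = np.zeros((3, 3, 3))
        grid[0, 0, 0] = grid[1, 1, 1] = 2.0
        c26 = inference.cluster_label(grid, 1.0, connectivity=26)
        c6 = inference.cluster_label(grid, 1.0, connectivity=6)
        assert len(c26) == 1 and c26[0].size == 2
        assert len(c6) == 2 and all(c.size == 1 for c in c6)

    def test_peak_is_max_member(self, rng):
        grid = np.zeros((5, 5, 5))
        grid[1:4, 1:4, 1:4] = rng.uniform(2, 9, (3, 3, 3))
        c = inference.cluster_label(grid, 1.0)[0]
        assert c.peak_f == grid.max()
        assert grid[c.peak_coord] == grid.max()


class TestPermutationFWE:
    def test_identical_maps_never_significant(self, rng):
        maps = np.tile(rng.standard_normal((1, 4, 4, 4)), (12, 1, 1, 1))
        out = inference.permutation_cluster_fwe(maps, three_group_design(4),
                                                n_perm=100, rng=0)
        assert out == []

    def test_seeded_reruns_identical(self, rng):
        maps = rng.standard_normal((12, 5, 5, 5))
        design = three_group_design(4)
        a = inference.permutation_cluster_fwe(maps, design, cdt_p=0.05,
                                              n_perm=120, rng=7)
        b = inference.permutation_cluster_fwe(maps, design, cdt_p=0.05,
                                              n_perm=120, rng=7)
        assert [(c.size, c.p_fwe) for c in a] == [(c.size, c.p_fwe) for c in b]

    def test_huge_planted_offset_detected(self, rng):
        maps = rng.standard_normal((30, 6, 6, 6))
        design = three_group_design(10)
        maps[np.asarray(design.indices("FOG"))[:, None, None, None],
             np.arange(2)[:, None, None], np.arange(2)[:, None], np.arange(2)] += 5.0
        out = inference.permutation_cluster_fwe(maps, design, n_perm=199, rng=1)
        assert any(c.significant for c in out)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.permutation_cluster_fwe(
                rng.standard_normal((6, 2, 2, 2)), three_group_design(2),
                n_perm=50, rng=0)


class TestClusterMeansAndPosthoc:
    def test_extract_means_matches_oracle(self, rng):
        maps = rng.standard_normal((9, 4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 0] = True
        cluster = inference.ClusterResult(size=4, peak_coord=(1, 1, 0),
                                          peak_f=1.0, member_voxels=mask)
        means = inference.extract_cluster_means(maps, cluster)
        np.testing.assert_allclose(means, maps[:, mask].mean(axis=1), atol=1e-12)
        one = np.zeros((4, 4, 4), bool)
        one[2, 2, 2] = True
        c1 = inference.ClusterResult(size=1, peak_coord=(2, 2, 2), peak_f=1.0,
                                     member_voxels=one)
        np.testing.assert_allclose(inference.extract_cluster_means(maps, c1),
                                   maps[:, 2, 2, 2])

    def test_equal_groups_not_significant(self, rng):
        design = three_group_design(8)
        vals = np.tile(rng.standard_normal(8), 3)
        res = inference.posthoc_pairwise(vals, design)
        assert len(res) == 3
        assert all(abs(r.t) < 1e-12 and not r.significant for r in res)

    def test_reproduces_summary_t_on_moment_exact_samples(self):
        # illness-duration summaries: pooled t between the patient groups
        vals = np.concatenate([
            moment_exact_sample(7.440, 4.435, 25, rng=1),
            moment_exact_sample(6.700, 2.309, 25, rng=2),
            moment_exact_sample(0.0, 1.0, 25, rng=3)])
        res = inference.posthoc_pairwise(vals, three_group_design(25))
        fog_nfog = [r for r in res if r.pair == ("FOG", "NFOG")][0]
        assert fog_nfog.t == pytest.approx(0.740, abs=5e-4)
        assert fog_nfog.df == 48
        assert fog_nfog.direction == 1

    def test_detection_rate_of_one_sd_offset_matches_power_oracle(self):
        # planted 1-SD FOG offset at n=25: detection frequency at the 0.001
        # alpha should match the noncentral-t power calculation
        n, sims, alpha = 25, 60, 0.001
        tcrit = stats.t.isf(alpha / 2, 2 * n - 2)
        ncp = 1.0 * np.sqrt(n / 2)
        power = stats.nct.sf(tcrit, 2 * n - 2, ncp) + stats.nct.cdf(
            -tcrit, 2 * n - 2, ncp)
        hits = 0
        rng = np.random.default_rng(99)
        for _ in range(sims):
            vals = np.concatenate([rng.standard_normal(n) + 1.0,
                                   rng.standard_normal(n),
                                   rng.standard_normal(n)])
            res = inference.posthoc_pairwise(vals, three_group_design(n))
            fog_hc = [r for r in res if r.pair == ("FOG", "HC")][0]
            hits += fog_hc.significant
        se = np.sqrt(power * (1 - power) / sims)
        assert abs(hits / sims - power) < 4 * se + 0.02


class TestClinicalCorrelation:
    def test_exact_arithmetic_case(self):
        # sample pairs constructed to r = 0.414 at n = 25 give p = 0.040
        rng = np.random.default_rng(0)
        x = rng.standard_normal(25)
        e = rng.standard_normal(25)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= (e @ x) / (x @ x) * x
        e /= e.std()
        y = 0.414 * x + np.sqrt(1 - 0.414 ** 2) * e
        r, p = inference.correlate_clinical(x, y)
        assert r == pytest.approx(0.414, abs=1e-10)
        assert round(p, 3) == 0.040

    def test_perfect_line(self):
        x = np.arange(10.0)
        r, p = inference.correlate_clinical(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(500):
            r, p = inference.correlate_clinical(rng.standard_normal(20),
                                                rng.standard_normal(20))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            inference.correlate_clinical(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            inference.correlate_clinical(np.arange(2.0), np.arange(2.0))


class TestWindowLengthValidation:
    def test_planted_effect_direction_retained_at_50tr(self):
        spec = dynfc.dynamic_effect_spec(rng_seed=21, n_per_group=10,
                                         n_volumes=185)
        subs, atlas, _ = dynfc.generate_cohort(spec)
        pre = [dynfc.preprocess_subject(s)[0] for s in subs]
        design = inference.GroupDesign(tuple(s.group for s in pre))
        mask = atlas.voxels(101)
        cluster = inference.ClusterResult(size=int(mask.sum()),
                                          peak_coord=(0, 0, 0), peak_f=0.0,
                                          member_voxels=mask)
        table30 = inference.validate_window_length(
            pre, atlas, [(11, cluster)], design,
            spec_50tr=dynfc.WindowSpec(length_tr=30))
        table50 = inference.validate_window_length(
            pre, atlas, [(11, cluster)], design)
        assert table30.loc[0, "highest_group"] == "FOG"
        assert table50.loc[0, "highest_group"] == "FOG"
        assert table50.loc[0, "window_length_tr"] == 50
        assert table50.loc[0, "mean_FOG"] > table50.loc[0, "mean_HC"]

    def test_null_cohort_shows_no_strong_difference(self):
        spec = dynfc.null_cohort_spec(rng_seed=8, n_per_group=5,
                                      n_volumes=120)
        subs, atlas, _ = dynfc.generate_cohort(spec)
        pre = [dynfc.preprocess_subject(s)[0] for s in subs]
        design = inference.GroupDesign(tuple(s.group for s in pre))
        mask = atlas.voxels(101)
        cluster = inference.ClusterResult(size=int(mask.sum()),
                                          peak_coord=(0, 0, 0), peak_f=0.0,
                                          member_voxels=mask)
        table = inference.validate_window_length(pre, atlas, [(11, cluster)],
                                                 design)
        assert table.loc[0, "p"] > 0.001
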