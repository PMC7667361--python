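"""Group inference: GLM, cluster extent, effect sizes, correlations, FDR."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import fcdmap as fm
from fcdmap import stats as st
from oracles import alphasim_null_bruteforce, bh_stepup, cohen_d_textbook, pearson_loop


def toy_cohort(n_per_group, rng):
    return pd.DataFrame(
        {
            "group": ["patient"] * n_per_group + ["control"] * n_per_group,
            "age": rng.uniform(25, 65, 2 * n_per_group),
            "gender": rng.choice(["F", "M"], 2 * n_per_group),
            "mean_fd": rng.uniform(0.02, 0.2, 2 * n_per_group),
        }
    )


class TestVoxelGLM:
    def test_identical_maps_give_t_zero(self, rng):
        maps = np.tile(rng.normal(size=(5, 5, 5)), (12, 1, 1, 1))
        cohort = toy_cohort(6, rng)
        design, names = st.build_design(cohort)
        out = st.fit_voxel_glm(maps, design, np.ones((5, 5, 5), dtype=bool))
        np.testing.assert_allclose(out.t, 0.0, atol=1e-10)

    def test_reduces_to_two_sample_t_without_covariates(self, rng):
        """GLM with [intercept, group] only must equal the classical
        pooled-variance two-sample t, voxel for voxel."""
        n = 9
        maps = rng.normal(size=(2 * n, 4, 4, 4))
        design = np.column_stack([np.ones(2 * n), np.r_[np.ones(n), np.zeros(n)]])
        mask = np.ones((4, 4, 4), dtype=bool)
        out = st.fit_voxel_glm(maps, design, mask)
        direct_t, direct_p = sstats.ttest_ind(maps[:n], maps[n:], axis=0)
        np.testing.assert_allclose(out.t, direct_t, atol=1e-10)
        np.testing.assert_allclose(out.p, direct_p, atol=1e-10)
        assert out.df == 2 * n - 2

    def test_recovers_planted_mean_shift(self, rng):
        """Group-coefficient estimate lands within ~3 SE of the planted
        shift at n = 27 + 27."""
        n = 27
        delta = 1.2
        noise_sd = 1.0
        maps = rng.normal(scale=noise_sd, size=(2 * n, 3, 3, 3))
        maps[:n, 1, 1, 1] += delta
        cohort = toy_cohort(n, rng)
        design, names = st.build_design(cohort)
        out = st.fit_voxel_glm(maps, design, np.ones((3, 3, 3), dtype=bool))
        se = noise_sd * np.sqrt(2.0 / n)
        assert abs(out.beta[1, 1, 1] - delta) < 3.5 * se

    def test_rank_deficient_design_names_columns(self, rng):
        cohort = toy_cohort(5, rng)
        design, names = st.build_design(cohort)
        design = np.column_stack([design, design[:, 1]])  # duplicate group
        with pytest.raises(ValueError, match="collinear"):
            st.fit_voxel_glm(
                rng.normal(size=(10, 2, 2, 2)), design,
                np.ones((2, 2, 2), dtype=bool),
                column_names=names + ["dup"],
            )


class TestClusterLabeling:
    AFF = np.diag([3.0, 3.0, 3.0, 1.0])

    def stat_with(self, voxels, shape=(8, 8, 8), value=10.0):
        out = np.zeros(shape)
        for v in voxels:
            out[v] = value
        return out

    def test_rmm5_connects_face_and_edge_not_corner(self):
        """On a 3 mm grid, rmm = 5 spans 3 mm (face) and 4.24 mm (edge)
        but not 5.2 mm (corner) neighbour distances."""
        face = self.stat_with([(2, 2, 2), (3, 2, 2)])
        edge = self.stat_with([(2, 2, 2), (3, 3, 2)])
        corner = self.stat_with([(2, 2, 2), (3, 3, 3)])
        assert len(fm.label_clusters(face, 5.0, self.AFF, rmm=5.0)) == 1
        assert len(fm.label_clusters(edge, 5.0, self.AFF, rmm=5.0)) == 1
        assert len(fm.label_clusters(corner, 5.0, self.AFF, rmm=5.0)) == 2

    def test_empty_suprathreshold_set(self):
        assert fm.label_clusters(np.zeros((5, 5, 5)), 3.0, self.AFF) == []

    def test_three_voxel_line_single_cluster_with_peak(self):
        stat = np.zeros((8, 8, 8))
        stat[2, 4, 4] = 6.0
        stat[3, 4, 4] = 9.0
        stat[4, 4, 4] = 7.0
        (cluster,) = fm.label_clusters(stat, 5.0, self.AFF, rmm=5.0)
        assert cluster.size == 3
        assert cluster.peak_stat == 9.0
        np.testing.assert_array_equal(cluster.peak_index, [3, 4, 4])

    def test_positive_and_negative_labeled_separately(self):
        stat = np.zeros((8, 8, 8))
        stat[2, 2, 2] = 8.0
        stat[3, 2, 2] = -8.0  # adjacent but opposite sign
        clusters = fm.label_clusters(stat, 5.0, self.AFF, rmm=5.0)
        assert len(clusters) == 2
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_enumeration_order_invariance(self, rng):
        stat = rng.normal(size=(8, 8, 8)) * 3
        a = fm.label_clusters(stat, 4.0, self.AFF, rmm=5.0)
        b = fm.label_clusters(stat[::-1].copy()[::-1].copy(), 4.0, self.AFF, rmm=5.0)
        assert sorted(c.size for c in a) == sorted(c.size for c in b)


class TestAlphaSim:
    MASK = None

    @classmethod
    def setup_class(cls):
        from fcdmap.simulate import ellipsoid_mask

        cls.MASK = ellipsoid_mask((8, 8, 8))
        cls.AFF = np.diag([3.0, 3.0, 3.0, 1.0])

    def test_degenerate_voxel_p_nothing_passes(self):
        cfg = fm.AlphaSimConfig(voxel_p=1.0, iterations=5, fwhm=0.0, seed=0)
        k_min, null = fm.alphasim_extent(self.MASK, self.AFF, cfg)
        assert np.all(null == self.MASK.sum())
        assert k_min > self.MASK.sum()

    def test_null_distribution_matches_bruteforce(self):
        """fwhm 0, voxel p .05: the null max-cluster distribution matches an
        independently coded flood-fill simulation within binomial error."""
        cfg = fm.AlphaSimConfig(voxel_p=0.05, iterations=800, fwhm=0.0, rmm=5.0, seed=3)
        _, null_impl = fm.alphasim_extent(self.MASK, self.AFF, cfg)
        null_oracle = alphasim_null_bruteforce(
            self.MASK, 3.0, 0.05, 5.0, 800, np.random.default_rng(17)
        )
        for k in (2, 3, 4, 5, 7):
            p_impl = np.mean(null_impl >= k)
            p_orac = np.mean(null_oracle >= k)
            se = np.sqrt(max(p_orac * (1 - p_orac), 1e-4) / 800)
            assert abs(p_impl - p_orac) < 4 * se + 0.01

    def test_extent_nondecreasing_in_fwhm(self):
        ks = []
        for fwhm in (0.0, 6.0):
            cfg = fm.AlphaSimConfig(voxel_p=0.01, iterations=400, fwhm=fwhm, seed=5)
            k_min, _ = fm.alphasim_extent(self.MASK, self.AFF, cfg)
            ks.append(k_min)
        assert ks[1] >= ks[0]

    def test_extent_threshold_helper(self):
        null = np.array([1, 1, 1, 2, 2, 3, 5, 8, 9, 10])
        # P(max >= 9) = 0.2, P(max >= 10) = 0.1, P(max >= 11) = 0
        assert st.extent_threshold(null, alpha=0.10) == 10
        assert st.extent_threshold(null, alpha=0.05) == 11


class TestEffectSizes:
    def test_equal_means_give_zero(self):
        assert fm.cohen_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_unit_case(self, rng):
        x1 = rng.normal(1.0, 1.0, 400_000)
        x2 = rng.normal(0.0, 1.0, 400_000)
        assert fm.cohen_d(x1, x2) == pytest.approx(1.0, abs=0.02)

    def test_matches_textbook_formula(self, rng):
        x1 = rng.normal(size=23)
        x2 = rng.normal(size=31)
        assert fm.cohen_d(x1, x2) == pytest.approx(cohen_d_textbook(x1, x2), abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            fm.cohen_d([2.0, 2.0], [1.0, 1.0])


class TestSummaryTests:
    def test_psqi_row_reproduces_printed_t(self):
        t, p = fm.two_sample_t_summary(13.29, 2.54, 27, 0.86, 1.06, 27)
        assert t == pytest.approx(23.489, abs=0.05)
        assert p < 1e-4

    def test_age_row_reproduces_printed_t(self):
        t, p = fm.two_sample_t_summary(42.59, 11.59, 27, 40.92, 11.46, 27)
        assert t == pytest.approx(0.531, abs=0.005)
        assert p == pytest.approx(0.598, abs=0.005)

    def test_equal_summaries_give_zero(self):
        t, p = fm.two_sample_t_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == 1.0

    def test_identical_constant_groups(self):
        t, p = fm.two_sample_t_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert t == 0.0 and p == 1.0

    def test_gender_table_chi_square_zero(self):
        stat, p = fm.chi_square_2x2([[17, 10], [17, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        stat, _ = fm.chi_square_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0, abs=1e-10)

    def test_proportional_rows_give_zero(self):
        stat, _ = fm.chi_square_2x2([[6, 9], [2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fm.chi_square_2x2([[0, 0], [5, 5]])


class TestPartialCorrelation:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        rho, p = fm.partial_correlation(x, x.copy(), cov)
        assert rho == pytest.approx(1.0, abs=1e-10)

    def test_no_covariates_equals_pearson(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.5 * x
        rho, _ = fm.partial_correlation(x, y)
        assert rho == pytest.approx(pearson_loop(x, y), abs=1e-12)

    def test_confound_induced_correlation_removed(self, rng):
        """x and y only share a confound; partialling it out leaves ~0."""
        n = 4000
        c = rng.normal(size=n)
        x = 2.0 * c + rng.normal(size=n)
        y = -1.5 * c + rng.normal(size=n)
        raw, _ = fm.partial_correlation(x, y)
        part, _ = fm.partial_correlation(x, y, c)
        assert abs(raw) > 0.4
        assert abs(part) < 0.06

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        z = rng.normal(size=40)
        ours_rho, ours_p = fm.partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours_rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fm.partial_correlation([1, 2], [3, 4], None)


class TestBhFdr:
    def test_all_equal_p(self):
        np.testing.assert_allclose(fm.bh_fdr([0.02] * 5), 0.02)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            fm.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_independent_stepup(self, rng):
        p = rng.uniform(0.001, 1.0, size=37)
        np.testing.assert_allclose(fm.bh_fdr(p), bh_stepup(p), atol=1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(0.001, 1.0, size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(fm.bh_fdr(p)[perm], fm.bh_fdr(p[perm]), atol=1e-12)

    def test_null_calibration(self, rng):
        """Uniform-null p-values: selecting q < .05 yields a false-discovery
        proportion consistent with 0.05."""
        fdps = []
        for _ in range(20):
            p = rng.uniform(size=10_000)
            q = fm.bh_fdr(p)
            fdps.append(np.count_nonzero(q < 0.05) / 10_000)
        assert np.mean(fdps) <= 0.05 + 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fm.bh_fdr([0.5, 0.0])

    def test_empty_input(self):
        assert fm.bh_fdr([]).size == 0


class TestClusterReport:
    def test_empty_table_keeps_header(self):
        table = st.cluster_report([], 5, np.zeros((4, 3, 3, 3)),
                                  np.array([True, True, False, False]),
                                  np.array([False, False, True, True]))
        assert list(table.columns)[:2] == ["label", "size"]
        assert len(table) == 0

    def test_equal_group_means_give_d_zero(self, rng):
        idx = np.array([[1, 1, 1], [1, 1, 2]])
        cluster = st.Cluster(indices=idx, sign=1, peak_index=idx[0],
                             peak_stat=5.0, peak_mm=np.zeros(3))
        maps = rng.normal(size=(8, 4, 4, 4))
        maps[4:] = maps[:4]  # mirror groups -> identical means
        table = st.cluster_report([cluster], 1, maps,
                                  np.r_[np.ones(4, bool), np.zeros(4, bool)],
                                  np.r_[np.zeros(4, bool), np.ones(4, bool)])
        assert table["cohen_d"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_subthreshold_clusters_dropped(self, rng):
        idx = np.array([[1, 1, 1]])
        cluster = st.Cluster(indices=idx, sign=1, peak_index=idx[0],
                             peak_stat=5.0, peak_mm=np.zeros(3))
        table = st.cluster_report([cluster], 2, rng.normal(size=(6, 3, 3, 3)),
                                  np.r_[np.ones(3, bool), np.zeros(3, bool)],
                                  np.r_[np.zeros(3, bool), np.ones(3, bool)])
        assert len(table) == 0
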