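import numpy as np
import pytest

from deltaadmix import simdata
from deltaadmix.sexbias import (
    bootstrap_delta_admix,
    build_matched_autosomal_sets,
    delta_admix,
    per_site_and_pooled,
    pooled_autosomal_proportion,
    pooled_x_proportion,
)

from conftest import F_FEMALE, F_MALE


class TestMatchedSets:
    def test_short_whole_chromosome_kept_intact(self, small_cohort):
        _, _, geno, _ = small_cohort
        m = build_matched_autosomal_sets(
            geno, seed=0,
            trim_chroms=(), whole_chroms=("chr7",),
        )
        # chr7 has more SNPs than X here, so it is downsampled to n_X
        assert len(m.subsets["chr7"]) == m.n_x
        n_x = len(geno.chrom_snp_indices("X"))
        assert m.n_x == n_x

    def test_trim_bound_respected(self, small_cohort):
        _, _, geno, _ = small_cohort
        m = build_matched_autosomal_sets(geno, trim_cm=180.0, seed=1)
        cm = geno.snps["cm"].to_numpy()
        for chrom in ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6"):
            idx = geno.chrom_snp_indices(chrom)
            first = cm[idx].min()
            assert (cm[m.subsets[chrom]] <= first + 180.0).all()
            assert len(m.subsets[chrom]) == m.n_x

    def test_deterministic_given_seed(self, small_cohort):
        _, _, geno, _ = small_cohort
        a = build_matched_autosomal_sets(geno, seed=7)
        b = build_matched_autosomal_sets(geno, seed=7)
        for chrom in a.subsets:
            np.testing.assert_array_equal(a.subsets[chrom], b.subsets[chrom])

    def test_too_small_chromosome_named_in_error(self, small_cohort):
        _, _, geno, _ = small_cohort
        # restrict to a slice where chr12 has fewer SNPs than the X
        few_chr12 = np.concatenate(
            [geno.chrom_snp_indices("chr12")[:5], geno.chrom_snp_indices("X")]
        )
        sub = geno.subset(snp_idx=few_chr12)
        with pytest.raises(ValueError, match="chr12"):
            build_matched_autosomal_sets(
                sub, seed=0, trim_chroms=(), whole_chroms=("chr12",)
            )

    def test_missing_cm_positions_rejected(self, small_cohort):
        _, _, geno, _ = small_cohort
        broken = geno.subset()
        broken.snps = broken.snps.assign(cm=0.0)
        with pytest.raises(ValueError, match="cM"):
            build_matched_autosomal_sets(broken, seed=0)


class TestPooledProportions:
    def test_female_double_weighting(self):
        q = np.array([[0.0], [0.3]])
        f_x = pooled_x_proportion(q, ["M", "F"])
        assert f_x[0] == pytest.approx((2 * 0.3 + 1 * 0.0) / 3)

    def test_identical_vectors_are_fixed_point(self):
        q = np.tile([0.25, 0.75], (10, 1))
        np.testing.assert_allclose(
            pooled_x_proportion(q, ["M", "F"] * 5), [0.25, 0.75]
        )

    def test_all_female_is_unweighted_mean(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet([1, 1], size=8)
        np.testing.assert_allclose(
            pooled_x_proportion(q, ["F"] * 8), q.mean(axis=0)
        )

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            pooled_x_proportion(np.array([[1.0]]), ["?"])

    def test_autosomal_pool_is_mean_of_means(self):
        # two subsets, hand mean: individual means then cohort mean
        q = np.array(
            [[[0.6, 0.4], [0.4, 0.6]],
             [[0.2, 0.8], [0.4, 0.6]]]
        )  # (2 ind, 2 subsets, 2 anc)
        expected = np.array([[0.5, 0.5], [0.3, 0.7]]).mean(axis=0)
        np.testing.assert_allclose(pooled_autosomal_proportion(q), expected)

    def test_empty_subset_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_autosomal_proportion(np.empty((3, 0, 2)))


class TestDeltaAdmix:
    def test_balanced_is_zero(self):
        assert delta_admix(0.7, 0.4, 0.4) == 0.0

    def test_hand_arithmetic(self):
        assert delta_admix(0.4, 0.5, 0.4) == pytest.approx(0.4 * 0.1 / 0.9)

    def test_maximal_male_bias_boundary(self):
        assert delta_admix(0.3, 0.0, 0.3) == pytest.approx(-0.3)

    def test_absent_ancestry_returns_zero(self):
        assert delta_admix(0.0, 0.0, 0.0) == 0.0

    def test_bounded_by_total_and_sign_contract(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            ft, fx, fa = rng.random(3)
            d = delta_admix(ft, fx, fa)
            assert -ft - 1e-12 <= d <= ft + 1e-12
            assert np.sign(d) == np.sign(fx - fa) or d == 0
        with pytest.raises(ValueError):
            delta_admix(1.2, 0.5, 0.5)


class TestBootstrap:
    def test_identical_individuals_degenerate_ci(self):
        q_x = np.tile([0.6, 0.4], (10, 1))
        q_auto = np.tile([0.5, 0.5], (10, 1, 1))
        res = bootstrap_delta_admix(q_x, q_auto, ["F"] * 10, n_boot=100, seed=0)
        for r in res:
            assert r.ci_low == pytest.approx(r.delta_admix)
            assert r.ci_high == pytest.approx(r.delta_admix)

    def test_seed_reproducibility(self, truth500):
        panel, cfg, geno, truth = truth500
        q_x = simdata.truth_q(truth, panel.labels, "x")
        q_auto = simdata.truth_q(truth, panel.labels, "auto")[:, None, :]
        sexes = truth["sex"].to_numpy()
        a = bootstrap_delta_admix(q_x, q_auto, sexes, n_boot=200, seed=5)
        b = bootstrap_delta_admix(q_x, q_auto, sexes, n_boot=200, seed=5)
        for ra, rb in zip(a, b):
            assert (ra.ci_low, ra.ci_high) == (rb.ci_low, rb.ci_high)

    def test_sign_recovery_on_biased_cohort(self):
        # f_f=(0.8,0.2), f_m=(0.2,0.8): ancestry 1 female-biased (positive),
        # ancestry 2 male-biased (negative), CIs excluding zero at n=300
        panel = simdata.simulate_panel_frequencies(2, 20, 0.1, seed=41)
        gmap = simdata.simulate_genetic_map(
            [("chr7", 187.0, 10), ("X", 180.0, 10)], seed=42
        )
        cfg = simdata.ContributionConfig(
            "s", 300, np.array([0.8, 0.2]), np.array([0.2, 0.8])
        )
        geno, truth = simdata.simulate_admixed_cohort(panel, gmap, [cfg], seed=43)
        q_x = simdata.truth_q(truth, panel.labels, "x")
        q_auto = simdata.truth_q(truth, panel.labels, "auto")[:, None, :]
        res = bootstrap_delta_admix(
            q_x, q_auto, truth["sex"].to_numpy(), n_boot=1000, seed=44,
            labels=panel.labels,
        )
        assert res[0].delta_admix > 0 and res[0].ci_low > 0
        assert res[1].delta_admix < 0 and res[1].ci_high < 0

    def test_antisymmetry_under_sex_swap(self):
        # swapping f_f and f_m flips the expected sign for every ancestry
        panel = simdata.simulate_panel_frequencies(3, 20, 0.1, seed=45)
        gmap = simdata.simulate_genetic_map(
            [("chr7", 187.0, 10), ("X", 180.0, 10)], seed=46
        )
        deltas = []
        for f_a, f_b in ((F_FEMALE, F_MALE), (F_MALE, F_FEMALE)):
            cfg = simdata.ContributionConfig("s", 800, f_a, f_b)
            _, truth = simdata.simulate_admixed_cohort(panel, gmap, [cfg], seed=47)
            q_x = simdata.truth_q(truth, panel.labels, "x")
            q_auto = simdata.truth_q(truth, panel.labels, "auto")[:, None, :]
            res = bootstrap_delta_admix(
                q_x, q_auto, truth["sex"].to_numpy(), n_boot=10, seed=48,
                labels=panel.labels,
            )
            deltas.append([r.delta_admix for r in res])
        fwd, rev = deltas
        assert np.sign(fwd[0]) == -np.sign(rev[0])
        assert np.sign(fwd[1]) == -np.sign(rev[1])

    def test_nboot_validation(self):
        with pytest.raises(ValueError):
            bootstrap_delta_admix(
                np.ones((2, 1)), np.ones((2, 1, 1)), ["F", "F"], n_boot=0
            )


class TestNullCalibration:
    def test_ci_rejection_rate_near_nominal(self):
        # under f_f = f_m the 95% CI should exclude zero ~5% of the time
        rng = np.random.default_rng(100)
        f = np.array([0.5, 0.5])
        n, rejections, n_cohorts = 150, 0, 200
        for _ in range(n_cohorts):
            q_auto = rng.dirichlet(30 * f, size=n)
            q_x = rng.dirichlet(30 * f, size=n)
            sexes = np.where(rng.random(n) < 0.5, "M", "F")
            res = bootstrap_delta_admix(
                q_x, q_auto[:, None, :], sexes, n_boot=500,
                seed=int(rng.integers(2**31 - 1)),
            )
            rejections += res[0].significant
        rate = rejections / n_cohorts
        assert 0.02 <= rate <= 0.10


class TestPerSiteAndPooled:
    def _inputs(self, n=30, sites=("a", "b"), seed=0):
        rng = np.random.default_rng(seed)
        q_x = rng.dirichlet([3, 3], size=n * len(sites))
        q_auto = rng.dirichlet([3, 3], size=n * len(sites))[:, None, :]
        sexes = np.where(rng.random(n * len(sites)) < 0.5, "M", "F")
        site_labels = np.repeat(list(sites), n)
        return q_x, q_auto, sexes, site_labels

    def test_single_site_pooled_equals_site(self):
        q_x, q_auto, sexes, _ = self._inputs(sites=("only",))
        table = per_site_and_pooled(
            q_x, q_auto, sexes, ["only"] * len(sexes), n_boot=50, seed=1
        )
        one = table[table.site == "only"].set_index("ancestry")
        pooled = table[table.site == "POOLED"].set_index("ancestry")
        for anc in one.index:
            assert one.loc[anc, "delta_admix"] == pytest.approx(
                pooled.loc[anc, "delta_admix"]
            )

    def test_pooled_is_unweighted_mean_of_sites(self):
        q_x, q_auto, sexes, site_labels = self._inputs(sites=("a", "b", "c"))
        table = per_site_and_pooled(
            q_x, q_auto, sexes, site_labels, n_boot=20, seed=2
        )
        for anc in table.ancestry.unique():
            site_vals = table[(table.site != "POOLED") & (table.ancestry == anc)][
                "delta_admix"
            ]
            pooled = table[(table.site == "POOLED") & (table.ancestry == anc)][
                "delta_admix"
            ].iloc[0]
            assert pooled == pytest.approx(site_vals.mean())


class TestMatchedSetStability:
    def test_downsampling_seed_barely_moves_estimate(self):
        # two different downsampling seeds at 5000 X SNPs move the ΔAdmix
        # point estimate by < 0.01
        from deltaadmix.ancestry import estimate_cohort_q, q_matrix
        from deltaadmix.genio import X_CHROM

        panel = simdata.simulate_panel_frequencies(2, 17000, 0.1, seed=51)
        gmap = simdata.simulate_genetic_map(
            [("chr7", 187.0, 6000), ("chr10", 181.0, 6000), ("X", 180.0, 5000)],
            seed=52,
        )
        cfg = simdata.ContributionConfig(
            "s", 40, np.array([0.7, 0.3]), np.array([0.3, 0.7])
        )
        geno, truth = simdata.simulate_admixed_cohort(panel, gmap, [cfg], seed=53)
        x_idx = geno.chrom_snp_indices(X_CHROM)
        _, q_x = q_matrix(estimate_cohort_q(geno, panel, scope=X_CHROM,
                                            snp_idx=x_idx, tol=1e-5))
        sexes = geno.individuals["sex"].to_numpy()
        points = []
        for seed in (1, 2):
            m = build_matched_autosomal_sets(
                geno, seed=seed, trim_chroms=(),
                whole_chroms=("chr7", "chr10"),
            )
            qs = np.stack(
                [
                    q_matrix(estimate_cohort_q(geno, panel, scope=c,
                                               snp_idx=idx, tol=1e-5))[1]
                    for c, idx in m.subsets.items()
                ],
                axis=1,
            )
            f_x = pooled_x_proportion(q_x, sexes)
            f_auto = pooled_autosomal_proportion(qs)
            points.append(delta_admix(f_auto, f_x, f_auto))
        assert np.abs(points[0] - points[1]).max() < 0.01
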