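import itertools

import numpy as np
import pandas as pd
import pytest

from deltaadmix.geo import (
    combine_asian_components,
    fit_cline,
    geographic_distance_matrix,
    haversine_km,
    leave_one_out_clines,
    mantel_test,
    site_mean_ancestry,
)


class TestSiteMeans:
    def test_single_individual_sites_identity(self):
        q = np.array([[0.2, 0.8], [0.7, 0.3]])
        means = site_mean_ancestry(q, ["a", "b"], ["x", "y"])
        np.testing.assert_allclose(means.loc["a", ["x", "y"]], [0.2, 0.8])

    def test_hand_mean(self):
        q = np.array([[0.2, 0.8], [0.4, 0.6], [0.9, 0.1]])
        means = site_mean_ancestry(q, ["a", "a", "b"], ["x", "y"])
        np.testing.assert_allclose(means.loc["a", ["x", "y"]], [0.3, 0.7])

    def test_min_n_drops_small_sites(self):
        q = np.tile([0.5, 0.5], (19, 1))
        sites = ["big"] * 10 + ["small"] * 9
        means = site_mean_ancestry(q, sites, ["x", "y"], min_n=10)
        assert list(means.index) == ["big"]


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(-33.9, 18.4, -33.9, 18.4) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(
            6371 * np.pi / 180, abs=1e-3
        )

    def test_antipodal_half_circumference(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(np.pi * 6371, abs=1e-3)

    def test_against_sklearn(self):
        from sklearn.metrics.pairwise import haversine_distances

        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [rng.uniform(-80, 80, 20), rng.uniform(-179, 179, 20)]
        )
        ours = geographic_distance_matrix(
            pd.DataFrame({"site": range(20), "latitude": pts[:, 0],
                          "longitude": pts[:, 1]})
        )
        theirs = haversine_distances(np.radians(pts)) * 6371
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c = rng.uniform(-85, 85, 3), rng.uniform(-180, 180, 3), None
            p = list(zip(a, b))
            d_ab = haversine_km(*p[0], *p[1])
            d_ba = haversine_km(*p[1], *p[0])
            d_ac = haversine_km(*p[0], *p[2])
            d_cb = haversine_km(*p[2], *p[1])
            assert d_ab == pytest.approx(d_ba, abs=1e-9)
            assert d_ab <= d_ac + d_cb + 1e-9

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            haversine_km(95, 0, 0, 0)


class TestMantel:
    @staticmethod
    def _random_dist(rng, n):
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_self_correlation(self):
        rng = np.random.default_rng(2)
        D = self._random_dist(rng, 6)
        res = mantel_test(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_matches_exhaustive_enumeration_4x4(self):
        rng = np.random.default_rng(3)
        D1 = self._random_dist(rng, 4)
        D2 = self._random_dist(rng, 4)
        res = mantel_test(D1, D2, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(_mantel_exhaustive(D1, D2))
        assert res.n_perm == 23

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        D1 = self._random_dist(rng, 5)
        D2 = self._random_dist(rng, 5)
        r1 = mantel_test(D1, D2, n_perm=9, seed=0).r
        perm = rng.permutation(5)
        r2 = mantel_test(
            D1[np.ix_(perm, perm)], D2[np.ix_(perm, perm)], n_perm=9, seed=0
        ).r
        assert r1 == pytest.approx(r2)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(5)
        D1 = self._random_dist(rng, 8)
        D2 = D1 + 0.3 * self._random_dist(rng, 8)
        np.fill_diagonal(D2, 0.0)
        ours = mantel_test(D1, D2, n_perm=999, seed=1)
        r_ref, p_ref, _ = mantel(
            DistanceMatrix(D1), DistanceMatrix(D2),
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_ref), abs=1e-12)
        assert ours.p_value == pytest.approx(float(p_ref), abs=0.05)

    def test_constant_matrix_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(D, D, n_perm=9)

    def test_null_rejection_rate_calibrated(self):
        # independent random matrices: rejection at alpha=0.05 stays near 5%
        rng = np.random.default_rng(6)
        rejections = 0
        for i in range(200):
            D1 = self._random_dist(rng, 6)
            D2 = self._random_dist(rng, 6)
            res = mantel_test(D1, D2, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.01 <= rejections / 200 <= 0.10


def _mantel_exhaustive(D1, D2):
    """All 24 permutations of a 4x4 matrix (identity counts once in the
    denominator convention (1 + count)/(n_perm + 1) with n_perm = 23)."""
    iu = np.triu_indices(4, 1)
    x = D1[iu]
    r_obs = np.corrcoef(x, D2[iu])[0, 1]
    count = 0
    perms = [p for p in itertools.permutations(range(4))
             if tuple(p) != tuple(range(4))]
    for perm in perms:
        perm = np.array(perm)
        y = D2[np.ix_(perm, perm)][iu]
        count += np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12
    return (1 + count) / (len(perms) + 1)


class TestClineFit:
    def test_collinear_points_r2_one(self):
        x = np.arange(5, dtype=float)
        y = 0.1 * x + 0.2
        fit = fit_cline(y, x, "latitude")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.1)

    def test_constant_ancestry_flat(self):
        fit = fit_cline(np.full(6, 0.4), np.arange(6.0), "longitude")
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-35, -30, 6)
        y = 0.02 * x + rng.normal(0, 0.01, 6) + 0.9
        fit = fit_cline(y, x, "latitude")
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        se = np.sqrt(resid @ resid / 4 / ((x - x.mean()) @ (x - x.mean())))
        from scipy import stats as st

        t = slope / se
        p = 2 * st.t.sf(abs(t), df=4)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fit_cline([0.1, 0.2], [1.0, 2.0], "latitude")

    def test_zero_coordinate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_cline([0.1, 0.2, 0.3], [1.0, 1.0, 1.0], "latitude")


class TestLeaveOneOut:
    @staticmethod
    def _tables(values, lats, names):
        means = pd.DataFrame({"anc": values, "n": 20}, index=pd.Index(names, name="site"))
        st = pd.DataFrame({"site": names, "latitude": lats,
                           "longitude": np.zeros(len(names))})
        return means, st

    def test_single_outlier_site_flagged(self):
        # five sites on a flat line plus one extreme site that alone creates
        # the significant slope: only its removal flips significance
        names = [f"s{i}" for i in range(6)]
        lats = np.array([-34.0, -33.5, -33.0, -32.5, -32.0, -26.0])
        vals = np.array([0.300, 0.302, 0.298, 0.301, 0.299, 0.65])
        means, st = self._tables(vals, lats, names)
        table = leave_one_out_clines(means, st, "anc", "latitude")
        flagged = table[table.flag == "flips"]["dropped_site"].tolist()
        assert flagged == ["s5"]

    def test_duplicated_site_is_redundant(self):
        names = [f"s{i}" for i in range(6)]
        lats = np.array([-34.0, -33.0, -32.0, -31.0, -30.0, -30.0])
        vals = 0.1 * (lats + 34) + 0.2
        vals[-1] = vals[-2]  # exact duplicate of s4
        means, st = self._tables(vals, lats, names)
        table = leave_one_out_clines(means, st, "anc", "latitude")
        row = table[table.dropped_site == "s5"].iloc[0]
        assert row.p_without < 10 * row.p_full + 1e-12
        assert row.flag == "stable"

    def test_three_remaining_sites_flagged_undefined(self):
        names = [f"s{i}" for i in range(4)]
        lats = np.array([-34.0, -33.0, -32.0, -31.0])
        vals = np.array([0.1, 0.3, 0.2, 0.4])
        means, st = self._tables(vals, lats, names)
        table = leave_one_out_clines(means, st, "anc", "latitude")
        assert (table.flag == "undefined").all()

    def test_too_few_sites_rejected(self):
        names = ["a", "b", "c"]
        means, st = self._tables([0.1, 0.2, 0.3], [1.0, 2.0, 3.0], names)
        with pytest.raises(ValueError, match="4"):
            leave_one_out_clines(means, st, "anc", "latitude")


class TestCombineComponents:
    def test_merge_two_columns(self):
        df = pd.DataFrame({"SA": [0.1], "EA": [0.05], "KS": [0.85]})
        out = combine_asian_components(df, ["SA", "EA"])
        assert out["Asian"].iloc[0] == pytest.approx(0.15)
        assert out.drop(columns="Asian").sum(axis=1).iloc[0] + 0.15 == pytest.approx(1.0)

    def test_single_column_identity(self):
        df = pd.DataFrame({"SA": [0.3], "KS": [0.7]})
        out = combine_asian_components(df, ["SA"], merged_label="SA2")
        assert out["SA2"].iloc[0] == pytest.approx(0.3)

    def test_missing_label_rejected(self):
        df = pd.DataFrame({"KS": [1.0]})
        with pytest.raises(ValueError, match="absent"):
            combine_asian_components(df, ["SA"])
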