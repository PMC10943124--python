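import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from handlat.stats import (
    ZERO_VARIANCE_T_SENTINEL,
    cohens_d,
    dice,
    fdr_bh,
    one_sample_t_map,
    roi_group_model,
    two_sample_t_map,
)


class TestTwoSampleT:
    def test_closed_form_example(self):
        res = two_sample_t_map(
            np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]])
        )
        assert res.t[0] == pytest.approx(-3.674, abs=1e-3)
        assert res.df[0] == 4

    def test_identical_groups_near_zero(self, rng):
        base = rng.standard_normal((100, 20))
        shift = rng.standard_normal((100, 20)) * 0.01
        res = two_sample_t_map(base, base + shift)
        assert np.all(np.abs(res.t) < 4)
        assert np.abs(res.t).mean() < 1.5

    def test_permutation_invariance(self, rng):
        A = rng.standard_normal((10, 5))
        B = rng.standard_normal((12, 5))
        r1 = two_sample_t_map(A, B)
        perm = rng.permutation(10)
        r2 = two_sample_t_map(A[perm], B)
        # identical up to float summation order
        assert np.allclose(r1.t, r2.t, atol=1e-12, rtol=0)

    def test_matches_scipy_on_fixture(self, rng):
        """Dual-route check on every vertex of a 50-vertex fixture."""
        A = rng.standard_normal((14, 50)) + 0.3
        B = rng.standard_normal((11, 50))
        res = two_sample_t_map(A, B)
        ref = sps.ttest_ind(A, B, axis=0)
        assert np.max(np.abs(res.t - ref.statistic)) < 1e-10
        assert np.max(np.abs(res.p - ref.pvalue)) < 1e-10

    def test_welch_matches_scipy(self, rng):
        A = rng.standard_normal((14, 20)) * 3
        B = rng.standard_normal((25, 20))
        res = two_sample_t_map(A, B, welch=True)
        ref = sps.ttest_ind(A, B, axis=0, equal_var=False)
        assert np.max(np.abs(res.t - ref.statistic)) < 1e-10

    def test_nan_subjects_adjust_df(self, rng):
        A = rng.standard_normal((6, 3))
        A[0, 1] = np.nan
        B = rng.standard_normal((5, 3))
        res = two_sample_t_map(A, B)
        assert res.df[0] == 9
        assert res.df[1] == 8

    def test_zero_variance_both_groups_nan(self):
        A = np.ones((3, 2))
        B = np.ones((3, 2)) * 2
        A[:, 1] = [1.0, 2.0, 3.0]
        B[:, 1] = [1.5, 2.5, 3.5]
        res = two_sample_t_map(A, B)
        assert np.isnan(res.t[0])
        assert np.isfinite(res.t[1])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            two_sample_t_map(np.ones((1, 3)), np.ones((4, 3)))


class TestOneSampleT:
    def test_all_zero_values(self):
        res = one_sample_t_map(np.zeros((4, 3)))
        assert np.allclose(res.t, 0)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = one_sample_t_map(np.ones((3, 1)))
        assert res.t[0] == ZERO_VARIANCE_T_SENTINEL

    def test_mean_zero(self):
        res = one_sample_t_map(np.array([[-1.0], [0.0], [1.0]]))
        assert res.t[0] == pytest.approx(0.0)
        assert res.p[0] == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        Y = rng.standard_normal((12, 30)) + 0.4
        res = one_sample_t_map(Y)
        ref = sps.ttest_1samp(Y, 0.0, axis=0)
        assert np.max(np.abs(res.t - ref.statistic)) < 1e-10
        assert np.max(np.abs(res.p - ref.pvalue)) < 1e-10


class TestFdr:
    def test_spec_example_all_rejected(self):
        mask, q = fdr_bh(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert mask.all()

    def test_none_rejected(self):
        mask, _ = fdr_bh(np.array([0.5, 0.6]), alpha=0.05)
        assert not mask.any()

    def test_single_small_p(self):
        mask, q = fdr_bh(np.array([0.001]), alpha=0.05)
        assert mask[0]
        assert q[0] == pytest.approx(0.001)

    def test_empty_input(self):
        mask, q = fdr_bh(np.array([]), alpha=0.05)
        assert mask.size == 0 and q.size == 0

    def test_nan_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02, 0.04])
        mask, q = fdr_bh(p, alpha=0.05)
        assert not mask[1] and np.isnan(q[1])
        assert mask[[0, 2, 3]].all()  # same as the m = 3 example

    def test_mask_never_more_liberal_than_alpha(self, rng):
        p = rng.random(500)
        mask, _ = fdr_bh(p, alpha=0.05)
        assert np.all(p[mask] <= 0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels(self, seed):
        """Dual-route check against the reference implementation."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.random(200), rng.random(20) * 1e-3])
        mask, q = fdr_bh(p, alpha=0.05)
        ref_mask, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(mask, ref_mask)
        assert np.allclose(q, ref_q)

    @pytest.mark.parametrize("seed", range(3))
    def test_by_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(100)
        mask, q = fdr_bh(p, alpha=0.05, method="by")
        ref_mask, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_by")
        assert np.array_equal(mask, ref_mask)
        assert np.allclose(q, ref_q)

    def test_q_monotone_in_sorted_p(self, rng):
        p = rng.random(100)
        _, q = fdr_bh(p, alpha=0.05)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestCohensD:
    def test_equal_means_zero(self, rng):
        a = rng.standard_normal(50)
        assert cohens_d(a, a) == 0.0

    def test_unit_gap_unit_sd(self, rng):
        a = rng.standard_normal(100000)
        d = cohens_d(a + 1.0, a)
        assert d == pytest.approx(1.0, abs=0.02)

    def test_hand_computation(self):
        # {0,1} vs {1,2}: pooled unbiased variance 0.5 -> d = -1/sqrt(0.5)
        d = cohens_d([0.0, 1.0], [1.0, 2.0])
        assert d == pytest.approx(-np.sqrt(2.0))


class TestDice:
    def test_identical_masks(self):
        m = np.array([True, False, True])
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        assert dice(np.array([True, False]), np.array([False, True])) == 0.0

    def test_partial_overlap(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True
        b[2:6] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros(5, bool), np.zeros(6, bool))


def make_cohort(rng, n_per_group, groups=("A", "B")):
    rows = []
    for g in groups:
        for _ in range(n_per_group):
            rows.append(
                {
                    "group": g,
                    "fd": rng.random(),
                    "age": float(rng.integers(100, 140)),
                    "sex": str(rng.choice(["F", "M"])),
                }
            )
    return pd.DataFrame(rows)


class TestRoiGroupModel:
    def test_reduces_to_two_sample_t(self, rng):
        cohort = make_cohort(rng, 12)
        cohort["fd"] = 0.5  # constant -> dropped
        cohort["age"] = 120.0
        cohort["sex"] = "F"
        y = rng.standard_normal(24) + np.repeat([0.0, 1.0], 12)
        model = roi_group_model(y, cohort, ["fd", "age", "sex"])
        ref = sps.ttest_ind(y[:12], y[12:])
        row = model["pairwise"].iloc[0]
        assert row["contrast"] == "A-B"
        assert row["t"] == pytest.approx(ref.statistic, abs=1e-10)
        assert row["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_duplicate_covariate_rank_error(self, rng):
        cohort = make_cohort(rng, 10)
        cohort["fd2"] = cohort["fd"]
        with pytest.raises(ValueError, match="collinear"):
            roi_group_model(rng.standard_normal(20), cohort, ["fd", "fd2"])

    def test_three_group_pairwise_contrasts(self, rng):
        cohort = make_cohort(rng, 8, groups=("A", "B", "C"))
        y = rng.standard_normal(24)
        model = roi_group_model(y, cohort, ["fd", "age", "sex"])
        assert set(model["pairwise"]["contrast"]) == {"A-B", "A-C", "B-C"}
        assert model["df_num"] == 2

    def test_null_calibration(self):
        """Under a true null the group test rejects at ~alpha."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            cohort = make_cohort(rng, 100)
            y = rng.standard_normal(200) + 0.3 * cohort["fd"].to_numpy()
            model = roi_group_model(y, cohort, ["fd", "age", "sex"])
            if model["group_p"] < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert 0.01 <= rate <= 0.10

    def test_covariate_adjustment_changes_estimate(self, rng):
        cohort = make_cohort(rng, 50)
        # outcome driven purely by fd, which differs by group
        cohort.loc[cohort["group"] == "B", "fd"] += 1.0
        y = 2.0 * cohort["fd"].to_numpy() + 0.1 * rng.standard_normal(100)
        adj = roi_group_model(y, cohort, ["fd"])
        raw = roi_group_model(y, cohort, [])
        assert abs(adj["pairwise"].iloc[0]["t"]) < abs(raw["pairwise"].iloc[0]["t"])


def test_bh_controls_fdr_on_null_quick():
    """Small-scale FDR control check (full-scale run in acceptance tests)."""
    rng = np.random.default_rng(5)
    fdrs = []
    for _ in range(30):
        p = rng.random(2000)
        mask, _ = fdr_bh(p, alpha=0.05)
        fdrs.append(1.0 if mask.any() else 0.0)
    assert np.mean(fdrs) <= 0.07 + 0.05
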