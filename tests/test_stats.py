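"""Permutation inference, effect sizes, ANOVA, correlation and ICC."""

import numpy as np
import pytest
from scipy import stats as sps

from facedim.dimorphism import FeatureMatrix
from facedim.stats import (
    anova_oneway,
    cohens_d,
    icc_3k,
    pearson_r,
    permutation_distance_test,
)


def matrix(f_rows, m_rows):
    rows = np.asarray(list(f_rows) + list(m_rows), dtype=float)
    n_f = len(f_rows)
    return FeatureMatrix(
        specimen_ids=[f"s{i}" for i in range(len(rows))],
        sex_labels=["F"] * n_f + ["M"] * (len(rows) - n_f),
        variables=[f"v{j}" for j in range(rows.shape[1])],
        values=rows,
    )


class TestPermutationDistanceTest:
    def test_point_masses_minimal_p(self):
        # 8 F at origin, 8 M at (1,0): only a shuffle reproducing the exact
        # partition ties the observed distance; with 99 draws and this seed
        # none does, so the add-one p is exactly 1/100
        X = matrix([(0.0, 0.0)] * 8, [(1.0, 0.0)] * 8)
        res = permutation_distance_test(X, n_perm=99, seed=5)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.observed_distance == pytest.approx(1.0)

    def test_determinism_same_seed(self, rng):
        X = matrix(rng.normal(size=(10, 4)), rng.normal(size=(10, 4)) + 0.3)
        r1 = permutation_distance_test(X, n_perm=500, seed=42)
        r2 = permutation_distance_test(X, n_perm=500, seed=42)
        assert (r1.p_value, r1.cohens_d) == (r2.p_value, r2.cohens_d)
        r3 = permutation_distance_test(X, n_perm=500, seed=43)
        assert r3.p_value != r1.p_value or r3.observed_distance == r1.observed_distance

    def test_add_one_p_never_zero_never_above_one(self, rng):
        X = matrix(rng.normal(size=(6, 2)), rng.normal(size=(6, 2)) + 5)
        res = permutation_distance_test(X, n_perm=49, seed=0)
        assert 0 < res.p_value <= 1

    def test_type_one_error_calibrated(self):
        # under exchangeable labels P(p <= alpha) ~= alpha; modest-size
        # simulation here, the full-size calibration runs in the
        # acceptance suite
        alpha = 0.05
        reps, n_perm = 150, 99
        ss = np.random.SeedSequence(777)
        rejections = 0
        for child in ss.spawn(reps):
            r = np.random.default_rng(child)
            X = matrix(r.normal(size=(10, 3)), r.normal(size=(10, 3)))
            res = permutation_distance_test(
                X, n_perm=n_perm, seed=int(child.generate_state(1)[0] % 2**31)
            )
            rejections += res.p_value <= alpha
        rate = rejections / reps
        p0 = np.floor(alpha * (n_perm + 1)) / (n_perm + 1)
        half = 2.6 * np.sqrt(p0 * (1 - p0) / reps)  # generous band
        assert abs(rate - p0) <= half

    def test_single_sex_errors(self):
        X = FeatureMatrix(
            specimen_ids=["a", "b", "c", "d"],
            sex_labels=["F"] * 4,
            variables=["v"],
            values=np.arange(4.0)[:, None],
        )
        with pytest.raises(ValueError):
            permutation_distance_test(X, n_perm=9, seed=0)


class TestCohensD:
    def test_hand_arithmetic(self):
        # M={2,4}, F={0,2}: mean diff 2, pooled SD sqrt(2) -> d = sqrt(2)
        d = cohens_d([0, 2, 2, 4], ["F", "F", "M", "M"])
        assert d == pytest.approx(np.sqrt(2))

    def test_equal_means_zero(self):
        assert cohens_d([1, 3, 1, 3], ["F", "F", "M", "M"]) == 0.0

    def test_degenerate_zero_pooled_sd(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([0, 0, 1, 1], ["F", "F", "M", "M"])

    def test_affine_invariance(self, rng):
        vals = rng.normal(size=20)
        labels = ["F"] * 10 + ["M"] * 10
        d = cohens_d(vals, labels)
        assert cohens_d(3.7 * vals - 11, labels) == pytest.approx(d)

    def test_orientation_male_minus_female(self):
        assert cohens_d([0, 0.5, 10, 10.5], ["F", "F", "M", "M"]) > 0


class TestAnovaOneway:
    def test_identical_groups(self):
        res = anova_oneway([1, 2, 3, 1, 2, 3], ["F"] * 3 + ["M"] * 3)
        assert res.F == pytest.approx(0.0)
        assert res.R2 == pytest.approx(0.0)

    def test_textbook_case(self):
        # M={1,2,3}, F={3,4,5}: SSB=6, SSW=4, F = 6/(4/4) = 6, R2 = 0.6
        res = anova_oneway([3, 4, 5, 1, 2, 3], ["F"] * 3 + ["M"] * 3)
        assert res.F == pytest.approx(6.0, abs=1e-9)
        assert res.R2 == pytest.approx(0.6, abs=1e-9)
        assert (res.df1, res.df2) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(6.0, 1, 4), abs=1e-12)

    def test_equals_squared_pooled_t(self, rng):
        vals = rng.normal(size=16)
        labels = ["F"] * 7 + ["M"] * 9
        res = anova_oneway(vals, labels)
        t = sps.ttest_ind(vals[7:], vals[:7], equal_var=True).statistic
        assert res.F == pytest.approx(t**2, abs=1e-9)

    def test_f_relates_to_d(self, rng):
        vals = rng.normal(size=14)
        labels = ["F"] * 6 + ["M"] * 8
        res = anova_oneway(vals, labels)
        n1, n2 = 6, 8
        assert res.F == pytest.approx(
            res.cohens_d**2 * n1 * n2 / (n1 + n2), abs=1e-9
        )

    def test_zero_total_ss_raises(self):
        with pytest.raises(ValueError, match="total"):
            anova_oneway([2, 2, 2, 2], ["F", "F", "M", "M"])


class TestPearson:
    def test_perfect_positive(self):
        x = [1, 2, 3, 4, 5]
        r, p = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 4.0, 8.0]
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_five_point_reference(self):
        # manual computation: r = cov(x,y)/(sx*sy); p from t with n-2 df
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 9.0])
        rm = float(np.corrcoef(x, y)[0, 1])
        t = rm * np.sqrt(3 / (1 - rm**2))
        pm = 2 * sps.t.sf(abs(t), 3)
        r, p = pearson_r(x, y)
        assert r == pytest.approx(rm, abs=1e-12)
        assert p == pytest.approx(pm, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestIcc3k:
    def test_identical_raters_give_one(self):
        R = np.tile(np.array([[1.0], [4.0], [6.0], [2.0]]), (1, 5))
        assert icc_3k(R).icc_3k == pytest.approx(1.0)

    def test_printed_fixture_against_hand_two_way_anova(self):
        # 4 stimuli x 3 raters; two-way mean squares computed by hand:
        # BMS = 17/3, EMS = 2/3 -> ICC(3,k) = (BMS-EMS)/BMS = 15/17
        R = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2]], dtype=float)
        res = icc_3k(R)
        assert res.icc_3k == pytest.approx(15 / 17, abs=1e-9)
        assert (res.n, res.k) == (4, 3)

    def test_matches_pingouin_consistency_average(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        R = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame(
            {
                "stim": np.repeat(np.arange(12), 5),
                "rater": np.tile(np.arange(5), 12),
                "y": R.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="stim", raters="rater", ratings="y")
        row = ref[ref.Type.isin(["ICC3k", "ICC(C,k)"])]
        expected = float(row["ICC"].iloc[0])
        assert icc_3k(R).icc_3k == pytest.approx(expected, abs=1e-9)

    def test_variance_components_oracle(self):
        # stimulus effect sd 1, residual sd 0.5, k=10:
        # expected ICC(3,k) = 1 / (1 + 0.25/10) = 0.97561
        rng = np.random.default_rng(99)
        n, k = 400, 10
        R = rng.normal(size=(n, 1)) + rng.normal(0, 0.5, size=(n, k))
        expected = 1 / (1 + 0.25 / k)
        assert icc_3k(R).icc_3k == pytest.approx(expected, abs=0.01)

    def test_invariant_to_per_rater_shifts(self, rng):
        R = rng.normal(size=(8, 4)) + rng.normal(size=(8, 1))
        shifted = R + np.array([10.0, -3.0, 0.5, 100.0])
        assert icc_3k(shifted).icc_3k == pytest.approx(icc_3k(R).icc_3k, abs=1e-12)

    def test_missing_cells_instruct_subsetting(self):
        R = np.ones((4, 3))
        R[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_3k(R)
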