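"""Cohort statistics: exact-test enumeration oracles, closed-form checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

import neopcg as n
from neopcg import (
    CohortTable,
    linear_regression,
    mann_whitney_exact,
    paired_t,
    run_cohort_analysis,
    spearman,
)
import pandas as pd


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every labeling."""
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    obs_dev = abs(u_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        u, p = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_complete_separation_9v9(self):
        u, p = mann_whitney_exact(list(range(10, 19)), list(range(9)))
        assert u == 81
        assert p == pytest.approx(2 / 48620, rel=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (3, 6), (5, 5), (6, 6)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        for trial in range(5):
            a = rng.integers(0, 8, n1).astype(float)  # integers force ties
            b = rng.integers(0, 8, n2).astype(float)
            _, p = mann_whitney_exact(a, b)
            assert p == pytest.approx(brute_force_mw_p(a, b), rel=1e-10)

    def test_large_sample_approximation_reasonable(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        _, p = mann_whitney_exact(a, b)
        ref = ss.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        rho, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == -1.0

    def test_rank_formula_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_exact_p_is_permutation_fraction(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p = spearman(x, y)
        # oracle: enumerate all 120 permutations
        rx = ss.rankdata(x); ry = ss.rankdata(y)
        vals = []
        for perm in itertools.permutations(range(5)):
            vals.append(abs(np.corrcoef(rx, ry[list(perm)])[0, 1]))
        expect = np.mean(np.array(vals) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expect, rel=1e-12)

    def test_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=18)
        y = x + rng.normal(size=18)
        rho, p = spearman(x, y)
        ref = ss.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_invariance_under_monotone_transform(self, seed):
        g = np.random.default_rng(seed)
        x = g.normal(size=10)
        y = g.normal(size=10)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRegression:
    def test_identity_line(self):
        slope, intercept = linear_regression([1, 2, 3], [1, 2, 3])
        assert (slope, intercept) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_exact_affine(self):
        x = np.array([0.0, 1.5, 3.0, 4.0])
        slope, intercept = linear_regression(x, 2 * x + 3)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            linear_regression([2, 2, 2], [1, 2, 3])

    def test_attenuated_sensor_gives_slope_below_one(self, rng):
        """Paired SNRs where the PS murmur is attenuated 0.8x relative to
        the stethoscope regress with slope < 1 in nearly all cohorts."""
        below = 0
        for _ in range(100):
            ratio = rng.uniform(2, 18, 9)
            steth = np.concatenate([20 * np.log10(ratio), np.zeros(9)])
            ps = np.concatenate([20 * np.log10(0.8 * ratio), np.zeros(9)])
            steth = steth + rng.normal(0, 1, 18)
            ps = ps + rng.normal(0, 1, 18)
            slope, _ = linear_regression(steth, ps)
            below += slope < 1.0
        assert below >= 95


class TestPairedT:
    def test_identical_pairs(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # zero variance

    def test_constant_shift_errors(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0], [1.0, 2.0])

    def test_near_identical_pairs_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([0.01, -0.01, 0.01, -0.01])
        t, p = paired_t(x, x + d)
        assert t == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula_and_scipy(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(0.5, 1, 12)
        t, p = paired_t(x, y)
        d = x - y
        t_direct = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(t_direct, rel=1e-12)
        ref = ss.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestCohortAnalysis:
    @staticmethod
    def _table(rng, n=9, with_vitals=False):
        ratio = rng.uniform(2, 18, n)
        rows = []
        for i in range(n):
            rows.append({"subject_id": f"chd{i}", "group": "CHD",
                         "snr_sys_steth": 20 * np.log10(ratio[i]) + rng.normal(0, 1),
                         "snr_sys_ps": 20 * np.log10(0.8 * ratio[i]) + rng.normal(0, 1)})
        for i in range(n):
            rows.append({"subject_id": f"ctl{i}", "group": "control",
                         "snr_sys_steth": rng.normal(0, 1),
                         "snr_sys_ps": rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        if with_vitals:
            df["hr_supine"] = rng.normal(138.7, 11.4, 2 * n)
            df["hr_prone"] = rng.normal(137.9, 12.6, 2 * n)
        return CohortTable(df)

    def test_separated_cohort_is_significant(self, rng):
        report = run_cohort_analysis(self._table(rng))
        assert report.mann_whitney[1] < 0.01
        assert report.group_difference_significant
        assert -1 <= report.spearman[0] <= 1
        assert 0 < report.spearman[1] <= 1

    def test_vitals_trigger_paired_tests(self, rng):
        report = run_cohort_analysis(self._table(rng, with_vitals=True))
        assert len(report.paired_tests) == 1
        assert report.paired_tests[0][0] == "hr"

    def test_single_group_errors(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "group": ["CHD", "CHD"],
                           "snr_sys_ps": [1.0, 2.0], "snr_sys_steth": [1.0, 2.0]})
        with pytest.raises(ValueError):
            run_cohort_analysis(CohortTable(df))

    def test_report_deterministic(self, rng):
        t = self._table(rng)
        r1 = run_cohort_analysis(t)
        r2 = run_cohort_analysis(t)
        assert r1.to_dict() == r2.to_dict()

    def test_duplicate_subjects_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "group": ["CHD", "control"],
                           "snr_sys_ps": [1.0, 2.0], "snr_sys_steth": [1.0, 2.0]})
        with pytest.raises(ValueError):
            CohortTable(df)
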