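"""Effect sizes, Bonferroni control, the comparison battery and ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tractometry.phantom import CohortSpec, simulate_cohort
from tractometry.stats import (
    bonferroni_threshold,
    cohens_d,
    effect_bin,
    family_size,
    group_compare,
    relative_difference,
    run_full_comparison,
    volume_vs_tbv_regression,
)


class TestBonferroni:
    def test_printed_threshold_for_772_comparisons(self):
        thr = bonferroni_threshold(0.05, 772)
        assert f"{thr:.5g}" == "6.4767e-05"

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.01, 10, 0.001)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestCohensD:
    def test_published_genu_value(self):
        assert cohens_d(2.06, 0.27, 490, 2.21, 0.27, 575) == pytest.approx(-0.56, abs=0.005)

    def test_published_tbv_value(self):
        assert cohens_d(1290, 102, 490, 1128, 90, 575) == pytest.approx(1.7, abs=0.05)

    def test_equal_means_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_antisymmetry(self):
        a = cohens_d(3.1, 0.4, 21, 2.7, 0.6, 34)
        b = cohens_d(2.7, 0.6, 34, 3.1, 0.4, 21)
        assert a == pytest.approx(-b, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            cohens_d(1, 0.0, 10, 1, 1, 10)
        with pytest.raises(ValueError):
            cohens_d(1, 1, 1, 1, 1, 10)


class TestEffectBin:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.0, "negligible"), (0.19, "negligible"),
            (0.2, "small"), (-0.49, "small"),
            (0.5, "medium"), (-0.56, "medium"), (0.79, "medium"),
            (0.8, "large"), (1.7, "large"), (-2.0, "large"),
        ],
    )
    def test_bins_with_upward_boundaries(self, d, expected):
        assert effect_bin(d) == expected

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-5, 5))
    def test_sign_invariance(self, d):
        assert effect_bin(d) == effect_bin(-d)


class TestRelativeDifference:
    def test_published_tbv(self):
        assert relative_difference(1290, 1128) == pytest.approx(12.6, abs=0.05)

    def test_published_genu(self):
        assert relative_difference(2.06, 2.21) == pytest.approx(-7.3, abs=0.05)

    def test_equal_means_zero(self):
        assert relative_difference(4.2, 4.2) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            relative_difference(0.0, 1.0)


class TestGroupCompare:
    def test_identical_samples_null_result(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        r = group_compare(v, v.copy())
        assert r.t_stat == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.cohens_d == 0.0
        assert not r.significant

    def test_t_from_raw_equals_t_from_summaries(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 55)
        r = group_compare(a, b)
        t2, p2 = sps.ttest_ind_from_stats(
            a.mean(), a.std(ddof=1), 40, b.mean(), b.std(ddof=1), 55, equal_var=True
        )
        assert r.t_stat == pytest.approx(t2, abs=1e-10)
        assert r.p_value == pytest.approx(p2, abs=1e-10)

    def test_genu_parameters_power_at_family_threshold(self):
        """Cohorts at the genu summaries reject at 6.4767e-5 in >=95/100 runs."""
        thr = bonferroni_threshold(0.05, 772)
        hits = 0
        for seed in range(100):
            df = simulate_cohort(
                CohortSpec(490, 575, {"g": (2.06, 0.27, 2.21, 0.27)}, rng_seed=seed)
            )
            r = group_compare(
                df.loc[df.sex == "M", "g"].to_numpy(),
                df.loc[df.sex == "F", "g"].to_numpy(),
                bonferroni_alpha=thr,
            )
            hits += r.significant
        assert hits >= 95

    def test_qc_columns_recorded_but_not_gating(self):
        rng = np.random.default_rng(1)
        # heteroscedastic + skewed: Levene/Shapiro should flag, t still reported
        a = np.exp(rng.normal(0, 1, 50))
        b = rng.normal(1.5, 0.1, 50)
        r = group_compare(a, b)
        assert np.isfinite(r.shapiro_p_m) and np.isfinite(r.levene_p)
        assert np.isfinite(r.t_stat) and np.isfinite(r.p_value)

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="at least 3"):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


def _synthetic_cohort(n_tracts=3, n_m=12, n_f=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_m + n_f):
        sex = "M" if i < n_m else "F"
        tbv = rng.normal(1200 if sex == "M" else 1100, 80)
        for t in range(n_tracts):
            row = {
                "subject_id": f"s{i:03d}", "sex": sex, "tract": f"tract_{t}",
                "tbv_cm3": tbv, "wmv_cm3": tbv * 0.38,
                "vol_pct_tbv": rng.normal(2.0, 0.3), "vol_pct_wmv": rng.normal(5.0, 0.8),
            }
            for m in ("fa", "md", "ad", "rd", "gfa", "ndi", "iwvf", "odi"):
                row[m] = rng.uniform(0.2, 0.8)
            rows.append(row)
    return pd.DataFrame(rows)


class TestRunFullComparison:
    def test_family_size_arithmetic(self):
        assert family_size(77) == 772
        assert family_size(3) == 32

    def test_three_tract_cohort_has_32_rows(self):
        res = run_full_comparison(_synthetic_cohort())
        assert len(res) == 32
        assert res.attrs["family_size"] == 32
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 32)

    def test_row_order_invariance(self):
        df = _synthetic_cohort(seed=3)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = run_full_comparison(df)
        b = run_full_comparison(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_single_sex_rejected(self):
        df = _synthetic_cohort()
        with pytest.raises(ValueError, match="both sexes"):
            run_full_comparison(df[df.sex == "M"])

    def test_null_cohort_family_wise_error_rate(self):
        """Bonferroni holds the FWER at alpha over 200 null cohorts."""
        n_reps, n, n_meas = 200, 20, 32
        thr = bonferroni_threshold(0.05, n_meas)
        rng = np.random.default_rng(42)
        fw_errors = 0
        for _ in range(n_reps):
            a = rng.standard_normal((n_meas, n))
            b = rng.standard_normal((n_meas, n))
            _, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
            fw_errors += np.any(p < thr)
        # binomial 99% upper bound at p=0.05, n=200
        assert fw_errors <= 17

    def test_effect_size_recovery_within_sampling_error(self):
        """Generated d comes back within ~2 SE of the target."""
        target = 0.5
        n = 200
        se = np.sqrt(2 / n + target**2 / (4 * n))
        for seed in range(5):
            df = simulate_cohort(
                CohortSpec(n, n, {"x": (target, 1.0, 0.0, 1.0)}, rng_seed=seed)
            )
            vm, vf = df.loc[df.sex == "M", "x"], df.loc[df.sex == "F", "x"]
            d = cohens_d(vm.mean(), vm.std(ddof=1), n, vf.mean(), vf.std(ddof=1), n)
            assert abs(d - target) < 2.5 * se


class TestRegressionAncova:
    @staticmethod
    def _cohort_with_slopes(slope_m, slope_f, seed, n=30, noise=0.15):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(2 * n):
            sex = "M" if i < n else "F"
            tbv = rng.normal(1200, 100)
            slope = slope_m if sex == "M" else slope_f
            vol = 1.0 + slope * (tbv - 1200) + rng.normal(0, noise)
            rows.append(
                {"subject_id": f"s{i}", "sex": sex, "tract": "t", "tbv_cm3": tbv,
                 "vol_pct_tbv": vol}
            )
        return pd.DataFrame(rows)

    def test_exact_linear_data_r2_one(self):
        df = self._cohort_with_slopes(2e-3, -1e-3, seed=0, noise=0.0)
        r = volume_vs_tbv_regression(df, "t")
        assert r.r2_m == pytest.approx(1.0, abs=1e-10)
        assert r.r2_f == pytest.approx(1.0, abs=1e-10)
        assert r.slope_m == pytest.approx(2e-3, rel=1e-8)
        assert r.slope_f == pytest.approx(-1e-3, rel=1e-8)
        assert r.interaction_p < 1e-10

    def test_interaction_type_i_error_calibrated(self):
        """Equal generating slopes: ~5% false interaction detections."""
        hits = sum(
            volume_vs_tbv_regression(
                self._cohort_with_slopes(1e-3, 1e-3, seed=s), "t"
            ).interaction_p < 0.05
            for s in range(400)
        )
        assert 0.02 <= hits / 400 <= 0.08

    def test_interaction_power_at_three_se(self):
        """Slope difference of 3 SE is detected in >=80% of replicates."""
        n, noise = 30, 0.15
        rng = np.random.default_rng(0)
        tbv = rng.normal(1200, 100, n)
        sxx = np.sum((tbv - tbv.mean()) ** 2)
        se_diff = noise * np.sqrt(2 / sxx)  # approx SE of the slope difference
        hits = sum(
            volume_vs_tbv_regression(
                self._cohort_with_slopes(1e-3 + 3 * se_diff, 1e-3, seed=s, n=n, noise=noise),
                "t",
            ).interaction_p < 0.05
            for s in range(400)
        )
        assert hits / 400 >= 0.8

    def test_needs_three_per_sex(self):
        df = self._cohort_with_slopes(1e-3, 1e-3, seed=0, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            volume_vs_tbv_regression(df, "t")
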