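"""Test-retest statistics: estimators, decision tree, comparisons."""

import numpy as np
import pytest
from scipy import stats

from quo2.reprostats import (
    PairedSample,
    bland_altman,
    bs_cv,
    compare_rois,
    compute_repro_metrics,
    difference_stats,
    paired_t,
    repeatability_coefficient,
    repro_table,
    transform_decision,
    ws_cv,
)


def _sample(a, b):
    return PairedSample([f"s{i}" for i in range(len(a))], np.asarray(a), np.asarray(b))


class TestDifferenceStats:
    def test_identical_tests_give_zero(self):
        dsd, wssd = difference_stats(_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert dsd == 0.0 and wssd == 0.0

    def test_hand_computed_diffs(self):
        s = _sample([0.0, 0.0, 0.0], [-1.0, 0.0, 1.0])
        dsd, wssd = difference_stats(s)
        assert dsd == pytest.approx(1.0)
        assert wssd == pytest.approx(0.7071, abs=1e-4)

    def test_shift_invariance(self):
        a = np.array([3.0, 5.0, 9.0, 4.0])
        b = np.array([4.0, 4.5, 10.0, 3.0])
        assert difference_stats(_sample(a, b))[0] == pytest.approx(
            difference_stats(_sample(a + 7, b + 7))[0]
        )

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            _sample([1.0, 2.0], [1.0, 2.0])


class TestWsCv:
    def test_identical_tests_zero(self):
        assert ws_cv(_sample([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])) == 0.0

    def test_single_subject_hand_value(self):
        """A=90, B=110: wsSD = 14.142, subject mean = 100, wsCV = 14.14%."""
        s = _sample([90.0, 100.0, 100.0], [110.0, 100.0, 100.0])
        expected = 100.0 * np.sqrt(((20 / np.sqrt(2)) / 100.0) ** 2 / 3)
        assert ws_cv(s) == pytest.approx(expected, rel=1e-12)
        one = np.abs(110 - 90) / np.sqrt(2) / 100.0
        assert expected == pytest.approx(100.0 * one / np.sqrt(3), rel=1e-12)

    def test_log_scale_zero_wssd_gives_zero(self):
        s = _sample([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert ws_cv(s, "log10") == 0.0

    def test_estimator_recovers_injected_cv(self, rng):
        """True within-subject CV of 10% at n = 1000 subjects is recovered
        within half a point."""
        n = 1000
        true = rng.uniform(80.0, 120.0, n)
        a = true * (1.0 + rng.normal(0.0, 0.10, n))
        b = true * (1.0 + rng.normal(0.0, 0.10, n))
        est = ws_cv(_sample(a, b))
        assert est == pytest.approx(10.0, abs=0.5)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            ws_cv(_sample([1.0, -1.0, 2.0], [-1.0, 1.0, 2.0]))


class TestRepeatability:
    def test_scaling(self):
        assert repeatability_coefficient(0.0) == 0.0
        assert repeatability_coefficient(6.63) == pytest.approx(13.0, abs=0.05)

    def test_coverage_of_repeated_differences(self, rng):
        """~95% of repeated normal differences fall within +/- CR."""
        diffs = rng.normal(0.0, 2.0, 10000)
        cr = repeatability_coefficient(np.std(diffs, ddof=1))
        frac = np.mean(np.abs(diffs - diffs.mean()) <= cr)
        assert frac == pytest.approx(0.95, abs=0.01)


class TestBsCv:
    def test_constant_zero(self):
        assert bs_cv(np.full(6, 3.0)) == 0.0

    def test_hand_value(self):
        assert bs_cv(np.array([8.0, 12.0])) == pytest.approx(28.28, abs=0.01)

    def test_scale_invariance(self):
        x = np.array([4.0, 7.0, 9.0, 12.0])
        assert bs_cv(3.5 * x) == pytest.approx(bs_cv(x), rel=1e-12)


class TestTransformDecision:
    def test_homoscedastic_normal_stays_original(self, rng):
        """Gaussian differences independent of the mean pass on the original
        scale in roughly 1 - 2*alpha of replicates."""
        keep = 0
        reps = 200
        for _ in range(reps):
            true = rng.uniform(90, 110, 8)
            a = true + rng.normal(0, 2.0, 8)
            b = true + rng.normal(0, 2.0, 8)
            scale, _, _ = transform_decision(_sample(a, b))
            keep += scale == "original"
        assert keep / reps > 0.8

    def test_multiplicative_error_triggers_log(self, rng):
        """SD proportional to the mean sends >= 90% of replicates to the
        log10 scale at n = 7."""
        chose_log = 0
        reps = 300
        for _ in range(reps):
            true = 10 ** rng.uniform(0.0, 4.0, 7)
            a = true * np.exp(rng.normal(0, 0.6, 7))
            b = true * np.exp(rng.normal(0, 0.6, 7))
            scale, _, _ = transform_decision(_sample(a, b))
            chose_log += scale in ("log10", "log10_failed")
        assert chose_log / reps >= 0.90

    def test_nonpositive_value_blocks_log_branch(self):
        # heteroscedastic with a negative value: log retry must error
        a = np.array([-1.0, 5.0, 50.0, 500.0, 1000.0, 2000.0, 4000.0])
        b = a * np.array([1.5, 0.5, 1.8, 0.6, 1.7, 0.5, 1.9])
        with pytest.raises(ValueError, match="positive"):
            _sample(a, b).log10()


class TestPairedT:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t(_sample([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]))

    def test_type_i_error_calibration(self, rng):
        """Null rejection rate is 5% +/- 1% over 10,000 replicates (n=7)."""
        n, reps = 7, 10000
        a = rng.normal(100, 10, size=(reps, n))
        b = rng.normal(100, 10, size=(reps, n))
        p = stats.ttest_rel(b, a, axis=1).pvalue
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)

    def test_power_at_two_sd_shift(self, rng):
        """A 2-SD mean shift at n = 7 is detected in > 90% of replicates."""
        n, reps = 7, 2000
        a = rng.normal(0.0, 1.0, size=(reps, n))
        b = a + rng.normal(2.0, 1.0, size=(reps, n))
        p = stats.ttest_rel(b, a, axis=1).pvalue
        assert np.mean(p < 0.05) > 0.90


class TestBlandAltman:
    def test_symmetric_diffs_centered(self):
        s = _sample([10.0, 20.0, 30.0], [11.0, 20.0, 29.0])
        md, limits, _ = bland_altman(s)
        assert md == pytest.approx(0.0)
        assert limits[1] - limits[0] == pytest.approx(
            2 * repeatability_coefficient(difference_stats(s)[0])
        )

    def test_monte_carlo_coverage(self, rng):
        diffs = rng.normal(0.5, 1.5, 5000)
        s = _sample(np.zeros(5000), diffs)
        _, _, within = bland_altman(s)
        assert within == pytest.approx(0.95, abs=0.01)


class TestCompareRois:
    def test_identical_distributions_ns(self, rng):
        vals = {f"roi{i}": rng.normal(50, 5, 16) for i in range(7)}
        table = compare_rois(vals)
        assert len(table) == 21  # all pairs of 7 ROIs
        assert (table["category"] == "ns").mean() > 0.9

    def test_separated_rois_reach_extreme_bin(self, rng):
        vals = {
            "a": rng.normal(50, 1, 16),
            "b": rng.normal(60, 1, 16),  # 10 SD apart
            "c": rng.normal(50.2, 1, 16),
        }
        table = compare_rois(vals)
        ab = table[(table.roi_a == "a") & (table.roi_b == "b")].iloc[0]
        assert ab["category"] == "<0.0005"

    def test_binning_rule(self):
        from quo2.reprostats import SIGNIFICANCE_BINS  # noqa: F401

        vals = {"a": np.zeros(3), "b": np.zeros(3)}
        # direct check of the binning applied to a known adjusted p
        table = compare_rois({"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 3.1]})
        assert set(table["category"]).issubset({"ns", "<0.05", "<0.005", "<0.0005"})


class TestReproMetricsCell:
    def test_invariants_hold_for_computed_cell(self, rng):
        a = rng.normal(100, 10, 8)
        b = a + rng.normal(1, 3, 8)
        r = compute_repro_metrics(_sample(a, b))
        assert r.wssd == pytest.approx(r.dsd / np.sqrt(2.0), rel=1e-12)
        assert r.cr == pytest.approx(1.96 * np.sqrt(2.0) * r.wssd, rel=1e-12)
        assert r.wscv_pct >= 0 and r.bscv_pct >= 0

    def test_subject_order_invariance(self, rng):
        a = rng.normal(100, 10, 9)
        b = a + rng.normal(0, 3, 9)
        perm = rng.permutation(9)
        r1 = compute_repro_metrics(_sample(a, b))
        r2 = compute_repro_metrics(_sample(a[perm], b[perm]))
        assert r1.dsd == pytest.approx(r2.dsd)
        assert r1.wscv_pct == pytest.approx(r2.wscv_pct)
        assert r1.bscv_pct == pytest.approx(r2.bscv_pct)

    def test_repro_table_identical_sessions(self, rng):
        import pandas as pd

        rows = []
        for subj in range(6):
            for roi in ("GM", "HIP"):
                v = 100 + 10 * subj + (5 if roi == "HIP" else 0)
                for test in ("A", "B"):
                    rows.append(
                        {"subject": f"s{subj}", "test": test, "roi": roi,
                         "metric": "cbf0", "value": v}
                    )
        df = pd.DataFrame(rows)
        # a verbatim session copy is perfectly reproducible: wsCV and CR are
        # zero and the test p-values undefined
        table = repro_table(df)
        assert np.allclose(table["wscv_pct"], 0.0)
        assert np.allclose(table["cr"], 0.0)
        assert table["p_paired_t"].isna().all()
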