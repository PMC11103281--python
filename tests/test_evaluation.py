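"""Metrics, agreement statistics, hypothesis tests, Dice."""

import itertools

import numpy as np
import pytest
from scipy import stats

from synthce.evaluation import (AncovaResult, ancova_compare, bland_altman,
                                bonferroni, bootstrap_ci, compare_models,
                                dice, image_metrics, psnr_from_mse,
                                roi_intensity_table, select_slices)
from synthce.volio import Volume


class TestPsnr:
    @pytest.mark.parametrize("mse,expected", [
        (12836.0, 55.25),   # printed median pairs reconciled by peak 65535
        (2339.0, 62.64),
    ])
    def test_printed_pairs_reconciled_by_16bit_peak(self, mse, expected):
        assert round(psnr_from_mse(mse), 2) == expected

    def test_monotone_decreasing_in_mse(self, rng):
        mses = np.sort(rng.uniform(1, 1e6, 50))
        vals = [psnr_from_mse(m) for m in mses]
        assert (np.diff(vals) < 0).all()

    def test_median_commutes_with_psnr(self, rng):
        """median(pSNR) = pSNR(median MSE): the monotone-transform identity
        that justifies cell-wise consistency checking."""
        mses = rng.uniform(100, 20000, 21)
        psnrs = np.array([psnr_from_mse(m) for m in mses])
        assert np.median(psnrs) == pytest.approx(
            psnr_from_mse(float(np.median(mses))))

    def test_zero_mse_reports_infinity(self):
        assert psnr_from_mse(0.0) == np.inf


class TestImageMetrics:
    def test_identical_images(self, rng):
        v = Volume(rng.uniform(-500, 2500, (32, 32)))
        rec = image_metrics(v, Volume(v.data.copy()))
        assert rec.mse == 0.0 and rec.psnr == np.inf
        assert rec.ssim == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            image_metrics(Volume(np.zeros((4, 4))), Volume(np.zeros((5, 5))))

    def test_foreground_scope_restricts_mse(self, rng):
        truth = Volume(np.full((32, 32), 100.0))
        pred_data = truth.data.copy()
        mask = np.zeros((32, 32), dtype=bool)
        mask[:16] = True
        pred_data[~mask] += 300.0       # error only outside the mask
        rec = image_metrics(Volume(pred_data), truth, mask=mask)
        assert rec.scope == "foreground"
        assert rec.mse == 0.0


class TestRoiTable:
    def test_uniform_intensity_readout(self):
        vol = Volume(np.full((16, 16, 12), 100.0))
        mask = np.zeros((16, 16, 12), dtype=bool)
        mask[4:8, 4:8, 2:9] = True
        out = roi_intensity_table(vol, {"aorta": mask})
        assert out["aorta"] == pytest.approx(100.0)

    def test_equal_spacing_slice_selection(self):
        mask = np.zeros((4, 4, 60), dtype=bool)
        mask[1, 1, 10:51] = True        # axial extent 10..50
        assert list(select_slices(mask, 5)) == [10, 20, 30, 40, 50]

    def test_short_extent_uses_all_slices(self):
        mask = np.zeros((4, 4, 10), dtype=bool)
        mask[0, 0, 3:6] = True
        with pytest.warns(UserWarning):
            zs = select_slices(mask, 5)
        assert list(zs) == [3, 4, 5]

    def test_missing_roi_recorded_absent(self):
        vol = Volume(np.zeros((8, 8, 8)))
        out = roi_intensity_table(vol, {"tumour": np.zeros((8, 8, 8), bool)})
        assert out["tumour"] is None

    def test_phantom_aorta_readout(self, clean_study_3d):
        t1 = clean_study_3d.targets[1.0]
        out = roi_intensity_table(t1, clean_study_3d.masks)
        curve = clean_study_3d.truth.enhancement_curves["aorta"]
        assert out["aorta"] == pytest.approx(curve.value_at(1.0))


class TestMetricTables:
    def test_median_summary_matches_monotone_identity(self, rng):
        """Within each cell the summarised median pSNR equals the pSNR of
        the median MSE when both come from the same records."""
        from synthce.evaluation import MetricRecord, summarise_metrics
        records = []
        for i in range(7):
            mse = float(rng.uniform(1000, 20000))
            records.append(MetricRecord(
                subject=f"s{i}", model="m", phase=1.0, scope="global",
                mse=mse, psnr=psnr_from_mse(mse), ssim=0.99))
        summary = summarise_metrics(records, ci_runs=200, seed=0)
        med_mse = summary.query("metric == 'mse'")["median"].iloc[0]
        med_psnr = summary.query("metric == 'psnr'")["median"].iloc[0]
        assert med_psnr == pytest.approx(psnr_from_mse(med_mse))


class TestBlandAltman:
    def test_perfect_agreement(self):
        y = np.array([100.0, 150.0, 200.0, 250.0])
        fit = bland_altman(y, y)
        assert fit.bias == 0.0
        assert fit.loa == (0.0, 0.0)
        assert fit.slope == pytest.approx(0.0)

    def test_constant_offset_classified(self):
        y = np.array([100.0, 150.0, 200.0, 250.0])
        fit = bland_altman(y + 10.0, y)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.bias_type == "constant"

    def test_proportional_scaling_slope(self):
        """pred = 1.2 truth: DI = 0.2 y, I-bar = 1.1 y, slope = 0.2/1.1."""
        y = np.linspace(100.0, 200.0, 11)
        fit = bland_altman(1.2 * y, y)
        assert fit.slope == pytest.approx(0.2 / 1.1)
        assert fit.bias_type == "proportional"

    def test_matches_normal_equation_oracle(self, rng):
        """Regression coefficients agree with a direct normal-equation
        solve on small instances."""
        for _ in range(5):
            pred = rng.normal(150, 30, size=6)
            truth = rng.normal(150, 30, size=6)
            fit = bland_altman(pred, truth)
            means = (pred + truth) / 2
            diffs = pred - truth
            X = np.column_stack([np.ones_like(means), means])
            beta = np.linalg.solve(X.T @ X, X.T @ diffs)
            assert fit.intercept == pytest.approx(beta[0])
            assert fit.slope == pytest.approx(beta[1])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_bias_type_recovery_rate(self):
        """Injected constant and proportional biases are classified
        correctly in at least 95% of seeded simulations at n = 15."""
        n_sim, ok_const, ok_prop = 60, 0, 0
        rng = np.random.default_rng(0)
        for _ in range(n_sim):
            truth = rng.uniform(100, 300, size=15)
            noise = rng.normal(0, 3, size=15)
            if bland_altman(truth + 40 + noise, truth).bias_type == "constant":
                ok_const += 1
            if bland_altman(truth * 1.3 + noise, truth).bias_type == "proportional":
                ok_prop += 1
        assert ok_const / n_sim >= 0.95
        assert ok_prop / n_sim >= 0.95


class TestAncova:
    def _fits(self, offsets, n=50, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for name, off in offsets.items():
            truth = rng.uniform(100, 300, size=n)
            pred = truth + off + rng.normal(0, 10, size=n)
            out[name] = bland_altman(pred, truth)
        return out

    def test_identical_models_nonsignificant(self):
        rng = np.random.default_rng(1)
        truth = rng.uniform(100, 300, size=40)
        noise = rng.normal(0, 10, size=40)
        fit_a = bland_altman(truth + noise, truth)
        fit_b = bland_altman(truth + noise, truth)
        res = ancova_compare({"a": fit_a, "b": fit_b})
        assert res.p_interaction > 0.05
        assert res.p_group > 0.05

    def test_constant_offset_detected_and_recovered(self):
        res = ancova_compare(self._fits({"a": 0.0, "b": 30.0}))
        assert res.p_interaction > 0.05
        assert res.contrasts[("a", "b")] < 0.05
        recovered = res.adjusted_means["b"] - res.adjusted_means["a"]
        assert recovered == pytest.approx(30.0, abs=10.0)

    def test_three_model_bonferroni_count(self):
        res = ancova_compare(self._fits({"a": 0.0, "b": 25.0, "c": 50.0}))
        assert res.contrasts is not None and len(res.contrasts) == 3

    def test_interaction_blocks_contrasts(self):
        rng = np.random.default_rng(2)
        truth = rng.uniform(100, 300, size=50)
        fit_a = bland_altman(truth + rng.normal(0, 5, 50), truth)
        fit_b = bland_altman(truth * 1.5 + rng.normal(0, 5, 50), truth)
        res = ancova_compare({"a": fit_a, "b": fit_b})
        assert res.p_interaction < 0.05
        assert res.contrasts is None and res.adjusted_means is None


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        lo, hi = bootstrap_ci(np.full(10, 3.3), runs=500, seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=20)
        assert bootstrap_ci(x, runs=1000, seed=5) == bootstrap_ci(
            x, runs=1000, seed=5)

    def test_runs_parameter_scales_down(self, rng):
        lo, hi = bootstrap_ci(rng.normal(size=15), runs=100, seed=0)
        assert lo <= hi

    def test_interval_covers_sample_median_typically(self, rng):
        x = rng.normal(size=25)
        lo, hi = bootstrap_ci(x, runs=2000, seed=1)
        assert lo <= np.median(x) <= hi


class TestHypothesisTests:
    def test_identical_groups_adjusted_to_one(self, rng):
        x = rng.normal(size=12)
        out = compare_models({"a": x, "b": x.copy()}, test="u")
        assert out[("a", "b")] == 1.0

    def test_shifted_gaussians_detected_by_u_test(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=30)
        b = rng.normal(2, 1, size=30)    # 2 sd separation
        out = compare_models({"a": a, "b": b}, test="u")
        assert out[("a", "b")] < 0.05

    def test_bonferroni_arithmetic(self):
        np.testing.assert_allclose(bonferroni([0.02], m=3), [0.06])
        np.testing.assert_allclose(bonferroni([0.5], m=4), [1.0])
        np.testing.assert_allclose(bonferroni([0.01, 0.02]), [0.02, 0.04])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": [1.0], "b": [1.0, 2.0]})

    def test_u_test_matches_exhaustive_enumeration(self):
        """Two-sided U-test p-value equals the exact permutation-rank
        enumeration for n <= 8 (no ties)."""
        x = np.array([1.2, 3.4, 5.1, 7.7])
        y = np.array([2.2, 4.0, 6.5, 8.8])
        got = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        # brute-force: every assignment of ranks to group x
        pooled = np.concatenate([x, y])
        order = stats.rankdata(pooled)
        u_obs = np.sum(order[: len(x)]) - len(x) * (len(x) + 1) / 2
        us = []
        for comb in itertools.combinations(range(len(pooled)), len(x)):
            u = np.sum(order[list(comb)]) - len(x) * (len(x) + 1) / 2
            us.append(u)
        us = np.array(us)
        mu = us.mean()
        p_exact = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12)
        assert got == pytest.approx(p_exact)

    def test_h_test_two_groups_matches_u_information(self):
        """For 2 groups the Kruskal-Wallis H-statistic is a monotone
        function of |U - mu_U|; check H matches its rank-sum closed form."""
        x = np.array([1.0, 4.0, 2.5])
        y = np.array([3.0, 5.0, 6.0])
        h, _ = stats.kruskal(x, y)
        pooled = np.concatenate([x, y])
        r = stats.rankdata(pooled)
        n, n1, n2 = 6, 3, 3
        expect = 12.0 / (n * (n + 1)) * (
            r[:3].sum() ** 2 / n1 + r[3:].sum() ** 2 / n2) - 3 * (n + 1)
        assert h == pytest.approx(expect)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2], b[6:] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100], b[50:150] = True, True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros(4, bool), np.zeros(4, bool)) == 1.0
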