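"""Preprocessing chain: calibration, LOD, plate normalization, Box-Cox,
Tukey fencing, control standardization, imputations, SNP filter, and the
acute-levodopa indicators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuro1c import preprocessing as pp
from neuro1c import synthetic as syn


class TestCalibration:
    def test_noiseless_quadratic_recovered(self):
        x = np.array([0.5, 1, 2, 4, 8, 16, 32], float)
        y = 1.0 + 2.0 * x + 0.1 * x**2
        curve = pp.fit_calibration(np.column_stack([x, y]))
        assert np.allclose(curve.coefficients, (1.0, 2.0, 0.1), atol=1e-9)

    def test_inverse_roundtrip_on_range(self):
        x = np.array([0.5, 1, 2, 4, 8, 16, 32], float)
        curve = pp.fit_calibration(
            np.column_stack([x, 50 + 100 * x + 0.5 * x**2]))
        conc = np.array([0.7, 3.3, 20.0])
        assert np.allclose(curve.concentration(curve.signal(conc)), conc,
                           atol=1e-9)

    def test_two_points_fall_back_to_identity(self):
        with pytest.warns(UserWarning):
            curve = pp.fit_calibration([(1.0, 10.0), (2.0, 20.0)])
        assert curve.identity
        assert np.allclose(curve.concentration([7.0]), [7.0])

    def test_noisy_fit_within_sampling_error(self, rng):
        x = np.repeat([1, 2, 4, 8, 16, 32, 64], 3).astype(float)
        est = []
        for _ in range(30):
            y = 1 + 2 * x + 0.1 * x**2 + rng.normal(0, 0.01, len(x))
            est.append(pp.fit_calibration(np.column_stack([x, y])).coefficients)
        est = np.asarray(est)
        assert np.allclose(est.mean(axis=0), (1, 2, 0.1), atol=0.01)


class TestLOD:
    def test_formula(self):
        assert pp.compute_lod([8, 10, 12]) == pytest.approx(10 + 3.09 * 2)

    def test_zero_sd(self):
        assert pp.compute_lod([5, 5, 5]) == 5.0

    def test_requires_two_blanks(self):
        with pytest.raises(pp.PreprocessingError):
            pp.compute_lod([5.0])

    def test_linear_in_blank_sd(self, rng):
        base = rng.normal(0, 1, 5000)
        lod1 = pp.compute_lod(100 + 10 * base)
        lod2 = pp.compute_lod(100 + 20 * base)
        assert (lod2 - 100) == pytest.approx(2 * (lod1 - 100), rel=1e-9)

    def test_simulated_normal_blanks(self, rng):
        lod = pp.compute_lod(rng.normal(100, 10, 10_000))
        assert lod == pytest.approx(130.9, abs=1.0)


class TestFlagBelowLOD:
    def _flags(self, values_below_fraction):
        n = 100
        k = int(values_below_fraction * n)
        sig = pd.DataFrame({"m": [0.0] * k + [10.0] * (n - k)},
                           index=[f"S{i}" for i in range(n)])
        plates = pd.Series(0, index=sig.index)
        lods = pd.DataFrame({"m": [5.0]}, index=[0])
        return pp.flag_below_lod(sig, plates, lods)["m"]

    def test_majority_below_excluded(self):
        assert self._flags(0.6)

    def test_exactly_half_retained(self):
        assert not self._flags(0.5)

    def test_all_above_retained(self):
        assert not self._flags(0.0)


class TestNormalizeAcrossPlates:
    def test_pure_offset_removed_exactly(self, rng):
        base = rng.normal(size=40)
        x = pd.Series(np.concatenate([base, base + 1.0]))
        plates = pd.Series([0] * 40 + [1] * 40)
        groups = pd.Series(["g1", "g2"] * 40)
        out = pp.normalize_across_plates(x, plates, groups)
        m = out.groupby(plates).mean()
        assert abs(m[0] - m[1]) < 1e-9

    def test_single_plate_identity(self, rng):
        x = pd.Series(rng.normal(size=30))
        out = pp.normalize_across_plates(x, pd.Series(0, index=x.index),
                                         pd.Series("g", index=x.index))
        assert np.allclose(out, x)

    def test_idempotent(self, rng):
        x = pd.Series(rng.normal(size=60) + np.repeat([0.0, 1.5], 30))
        plates = pd.Series(np.repeat([0, 1], 30))
        groups = pd.Series(list("ab") * 30)
        once = pp.normalize_across_plates(x, plates, groups)
        twice = pp.normalize_across_plates(once, plates, groups)
        assert np.allclose(once, twice, atol=1e-9)

    def test_group_effect_preserved(self, rng):
        """Planted 1-SD group effect survives plate normalization within 0.1."""
        diffs = []
        for _ in range(50):
            n = 200
            groups = pd.Series(np.tile(["a", "b"], n // 2))
            plates = pd.Series(np.repeat([0, 1], n // 2))
            x = pd.Series(rng.normal(size=n) + (groups == "b") * 1.0
                          + plates * 0.8)
            out = pp.normalize_across_plates(x, plates, groups)
            diffs.append(out[groups == "b"].mean() - out[groups == "a"].mean())
        assert abs(np.mean(diffs) - 1.0) < 0.1

    def test_tiny_plate_left_unadjusted(self, rng):
        x = pd.Series(rng.normal(size=32))
        plates = pd.Series([0] * 30 + [1] * 2)
        groups = pd.Series("g", index=x.index)
        with pytest.warns(UserWarning, match="< 3 samples"):
            pp.normalize_across_plates(x, plates, groups)


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        inside = sum(
            abs(pp.estimate_boxcox_lambda(np.exp(rng.normal(0, 0.5, 500)))) <= 0.15
            for _ in range(40))
        assert inside >= 0.9 * 40

    def test_gaussian_lambda_near_one(self, rng):
        lams = [pp.estimate_boxcox_lambda(rng.normal(20, 2, 500))
                for _ in range(20)]
        assert abs(np.mean(lams) - 1.0) < 0.2

    def test_lambda_one_is_affine_shift(self):
        x = np.array([1.0, 2.5, 7.0])
        assert np.allclose(pp.apply_boxcox(x, 1.0), x - 1.0)

    def test_lambda_zero_is_log(self):
        x = np.array([1.0, np.e, np.e**2])
        assert np.allclose(pp.apply_boxcox(x, 0.0), [0, 1, 2])

    def test_nonpositive_rejected(self):
        with pytest.raises(pp.PreprocessingError):
            pp.estimate_boxcox_lambda([1.0, -2.0])

    def test_shift_positive(self):
        shifted, shift = pp.shift_positive([-2.0, 0.0, 3.0])
        assert shift == 3.0 and shifted.min() == 1.0


class TestTukeyWinsorize:
    def test_remote_outlier_clamped_to_fence(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], float)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        fence = q3 + 3 * (q3 - q1)
        out = pp.tukey_winsorize(x)
        assert out[-1] == pytest.approx(fence)
        assert np.allclose(out[:-1], x[:-1])

    def test_no_outliers_identity(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(pp.tukey_winsorize(x), x)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    def test_idempotent_and_rank_preserving(self, xs):
        x = np.asarray(xs, float)
        once = pp.tukey_winsorize(x)
        assert np.allclose(pp.tukey_winsorize(once), once)
        assert (np.argsort(np.argsort(once, kind="stable"), kind="stable")
                == np.argsort(np.argsort(x, kind="stable"), kind="stable")).all() \
            or len(np.unique(once)) < len(np.unique(x))  # ties created at fences


class TestStandardizeToControls:
    def test_direct_example(self):
        z = pp.standardize_to_controls([1, 2, 3, 4], [True, True, True, False])
        assert np.allclose(z, [-1, 0, 1, 2])

    def test_control_mean_zero_after(self, rng):
        x = rng.normal(5, 2, 100)
        mask = np.zeros(100, bool)
        mask[:40] = True
        z = pp.standardize_to_controls(x, mask)
        assert abs(z[mask].mean()) < 1e-12
        assert z[mask].std(ddof=1) == pytest.approx(1.0)

    def test_constant_controls_rejected(self):
        with pytest.raises(pp.PreprocessingError):
            pp.standardize_to_controls([1, 1, 1, 5], [True, True, True, False])


class TestImputation:
    def test_conditional_mean(self):
        t = pd.DataFrame({"group": ["a", "a", "a", "b"], "sex": "M",
                          "bmi": [25.0, 27.0, np.nan, 30.0]})
        out = pp.impute_conditional_mean(t, "bmi")
        assert out["bmi"].iloc[2] == 26.0

    def test_no_missing_identity(self):
        t = pd.DataFrame({"group": ["a"], "sex": ["M"], "bmi": [25.0]})
        assert pp.impute_conditional_mean(t, "bmi").equals(t)

    def test_empty_cell_falls_back_to_group_mean(self):
        t = pd.DataFrame({"group": ["a", "a", "a"], "sex": ["M", "M", "F"],
                          "bmi": [24.0, 26.0, np.nan]})
        out = pp.impute_conditional_mean(t, "bmi")
        assert out["bmi"].iloc[2] == 25.0

    def test_half_min(self):
        x = pp.half_min_interpolate([0.8, 1.2, np.nan, np.nan])
        assert np.allclose(x[2:], 0.4)

    def test_half_min_single_detected(self):
        assert pp.half_min_interpolate([2.0, np.nan])[1] == 1.0

    def test_half_min_all_missing_rejected(self):
        with pytest.raises(pp.PreprocessingError):
            pp.half_min_interpolate([np.nan, np.nan])


class TestRareSNPFilter:
    @pytest.mark.parametrize("carriers,kept", [(4, False), (5, True)])
    def test_carrier_boundary(self, carriers, kept):
        g = pd.DataFrame({"s": [1] * carriers + [0] * (20 - carriers)},
                         dtype=float)
        assert ("s" in pp.filter_rare_snps(g).columns) == kept

    def test_monomorphic_removed(self):
        g = pd.DataFrame({"s": [0.0] * 20})
        assert pp.filter_rare_snps(g).shape[1] == 0

    def test_allele_count_mode(self):
        g = pd.DataFrame({"s": [2.0, 2.0, 1.0] + [0.0] * 17})
        assert "s" in pp.filter_rare_snps(g, count="alleles").columns
        assert "s" not in pp.filter_rare_snps(g, count="carriers").columns


class TestDopaIndicators:
    def _groups(self):
        return pd.Series(["HC-CN"] * 20 + ["PD-D", "PD-CN"])

    def test_pdd_above_threshold_flagged(self, rng):
        groups = self._groups()
        dopa = pd.Series(np.r_[rng.normal(0, 1, 20), 1.70, 1.50])
        ctrl = dopa[:20]
        thr = ctrl.mean() + 1.6449 * ctrl.std(ddof=1)
        out = pp.derive_dopa_indicators(dopa, groups)
        assert out["dopa_pdd"].iloc[20] == int(1.70 > thr)
        assert out["dopa_pdnd"].iloc[21] == int(1.50 > thr)

    def test_controls_never_flagged(self):
        groups = self._groups()
        dopa = pd.Series([0.0] * 19 + [3.0, 0.1, 0.1])
        out = pp.derive_dopa_indicators(dopa, groups)
        assert out.iloc[:20].sum().sum() == 0

    def test_requires_controls(self):
        with pytest.raises(pp.PreprocessingError):
            pp.derive_dopa_indicators(pd.Series([1.0, 2.0]),
                                      pd.Series(["PD-D", "PD-CN"]))


class TestFullChain:
    def test_control_moments_and_metadata(self, cohort, null_assay):
        proc = pp.preprocess_assay(null_assay, cohort)
        groups = cohort.set_index("subject_id")["group"].reindex(proc.z.index)
        ctrl = proc.z[(groups == "HC-CN").to_numpy()]
        assert ctrl.mean().abs().max() < 1e-10
        assert (ctrl.std(ddof=1) - 1).abs().max() < 1e-10
        assert set(proc.meta["lambda"]) == set(proc.z.columns)

    def test_below_lod_metabolite_excluded(self, cohort):
        assay = syn.generate_raw_assay(cohort, [], seed=21)
        # force one metabolite's sample signals to blank level
        low = assay["metabolite"] == "MeCbl"
        assay.loc[low & (assay["well_type"] == "sample"), "signal"] = 50.0
        proc = pp.preprocess_assay(assay, cohort)
        assert "MeCbl" in proc.meta["excluded"]
        assert "MeCbl" not in proc.z.columns
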