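"""SD -> chain-length calibration, Mw determination, method comparison."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pegcal import (
    CalibrationModel,
    DomainError,
    FitError,
    GeneratorConfig,
    Measurement,
    compare_methods,
    determine_mw,
    fit_calibration,
    make_calibration_dataset,
    predict_h_rms,
    simulate_spectrum,
)
from pegcal.datasets import reference_panel_derived
from pegcal.spectra import Spectrum, replicate_stability
from pegcal.synthetic_data import TRUTH_POWER_LAW, aggregation_fraction
from pegcal.polymer_dimensions import mw_to_h_rms


def eq12_model(n=6):
    """A noiseless calibration sampled from the published 16-nm line
    h = 1.4366*SD - 0.3308."""
    sd = np.linspace(1.5, 7.5, n)
    h = 1.4366 * sd - 0.3308
    return fit_calibration(sd.tolist(), h.tolist())


class TestFitCalibration:
    def test_noiseless_line_recovered(self):
        model = eq12_model()
        assert model.slope == pytest.approx(1.4366, abs=1e-10)
        assert model.intercept == pytest.approx(-0.3308, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_simulated_scatter_within_two_standard_errors(self):
        rng = np.random.default_rng(7)
        sd = np.linspace(1.5, 7.5, 8)
        h = 1.4366 * sd - 0.3308 + rng.normal(0, 0.15, 8)
        model = fit_calibration(sd.tolist(), h.tolist())
        se_slope = model.residual_sd / math.sqrt(np.sum((sd - sd.mean()) ** 2))
        assert abs(model.slope - 1.4366) < 2 * se_slope + 1e-12

    def test_two_points_rejected(self):
        with pytest.raises(FitError):
            fit_calibration([1.0, 2.0], [1.0, 2.0])

    def test_constant_sd_rejected(self):
        with pytest.raises(FitError):
            fit_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_json_round_trip(self):
        model = eq12_model()
        clone = CalibrationModel.from_json(model.to_json())
        assert clone == model


class TestPredictHrms:
    def test_published_line_at_sd_five(self):
        pred = predict_h_rms(Measurement(5.0, 0.0), eq12_model())
        assert pred.h_rms.value == pytest.approx(1.4366 * 5 - 0.3308, abs=1e-9)
        assert pred.h_rms.value == pytest.approx(6.852, abs=1e-3)
        assert not pred.extrapolated

    def test_intercept_at_zero_sd_flagged_extrapolated(self):
        pred = predict_h_rms(Measurement(0.0, 0.0), eq12_model())
        assert pred.h_rms.value == pytest.approx(-0.3308, abs=1e-9)
        assert pred.extrapolated

    def test_affine_in_the_mean(self):
        model = eq12_model()
        sds = [2.0, 3.5, 6.0]
        mean_of_preds = np.mean(
            [predict_h_rms(Measurement(s), model).h_rms.value for s in sds]
        )
        pred_of_mean = predict_h_rms(Measurement(float(np.mean(sds))), model).h_rms.value
        assert pred_of_mean == pytest.approx(mean_of_preds, rel=1e-12)

    def test_variance_minimal_at_training_mean(self):
        rng = np.random.default_rng(3)
        sd = np.linspace(1.5, 7.5, 8)
        h = 1.4366 * sd - 0.3308 + rng.normal(0, 0.2, 8)
        model = fit_calibration(sd.tolist(), h.tolist())
        grid = np.linspace(model.sd_min, model.sd_max, 30)
        variances = [predict_h_rms(Measurement(x), model).h_rms.sd ** 2 for x in grid]
        at_mean = predict_h_rms(Measurement(model.sd_mean), model).h_rms.sd ** 2
        assert at_mean <= min(variances) + 1e-12

    def test_sd_uncertainty_propagates(self):
        model = eq12_model()
        narrow = predict_h_rms(Measurement(5.0, 0.0), model).h_rms.sd
        wide = predict_h_rms(Measurement(5.0, 0.5), model).h_rms.sd
        assert wide**2 - narrow**2 == pytest.approx(model.slope**2 * 0.25, rel=1e-9)


class TestDetermineMw:
    def test_published_size_inverts_to_published_mw(self):
        # 9.903 nm through the published law -> ~1.19e4 Da
        from pegcal import h_rms_to_mw

        mw = h_rms_to_mw(9.903, TRUTH_POWER_LAW)
        assert mw.value == pytest.approx(1.19e4, rel=0.01)

    def test_synthetic_triplicate_recovery(self, profile16):
        config = GeneratorConfig(profile=profile16, seed=11)
        bundle = make_calibration_dataset(config=config)
        cal = fit_calibration(
            [replicate_stability(s.spectra, bundle.blank, profile16)[0] for s in bundle.samples],
            [s.h_ref for s in bundle.samples],
            profile=profile16,
        )
        rng = np.random.default_rng(12)
        true_mw = 5000.0
        f = aggregation_fraction(mw_to_h_rms(true_mw, TRUTH_POWER_LAW), config)
        spectra = [
            simulate_spectrum(f, config, rng=rng, sample_id="u", replicate=r)
            for r in range(3)
        ]
        det = determine_mw(spectra, bundle.blank, cal, TRUTH_POWER_LAW, profile16)
        assert det.flag in ("in-range", "extrapolated")
        assert det.mw.value == pytest.approx(true_mw, rel=0.15)
        assert det.sd_sd is not None and det.n_replicates == 3

    def test_single_replicate_has_no_sd_scatter(self, profile16):
        config = GeneratorConfig(profile=profile16, noise_sd=0.0, seed=0)
        blank = simulate_spectrum(0.0, config, is_blank=True)
        spec = simulate_spectrum(0.5, config, sample_id="u")
        model = eq12_model()
        det = determine_mw([spec], blank, model, TRUTH_POWER_LAW, profile16)
        assert det.n_replicates == 1
        assert det.sd_sd is None
        # uncertainty comes from the calibration residual alone
        assert det.h_rms.sd == pytest.approx(
            predict_h_rms(Measurement(det.sd_mean, 0.0), model).h_rms.sd
        )

    def test_fully_stable_sample_reported_above_range(self, profile16):
        config = GeneratorConfig(profile=profile16, noise_sd=0.0, seed=0)
        blank = simulate_spectrum(0.0, config, is_blank=True)
        stable = simulate_spectrum(0.0, config, sample_id="u")
        det = determine_mw([stable] * 3, blank, eq12_model(), TRUTH_POWER_LAW, profile16)
        assert det.flag == "above-range"
        assert det.mw is None and det.h_rms is None

    def test_panel_ordering_preserved(self, profile16):
        """Determinations on noiseless spectra of the reference panel keep
        the exact molar-mass ordering (rank correlation 1)."""
        config = GeneratorConfig(profile=profile16, noise_sd=0.0, replicate_cv=0.0, seed=0)
        bundle = make_calibration_dataset(config=config, replicates=1)
        cal = fit_calibration(
            [replicate_stability(s.spectra, bundle.blank, profile16)[0] for s in bundle.samples],
            [s.h_ref for s in bundle.samples],
        )
        derived = reference_panel_derived()
        apeg = derived[derived.label.str.startswith("APEG")]
        in_range = apeg[(apeg.h_rms_nm >= 1.9) & (apeg.h_rms_nm <= 10.2)]
        mws = []
        for h in in_range.h_rms_nm:
            f = aggregation_fraction(float(h), config)
            spec = simulate_spectrum(f, config, sample_id="panel")
            det = determine_mw([spec], bundle.blank, cal, TRUTH_POWER_LAW, profile16)
            mws.append(det.mw.value)
        rho = stats.spearmanr(mws, in_range.h_rms_nm).statistic
        assert rho == pytest.approx(1.0)

    def test_half_split_recovery_without_sign_bias(self, profile16):
        """Calibrate on 25 simulated standards, predict 25 held-out unknowns:
        median |relative Mw error| <= 15% and no systematic sign bias."""
        config = GeneratorConfig(profile=profile16, seed=3)
        rng = np.random.default_rng(3)
        mws = rng.uniform(600, 12000, 50)
        blank = simulate_spectrum(0.0, config, rng=rng, is_blank=True)
        entries = []
        for mw in mws:
            h = mw_to_h_rms(float(mw), TRUTH_POWER_LAW)
            f = aggregation_fraction(h, config)
            specs = [
                simulate_spectrum(f, config, rng=rng, replicate=r) for r in range(3)
            ]
            from pegcal import simulate_dls
            from pegcal.polymer_dimensions import RH_OVER_RG, SQRT6

            hv = simulate_dls(float(mw), 3, config, rng=rng) / RH_OVER_RG * SQRT6
            entries.append((float(mw), specs, Measurement(float(hv.mean()), float(hv.std(ddof=1)))))
        train, test = entries[:25], entries[25:]
        cal = fit_calibration(
            [replicate_stability(s, blank, profile16)[0] for _, s, _ in train],
            [h for _, _, h in train],
        )
        errs = np.array(
            [
                (determine_mw(s, blank, cal, TRUTH_POWER_LAW, profile16).mw.value - mw) / mw
                for mw, s, _ in test
            ]
        )
        assert np.median(np.abs(errs)) <= 0.15
        n_pos = int((errs > 0).sum())
        p = stats.binomtest(n_pos, int((errs != 0).sum())).pvalue
        assert p > 0.05


class TestCompareMethods:
    def test_identical_groups(self):
        res = compare_methods(5.0, 1.0, 3, 5.0, 1.0, 3)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert res.df == 4

    def test_published_mw_comparison_not_significant(self):
        # colorimetric 8,096 +/- 532 vs reference 8,350 +/- 301, triplicates
        res = compare_methods(8096, 532, 3, 8350, 301, 3)
        assert res.pvalue > 0.1

    def test_matches_exact_permutation_test(self):
        a = (1.0, 2.0, 3.0)
        b = (2.5, 3.5, 4.5)
        res = compare_methods(
            float(np.mean(a)), float(np.std(a, ddof=1)), 3,
            float(np.mean(b)), float(np.std(b, ddof=1)), 3,
        )
        pool = a + b
        t_obs = abs(res.statistic)
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            ga = [pool[i] for i in idx]
            gb = [pool[i] for i in range(6) if i not in idx]
            t = stats.ttest_ind(ga, gb).statistic
            total += 1
            if abs(t) >= t_obs - 1e-9:
                count += 1
        p_perm = count / total
        assert abs(res.pvalue - p_perm) < 0.15

    def test_welch_variant_differs_for_unequal_variances(self):
        student = compare_methods(10, 1.0, 3, 12, 5.0, 3)
        welch = compare_methods(10, 1.0, 3, 12, 5.0, 3, welch=True)
        assert welch.df < student.df
        assert welch.pvalue != pytest.approx(student.pvalue)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            compare_methods(1.0, 1.0, 1, 2.0, 1.0, 3)
        with pytest.raises(DomainError):
            compare_methods(1.0, 0.0, 3, 2.0, 1.0, 3)
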