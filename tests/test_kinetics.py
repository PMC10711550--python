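"""EMSA fraction-bound/Hill, BLI 1:1 kinetics, and FRAP fitting."""

import numpy as np
import pandas as pd
import pytest

from tfse.kinetics import (
    BindingCurve,
    ExponentialPhaseModel,
    HillBindingModel,
    derive_rate_constants,
    fit_bli,
    fit_bli_association,
    fit_bli_dissociation,
    fit_bli_global,
    fit_frap,
    fit_hill,
    fraction_bound,
    frap_correct,
)
from tfse.simulate import (
    simulate_binding_curve,
    simulate_bli_trace,
    simulate_frap_trace,
)


class TestFractionBound:
    def test_endpoints(self):
        assert fraction_bound(100.0, 100.0) == 0.0
        assert fraction_bound(0.0, 100.0) == 100.0

    def test_71_percent_occupancy(self):
        # free band at 29% of the zero-protein lane -> 71% bound
        assert fraction_bound(0.29 * 580.0, 580.0) == pytest.approx(71.0)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert fraction_bound(120.0, 100.0) == 0.0
        with pytest.warns(UserWarning, match="clipping"):
            assert fraction_bound(-5.0, 100.0) == 100.0

    def test_nonpositive_total_is_error(self):
        with pytest.raises(ValueError):
            fraction_bound(1.0, 0.0)

    def test_monotone_decreasing_in_free(self, rng):
        frees = np.sort(rng.uniform(0, 50, size=20))
        vals = [fraction_bound(f, 50.0) for f in frees]
        assert np.all(np.diff(vals) <= 0)
        assert all(0 <= v <= 100 for v in vals)


class TestHill:
    def test_noiseless_recovery_to_1e6(self):
        curve, truth = simulate_binding_curve(kd_nm=10.0, hill=1.5, seed=0)
        fit = fit_hill(curve)
        assert fit.kd_nm == pytest.approx(truth["kd_nm"], rel=1e-6)
        assert fit.hill_coefficient == pytest.approx(truth["hill"], rel=1e-6)
        assert fit.bmax == 1.0

    @pytest.mark.parametrize("h", [0.7, 1.0, 2.5])
    def test_half_saturation_at_kd_for_any_h(self, h):
        m = HillBindingModel().fit([1, 5, 25, 125], [0.1, 0.4, 0.8, 0.95])
        m.kd_, m.h_ = 5.0, h
        assert m.predict([5.0])[0] == pytest.approx(0.5)

    def test_free_bmax_mode_recovers_submaximal_plateau(self):
        x = np.array([1.0, 3, 10, 30, 100, 300])
        y = 0.8 / (1 + (10.0 / x) ** 1.2)
        m = HillBindingModel(fix_bmax=False).fit(x, y)
        assert m.bmax_ == pytest.approx(0.8, rel=1e-6)
        assert m.kd_ == pytest.approx(10.0, rel=1e-6)

    def test_noisy_median_kd_error_below_10pct(self):
        errs = []
        for seed in range(20):
            curve, truth = simulate_binding_curve(noise_sd=0.02, seed=seed)
            fit = fit_hill(curve)
            errs.append(abs(fit.kd_nm - truth["kd_nm"]) / truth["kd_nm"])
        assert np.median(errs) < 0.10

    def test_too_few_points_and_no_binding_error(self):
        with pytest.raises(ValueError):
            HillBindingModel().fit([1, 10], [0.1, 0.9])
        with pytest.raises(ValueError):
            HillBindingModel().fit([1, 10, 100], [0.0, 0.0, 0.0])


class TestBliPhases:
    def test_association_noiseless_exact(self):
        t = np.arange(0.0, 600.0, 1.0)
        y = 1.0 * (1.0 - np.exp(-0.01 * t))
        y0, a, kobs = fit_bli_association(t, y)
        assert y0 == pytest.approx(0.0, abs=1e-8)
        assert a == pytest.approx(1.0, rel=1e-8)
        assert kobs == pytest.approx(0.01, rel=1e-8)

    def test_flat_trace_is_error(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError, match="flat"):
            fit_bli_association(t, np.full_like(t, 0.7))

    def test_truncation_at_3_over_kobs_changes_kobs_below_5pct(self):
        kobs = 0.01
        t = np.arange(0.0, 600.0, 1.0)
        y = 1.0 - np.exp(-kobs * t)
        full = fit_bli_association(t, y)[2]
        cut = t <= 3.0 / kobs
        trunc = fit_bli_association(t[cut], y[cut])[2]
        assert abs(trunc - full) / full < 0.05

    def test_dissociation_noiseless_exact_and_half_life(self):
        kd = 0.002
        t = np.arange(0.0, 2000.0, 2.0)
        y = 0.1 + 0.9 * np.exp(-kd * t)
        y0, a, kd_fit = fit_bli_dissociation(t, y)
        assert kd_fit == pytest.approx(kd, rel=1e-8)
        # closed form: signal(t_half) - Y0 = A/2 at t_half = ln2/kd
        t_half = np.log(2) / kd_fit
        assert y0 + a * np.exp(-kd_fit * t_half) - y0 == pytest.approx(a / 2)

    def test_no_dissociation_flags_lower_bound_only(self):
        t = np.arange(0.0, 100.0, 1.0)
        y = np.exp(-5e-5 * t)  # decays by 0.5% over the whole window
        m = ExponentialPhaseModel("dissociation").fit(t, y)
        assert m.rate_lower_bound_only_


class TestRateConstantArithmetic:
    def test_printed_equation_example(self):
        ka, KD = derive_rate_constants(0.01, 0.002, 100.0)
        assert ka == pytest.approx(8e-5)
        assert KD == pytest.approx(25.0)

    def test_no_net_association_error(self):
        with pytest.raises(ValueError, match="net association"):
            derive_rate_constants(0.002, 0.002, 100.0)
        with pytest.raises(ValueError):
            derive_rate_constants(0.01, 0.002, 0.0)

    def test_round_trip_inverse_of_kobs(self, rng):
        for _ in range(50):
            ka = float(rng.uniform(1e-6, 1e-3))
            kd = float(rng.uniform(1e-5, 1e-2))
            conc = float(rng.uniform(1, 500))
            kobs = ka * conc + kd
            ka_back, KD = derive_rate_constants(kobs, kd, conc)
            assert ka_back == pytest.approx(ka, rel=1e-12)
            assert KD == pytest.approx(kd / ka, rel=1e-12)


class TestBliTraceAnalysis:
    def test_sequential_recovers_truth_noiseless(self):
        trace, truth = simulate_bli_trace(seed=0)
        fit = fit_bli(trace, mode="sequential")[0]
        assert fit.kobs == pytest.approx(truth["kobs"], rel=1e-6)
        assert fit.kd == pytest.approx(truth["kd"], rel=1e-6)
        assert fit.ka == pytest.approx(truth["ka"], rel=1e-6)
        assert fit.KD == pytest.approx(truth["KD_nm"], rel=1e-6)

    def test_global_fit_across_concentrations(self):
        traces = [
            simulate_bli_trace(analyte_conc_nm=c, seed=0)[0]
            for c in (25.0, 50.0, 100.0, 200.0)
        ]
        res = fit_bli_global(pd.concat(traces, ignore_index=True))
        assert res["ka"] == pytest.approx(8e-5, rel=1e-4)
        assert res["kd"] == pytest.approx(2e-3, rel=1e-4)
        assert res["KD"] == pytest.approx(25.0, rel=1e-4)

    def test_missing_phase_is_error(self):
        trace, _ = simulate_bli_trace(seed=0)
        with pytest.raises(ValueError, match="both phases"):
            fit_bli(trace[trace["phase"] == "assoc"])


class TestFrapCorrect:
    def test_roi_equal_ref_no_background_is_all_ones(self):
        x = np.linspace(100, 80, 30)
        out = frap_correct(x, x, np.zeros(30), bleach_index=5)
        assert np.allclose(out, 1.0)

    def test_reference_drift_exactly_compensated(self):
        trace, truth = simulate_frap_trace(seed=0, drift_per_s=0.0)
        drifted, _ = simulate_frap_trace(seed=0, drift_per_s=5e-3)
        a = frap_correct(trace["roi"], trace["reference"], trace["background"],
                         truth["bleach_index"])
        b = frap_correct(drifted["roi"], drifted["reference"],
                         drifted["background"], truth["bleach_index"])
        assert np.allclose(a, b)

    def test_hand_computed_values(self):
        roi = np.array([110.0, 110, 35, 60])
        ref = np.array([110.0, 110, 110, 110])
        bg = np.array([10.0, 10, 10, 10])
        out = frap_correct(roi, ref, bg, bleach_index=2)
        assert np.allclose(out, [1.0, 1.0, 0.25, 0.5])
        assert out[:2].mean() == pytest.approx(1.0, abs=1e-9)

    def test_rescaling_after_bg_subtraction_is_invariant(self):
        trace, truth = simulate_frap_trace(seed=1)
        bg = trace["background"].to_numpy()
        roi, ref = trace["roi"].to_numpy(), trace["reference"].to_numpy()
        a = frap_correct(roi, ref, bg, truth["bleach_index"])
        b = frap_correct(bg + 3.3 * (roi - bg), bg + 3.3 * (ref - bg), bg,
                         truth["bleach_index"])
        assert np.allclose(a, b)

    def test_reference_below_background_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            frap_correct([1.0, 1, 1], [0.5, 2, 2], [1.0, 1, 1], 1)


class TestFrapFit:
    def test_single_exponential_tau_10s(self):
        trace, truth = simulate_frap_trace(tau1_s=10.0, a1=0.8, a2=0.0, seed=0)
        corr = frap_correct(trace["roi"], trace["reference"],
                            trace["background"], truth["bleach_index"])
        fit = fit_frap(corr, trace["time_s"].to_numpy(), truth["bleach_index"])
        assert fit.tau_s == pytest.approx(10.0, rel=1e-6)

    def test_full_recovery_gives_mobile_fraction_one(self):
        trace, truth = simulate_frap_trace(a1=0.8, bleach_depth=0.8, seed=0)
        corr = frap_correct(trace["roi"], trace["reference"],
                            trace["background"], truth["bleach_index"])
        fit = fit_frap(corr, trace["time_s"].to_numpy(), truth["bleach_index"])
        assert fit.mobile_fraction == pytest.approx(1.0, rel=1e-6)

    def test_partial_recovery_mobile_fraction(self):
        trace, truth = simulate_frap_trace(a1=0.4, a2=0.0, bleach_depth=0.8,
                                           duration_s=200, seed=0)
        corr = frap_correct(trace["roi"], trace["reference"],
                            trace["background"], truth["bleach_index"])
        fit = fit_frap(corr, trace["time_s"].to_numpy(), truth["bleach_index"])
        assert fit.mobile_fraction == pytest.approx(0.5, rel=1e-4)

    def test_two_component_weighted_tau(self):
        trace, truth = simulate_frap_trace(
            tau1_s=5.0, tau2_s=50.0, a1=0.4, a2=0.4, duration_s=300.0, seed=0
        )
        corr = frap_correct(trace["roi"], trace["reference"],
                            trace["background"], truth["bleach_index"])
        fit = fit_frap(corr, trace["time_s"].to_numpy(), truth["bleach_index"])
        assert truth["tau_s"] == pytest.approx(27.5)
        assert fit.tau_s == pytest.approx(27.5, rel=0.01)
        assert fit.tau1_s < fit.tau2_s

    def test_short_post_bleach_segment_is_error(self):
        with pytest.raises(ValueError):
            fit_frap(np.ones(12), np.arange(12.0), bleach_index=8)
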