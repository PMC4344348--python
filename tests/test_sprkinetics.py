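"""Forward model and fitting of the 1:1 interaction kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindscreen import sprkinetics as spr
from bindscreen import synthdata as sd
from bindscreen.errors import (
    InsufficientDataError,
    InvalidInputError,
    UnfittableSegmentError,
)

KA, KD_RATE, RMAX = 1e5, 1e-2, 100.0


@pytest.fixture
def params():
    return spr.KineticParameters(ka=KA, kd=KD_RATE, rmax=RMAX)


class TestForwardModel:
    def test_association_starts_at_zero(self, params):
        assert spr.predicted_response(params, 1e-6, 0.0, "association") == 0.0

    def test_association_value_at_10s(self, params):
        # k_obs = 1e-6*1e5 + 1e-2 = 0.11 1/s, R_eq = 100*0.1/0.11 = 90.909 RU
        expected = (100.0 * 0.1 / 0.11) * (1.0 - np.exp(-0.11 * 10.0))
        got = spr.predicted_response(params, 1e-6, 10.0, "association")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(60.648, abs=0.001)

    def test_dissociation_starts_at_amplitude(self, params):
        assert spr.predicted_response(params, 1e-6, 0.0, "dissociation", r0=100.0) == 100.0

    def test_dissociation_requires_r0(self, params):
        with pytest.raises(InvalidInputError):
            spr.predicted_response(params, 1e-6, 1.0, "dissociation")

    def test_half_saturation_at_kd(self, params):
        c = params.kD  # C = K_D gives R_eq = Rmax/2
        assert spr.steady_state_response(params, c) == pytest.approx(RMAX / 2, rel=1e-12)

    def test_saturation_limit(self, params):
        assert spr.steady_state_response(params, 1000 * params.kD) == pytest.approx(
            99.9, abs=0.01
        )

    def test_steady_state_value(self, params):
        assert spr.steady_state_response(params, 1e-6) == pytest.approx(
            90.909, abs=0.001
        )

    def test_steady_state_rejects_nonpositive_concentration(self, params):
        with pytest.raises(InvalidInputError):
            spr.steady_state_response(params, 0.0)

    def test_steady_state_matches_long_time_association(self, params):
        # at t = 50/k_obs the exponential term is e^-50, numerically zero
        kobs = 1e-6 * params.ka + params.kd
        plateau = spr.predicted_response(params, 1e-6, 50.0 / kobs, "association")
        assert plateau == pytest.approx(
            spr.steady_state_response(params, 1e-6), rel=1e-6
        )

    def test_plateau_monotone_in_concentration(self, params):
        concs = np.array([0.25, 0.5, 1, 2, 4]) * 1e-6
        plateaus = [spr.steady_state_response(params, c) for c in concs]
        assert np.all(np.diff(plateaus) > 0)


class TestSplitPhases:
    def test_segment_sample_counts(self, params):
        proto = sd.InjectionProtocol(0.0, 300.0, 600.0, 1.0, (1e-6, 2e-6))
        s = sd.simulate_sensorgram(params, proto, 1e-6, sd.SensorgramNoiseModel())
        assoc, diss = spr.split_phases(s)
        assert assoc.times.size == 301
        assert diss.times.size == 300

    def test_rezeroed_segments_start_at_zero(self, params):
        proto = sd.InjectionProtocol(30.0, 330.0, 630.0, 1.0, (1e-6, 2e-6))
        s = sd.simulate_sensorgram(params, proto, 1e-6, sd.SensorgramNoiseModel())
        assoc, diss = spr.split_phases(s)
        assert assoc.times[0] == 0.0
        assert diss.times[0] > 0.0

    def test_empty_dissociation_raises(self, params):
        t = np.arange(0.0, 301.0)
        r = np.ones_like(t)
        s = spr.Sensorgram(t, r, (0.0, 299.9, 300.0), 1e-6)
        with pytest.raises(InsufficientDataError):
            spr.split_phases(s)

    def test_baseline_offset_leaves_rates_invariant(self, params):
        """A constant pre-injection offset must not move ka or kd."""
        proto = sd.InjectionProtocol(30.0, 330.0, 630.0, 1.0, (0.5e-6, 1e-6, 2e-6))
        noise = sd.SensorgramNoiseModel(sigma_ru=0.0, seed=0)
        series = sd.simulate_sensorgram_series(params, proto, noise)
        shifted = spr.SensorgramSeries(
            [
                spr.Sensorgram(
                    s.times, s.responses + 37.5, s.phase_boundaries, s.concentration
                )
                for s in series
            ]
        )
        base = spr.fit_global(series)
        moved = spr.fit_global(shifted)
        assert moved.ka_hat == pytest.approx(base.ka_hat, rel=1e-9)
        assert moved.kd_hat == pytest.approx(base.kd_hat, rel=1e-9)


class TestDissociationFit:
    @pytest.mark.parametrize("r0,kd", [(100.0, 0.01), (50.0, 0.1), (200.0, 0.001)])
    def test_noiseless_matches_loglinear_oracle(self, r0, kd):
        t = np.arange(0.0, 301.0)
        seg = spr.PhaseSegment(t, r0 * np.exp(-kd * t), 1e-6, "dissociation")
        # independent oracle: exact log-linear regression
        slope, intercept = np.polyfit(t, np.log(r0 * np.exp(-kd * t)), 1)
        fit = spr.fit_dissociation(seg)
        assert fit.kd_hat == pytest.approx(-slope, rel=1e-9)
        assert fit.kd_hat == pytest.approx(kd, rel=1e-9)
        assert fit.r0_hat == pytest.approx(np.exp(intercept), rel=1e-9)

    def test_flat_segment_gives_zero_rate(self):
        t = np.arange(0.0, 50.0)
        seg = spr.PhaseSegment(t, np.full_like(t, 42.0), 1e-6, "dissociation")
        fit = spr.fit_dissociation(seg)
        assert fit.kd_hat == pytest.approx(0.0, abs=1e-9)
        assert fit.r0_hat == pytest.approx(42.0, rel=1e-9)

    def test_all_nonpositive_raises(self):
        t = np.arange(0.0, 10.0)
        seg = spr.PhaseSegment(t, -np.ones_like(t), 1e-6, "dissociation")
        with pytest.raises(UnfittableSegmentError):
            spr.fit_dissociation(seg)

    def test_noisy_recovery_within_five_percent_median(self):
        """Monte-Carlo: 1 RU noise on a 100 RU decay recovers kd to ~5%."""
        t = np.arange(0.0, 301.0)
        clean = 100.0 * np.exp(-0.01 * t)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            seg = spr.PhaseSegment(t, clean + rng.normal(0, 1.0, t.shape), 1e-6, "dissociation")
            errors.append(abs(spr.fit_dissociation(seg).kd_hat / 0.01 - 1.0))
        assert np.median(errors) <= 0.05


class TestAssociationFit:
    def _segment(self, params, c):
        t = np.arange(0.0, 301.0)
        r = spr.predicted_response(params, c, t, "association")
        return spr.PhaseSegment(t, r, c, "association")

    def test_noiseless_roundtrip_with_fixed_kd(self, params):
        fit = spr.fit_association(self._segment(params, 1e-6), kd_fixed=KD_RATE)
        assert fit.ka_hat == pytest.approx(KA, rel=1e-6)
        assert fit.rmax_hat == pytest.approx(RMAX, rel=1e-6)

    def test_kobs_value(self, params):
        fit = spr.fit_association(self._segment(params, 1e-6))
        assert fit.kobs_hat == pytest.approx(0.11, rel=1e-6)
        assert fit.ka_hat is None  # single curve cannot separate ka from kd

    def test_plateau_at_kd_concentration_is_half_rmax(self, params):
        fit = spr.fit_association(self._segment(params, params.kD))
        assert fit.req_hat == pytest.approx(RMAX / 2, rel=1e-6)


class TestKobsLine:
    def test_exact_line_through_noiseless_points(self, noiseless):
        ka_hat, kd_hat, diag = spr.fit_kobs_linear(noiseless)
        assert ka_hat == pytest.approx(1e5, rel=1e-6)
        assert kd_hat == pytest.approx(1.77e-2, rel=1e-6)
        assert len(diag["kobs"]) == 5

    def test_two_concentrations_suffice(self, egf_like_params):
        proto = sd.InjectionProtocol(30.0, 330.0, 630.0, 1.0, (1e-6, 4e-6))
        series = sd.simulate_sensorgram_series(
            egf_like_params, proto, sd.SensorgramNoiseModel()
        )
        ka_hat, kd_hat, _ = spr.fit_kobs_linear(series)
        assert ka_hat == pytest.approx(1e5, rel=1e-6)


class TestGlobalFit:
    @pytest.mark.parametrize("mode", ["independent", "global"])
    def test_noiseless_recovery_both_modes(self, noiseless, mode):
        result = spr.fit_global(noiseless, mode=mode)
        assert result.ka_hat == pytest.approx(1e5, rel=1e-3)
        assert result.kd_hat == pytest.approx(1.77e-2, rel=1e-3)
        assert result.rmax_hat == pytest.approx(100.0, rel=1e-3)
        assert result.kD_hat == pytest.approx(1.77e-7, rel=1e-3)
        assert result.converged
        assert result.kD_hat == result.kd_hat / result.ka_hat

    def test_modes_agree_on_noiseless_data(self, noiseless):
        indep = spr.fit_global(noiseless, mode="independent")
        glob = spr.fit_global(noiseless, mode="global")
        assert glob.ka_hat == pytest.approx(indep.ka_hat, rel=1e-6)
        assert glob.kd_hat == pytest.approx(indep.kd_hat, rel=1e-6)
        assert glob.rmax_hat == pytest.approx(indep.rmax_hat, rel=1e-6)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        log_ka=st.floats(4.0, 6.0),
        log_kd=st.floats(-2.5, -1.0),
        rmax=st.floats(50.0, 500.0),
    )
    def test_exact_recovery_across_parameter_space(self, log_ka, log_kd, rmax):
        """Noiseless generator -> fit recovers (ka, kd, Rmax) to <=1e-4 relative."""
        truth = spr.KineticParameters(ka=10**log_ka, kd=10**log_kd, rmax=rmax)
        proto = sd.InjectionProtocol(
            30.0, 330.0, 630.0, 1.0, tuple(np.array([0.25, 0.5, 1, 2, 4]) * 1e-6)
        )
        series = sd.simulate_sensorgram_series(truth, proto, sd.SensorgramNoiseModel())
        result = spr.fit_global(series)
        assert result.ka_hat == pytest.approx(truth.ka, rel=1e-4)
        assert result.kd_hat == pytest.approx(truth.kd, rel=1e-4)
        assert result.rmax_hat == pytest.approx(truth.rmax, rel=1e-4)

    def test_noisy_series_median_kd_error_below_five_percent(self, egf_like_params, protocol):
        errors = []
        for seed in range(40):
            noise = sd.SensorgramNoiseModel(sigma_ru=1.0, seed=seed)
            series = sd.simulate_sensorgram_series(egf_like_params, protocol, noise)
            result = spr.fit_global(series)
            errors.append(abs(result.kD_hat / 1.77e-7 - 1.0))
        assert np.median(errors) <= 0.05


class TestComputeKd:
    def test_unit_ratio(self):
        assert spr.compute_kd(1.0, 1.0) == 1.0

    def test_direct_ratio(self):
        assert spr.compute_kd(1e5, 1e-2) == pytest.approx(1e-7)

    def test_antibody_magnitude_fixture(self):
        # formatting/round-trip fixture at the tight-binder magnitude
        assert spr.compute_kd(1e7, 2.07e-2) == pytest.approx(2.07e-9, rel=1e-12)

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(InvalidInputError):
            spr.compute_kd(0.0, 1e-2)


class TestReferenceSubtraction:
    def test_control_channel_subtraction(self, egf_like_params, protocol):
        noise = sd.SensorgramNoiseModel(sigma_ru=0.0, seed=0)
        s = sd.simulate_sensorgram(egf_like_params, protocol, 1e-6, noise)
        bulk = spr.Sensorgram(
            s.times, np.full_like(s.times, 5.0), s.phase_boundaries, s.concentration
        )
        corrected = spr.subtract_reference(s, bulk)
        assert np.allclose(corrected.responses, s.responses - 5.0)

    def test_mismatched_grid_rejected(self, egf_like_params, protocol):
        noise = sd.SensorgramNoiseModel(sigma_ru=0.0, seed=0)
        s = sd.simulate_sensorgram(egf_like_params, protocol, 1e-6, noise)
        other = spr.Sensorgram(
            s.times[:-1] + 0.5, s.responses[:-1], (30.0, 330.0, 629.0), 1e-6
        )
        with pytest.raises(InvalidInputError):
            spr.subtract_reference(s, other)
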