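import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprquant.errors import SensorgramFormatError, ValidationError
from sprquant.sensorgram import (
    InjectionSchedule,
    LangmuirParameters,
    Sensorgram,
    fit_langmuir,
    langmuir_curve,
    read_sensorgram,
    reference_subtract,
    simulate_sensorgram,
    steady_state_response,
    write_sensorgram,
)

SCHEDULE = InjectionSchedule(
    start_s=60.0, association_s=720.0, dissociation_s=180.0, concentration_m=100e-6
)
PARAMS = LangmuirParameters(k_on=1e4, k_off=1e-3, r_max=0.6)


class TestIO:
    def test_small_file_roundtrip(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "# flow_rate_ul_min = 20.0\n"
            "time_s\tresponse_deg\tchannel\n"
            "0.0\t0.1\tch1\n1.0\t0.2\tch1\n2.0\t0.3\tch1\n"
        )
        s = read_sensorgram(path)
        assert len(s) == 3
        assert s.channel == "ch1"
        assert s.metadata["flow_rate_ul_min"] == 20.0

    def test_decreasing_time_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "time_s\tresponse_deg\tchannel\n0.0\t0.1\ta\n2.0\t0.2\ta\n1.0\t0.3\ta\n"
        )
        with pytest.raises(SensorgramFormatError, match="row 3"):
            read_sensorgram(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time_s\tresponse_deg\n0.0\t0.1\n")
        with pytest.raises(SensorgramFormatError, match="channel"):
            read_sensorgram(path)

    def test_simulated_roundtrip_full_precision(self, tmp_path):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.01, seed=3)
        path = tmp_path / "sim.tsv"
        write_sensorgram(s, path)
        back = read_sensorgram(path)
        assert np.array_equal(back.time, s.time)
        assert np.array_equal(back.response, s.response)
        assert back.channel == s.channel


class TestReferenceSubtract:
    def test_zero_reference_identity(self):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.0)
        ref = Sensorgram(time=s.time, response=np.zeros_like(s.response), channel="r")
        out = reference_subtract(s, ref)
        assert np.array_equal(out.response, s.response)

    def test_self_subtraction_zero(self):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.0)
        out = reference_subtract(s, s)
        assert np.allclose(out.response, 0.0)

    def test_recovers_pure_binding_from_bulk_shifted_pair(self):
        active = simulate_sensorgram(
            PARAMS, SCHEDULE, noise_sd=0.0, bulk_shift_deg=0.05, drift_deg_per_s=1e-5
        )
        reference = simulate_sensorgram(
            LangmuirParameters(0.0, 0.0, 0.0), SCHEDULE, noise_sd=0.0,
            bulk_shift_deg=0.05, drift_deg_per_s=1e-5,
        )
        corrected = reference_subtract(active, reference)
        pure = langmuir_curve(active.time, PARAMS, SCHEDULE)
        assert np.allclose(corrected.response, pure, atol=1e-12)

    def test_non_overlapping_ranges_rejected(self):
        a = Sensorgram(np.arange(10.0), np.zeros(10))
        b = Sensorgram(np.arange(20.0, 30.0), np.zeros(10))
        with pytest.raises(ValidationError):
            reference_subtract(a, b)

    def test_interpolates_mismatched_grids(self):
        t_fine = np.linspace(0.0, 100.0, 201)
        t_coarse = np.linspace(0.0, 100.0, 51)
        a = Sensorgram(t_fine, 2.0 * t_fine)
        b = Sensorgram(t_coarse, t_coarse)
        out = reference_subtract(a, b)
        assert np.allclose(out.response, t_fine, atol=1e-12)


class TestSteadyState:
    def test_constant_series(self):
        s = Sensorgram(np.arange(10.0), np.full(10, 0.42))
        est = steady_state_response(s, (2.0, 8.0))
        assert est.mean_deg == pytest.approx(0.42)
        assert est.sd_deg == pytest.approx(0.0)

    def test_symmetric_ramp_gives_midpoint(self):
        s = Sensorgram(np.arange(11.0), np.arange(11.0) * 0.1)
        est = steady_state_response(s, (2.0, 8.0))
        assert est.mean_deg == pytest.approx(0.5)

    def test_noiseless_plateau_hits_rmax(self):
        params = LangmuirParameters(k_on=1e5, k_off=0.0, r_max=0.6)
        s = simulate_sensorgram(params, SCHEDULE, noise_sd=0.0)
        est = steady_state_response(s, (700.0, 779.0))
        assert est.mean_deg == pytest.approx(0.6, rel=1e-3)

    def test_window_outside_series_rejected(self):
        s = Sensorgram(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValidationError):
            steady_state_response(s, (5.0, 20.0))

    def test_window_too_few_samples(self):
        s = Sensorgram(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValidationError):
            steady_state_response(s, (4.9, 5.1))


class TestSimulate:
    def test_matches_closed_form_exactly_when_noiseless(self):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.0)
        expected = langmuir_curve(s.time, PARAMS, SCHEDULE)
        assert np.allclose(s.response, expected, atol=1e-12)

    def test_requested_r_eq_example(self):
        # k_on*C = 1, k_off = 1e-3 -> R_eq = 0.6/(1 + 1e-3)
        r_eq = 0.6 * 1.0 / (1.0 + 1e-3)
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.0)
        plateau = s.response[s.time == SCHEDULE.start_s + SCHEDULE.association_s - 1]
        assert plateau[0] == pytest.approx(r_eq, rel=1e-3)

    def test_deterministic_under_seed(self):
        a = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.01, seed=11)
        b = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.01, seed=11)
        assert np.array_equal(a.response, b.response)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=-0.1)

    def test_bounded_and_phase_monotone_noise_free(self):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.0)
        assert np.all(s.response >= -1e-15)
        assert np.all(s.response <= PARAMS.r_max + 1e-15)
        assoc_end = SCHEDULE.start_s + SCHEDULE.association_s
        assoc = s.response[(s.time >= SCHEDULE.start_s) & (s.time <= assoc_end)]
        diss = s.response[s.time >= assoc_end]
        assert np.all(np.diff(assoc) >= -1e-15)
        assert np.all(np.diff(diss) <= 1e-15)

    @settings(max_examples=25, deadline=None)
    @given(
        st.floats(1e2, 1e6),
        st.floats(0.0, 1e-2),
        st.floats(0.01, 2.0),
    )
    def test_bounded_for_random_kinetics(self, k_on, k_off, r_max):
        params = LangmuirParameters(k_on=k_on, k_off=k_off, r_max=r_max)
        s = simulate_sensorgram(params, SCHEDULE, noise_sd=0.0, sample_interval_s=5.0)
        assert np.all(s.response >= -1e-12)
        assert np.all(s.response <= r_max + 1e-12)


class TestFit:
    def test_noiseless_recovery(self):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.0)
        fit = fit_langmuir(s, SCHEDULE)
        assert fit.params.k_on == pytest.approx(PARAMS.k_on, rel=1e-3)
        assert fit.params.k_off == pytest.approx(PARAMS.k_off, rel=1e-3)
        assert fit.params.r_max == pytest.approx(PARAMS.r_max, rel=1e-3)
        assert not fit.low_signal

    def test_noisy_recovery_fixed_seed(self):
        s = simulate_sensorgram(PARAMS, SCHEDULE, noise_sd=0.02 * PARAMS.r_max, seed=5)
        fit = fit_langmuir(s, SCHEDULE)
        assert fit.params.k_on == pytest.approx(PARAMS.k_on, rel=0.05)
        assert fit.params.k_off == pytest.approx(PARAMS.k_off, rel=0.05)
        assert fit.params.r_max == pytest.approx(PARAMS.r_max, rel=0.05)

    def test_median_recovery_over_20_seeds(self):
        rel_errors = {"k_on": [], "k_off": [], "r_max": []}
        for seed in range(20):
            s = simulate_sensorgram(
                PARAMS, SCHEDULE, noise_sd=0.02 * PARAMS.r_max, seed=seed
            )
            fit = fit_langmuir(s, SCHEDULE)
            rel_errors["k_on"].append(abs(fit.params.k_on - PARAMS.k_on) / PARAMS.k_on)
            rel_errors["k_off"].append(
                abs(fit.params.k_off - PARAMS.k_off) / PARAMS.k_off
            )
            rel_errors["r_max"].append(
                abs(fit.params.r_max - PARAMS.r_max) / PARAMS.r_max
            )
        for name, errs in rel_errors.items():
            assert np.median(errs) < 0.05, f"{name} median error {np.median(errs):.3f}"

    def test_flat_zero_curve_flagged_low_signal(self):
        s = Sensorgram(np.arange(0.0, 960.0), np.zeros(960))
        fit = fit_langmuir(s, SCHEDULE)
        assert fit.low_signal
        assert fit.params.r_max == pytest.approx(0.0, abs=1e-6)


class TestValidation:
    def test_schedule_invariants(self):
        with pytest.raises(ValidationError):
            InjectionSchedule(0.0, -1.0, 10.0, 1e-6)
        with pytest.raises(ValidationError):
            InjectionSchedule(0.0, 10.0, 10.0, -1e-6)

    def test_sensorgram_monotone_time(self):
        with pytest.raises(ValidationError):
            Sensorgram(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            LangmuirParameters(-1.0, 0.0, 0.1)
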