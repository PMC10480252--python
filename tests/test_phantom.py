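"""Unit and property tests for the virtual-phantom generator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stenobench as sb
from stenobench.phantom import pressure_field

from conftest import FLOWS, NOISELESS, clean_config


# ---------------------------------------------------------------------------
# sensor array
# ---------------------------------------------------------------------------

class TestSensorArray:
    def test_default_layout(self):
        array = sb.SensorArray()
        assert array.positions_mm == (-30.0, 15.0, 30.0, 50.0, 75.0,
                                      100.0, 200.0, 500.0)
        assert array.channel_ids == tuple(range(1, 9))
        assert sum(x < 0 for x in array.positions_mm) == 1

    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            sb.SensorArray(positions_mm=(0.0, 10.0, 10.0))

    def test_channel_lookup(self):
        array = sb.SensorArray()
        assert array.index_of(1) == 0
        assert array.position_of(7) == 200.0
        with pytest.raises(KeyError):
            array.index_of(9)


# ---------------------------------------------------------------------------
# flow waveform
# ---------------------------------------------------------------------------

class TestFlowWaveform:
    @pytest.mark.parametrize("peak_flow", FLOWS)
    def test_pulsatile_period_and_peak(self, peak_flow):
        fs, n = 10_000.0, 50_000
        cond = sb.FlowCondition("pulsatile", peak_flow, 75.0)
        q = sb.generate_flow_waveform(cond, fs, n)
        period = int(fs * 60.0 / 75.0)  # 0.8 s
        # periodic with period 60/HR and non-negative
        np.testing.assert_allclose(q[period:], q[:-period], atol=1e-12)
        assert np.all(q >= 0.0)
        # peak equals peak_flow within one sample's discretisation
        assert q.max() <= peak_flow + 1e-12
        t_sys = 0.35 * 0.8
        dq_max = peak_flow * np.pi / t_sys / fs  # max change per sample
        assert q.max() >= peak_flow - dq_max
        # diastole carries no flow
        assert q[int(0.5 * period)] == 0.0

    def test_constant_mode(self):
        cond = sb.FlowCondition("constant", 100.0)
        q = sb.generate_flow_waveform(cond, 1000.0, 500)
        assert np.all(q == 100.0)

    def test_zero_flow_is_identically_zero(self):
        cond = sb.FlowCondition("pulsatile", 0.0, 75.0)
        assert not np.any(sb.generate_flow_waveform(cond, 1000.0, 2000))

    def test_invalid_conditions_rejected(self):
        with pytest.raises(ValueError):
            sb.FlowCondition("pulsatile", -1.0, 75.0)
        with pytest.raises(ValueError):
            sb.FlowCondition("pulsatile", 100.0, None)
        with pytest.raises(ValueError):
            sb.FlowCondition("steady", 100.0)


# ---------------------------------------------------------------------------
# simplified Bernoulli
# ---------------------------------------------------------------------------

class TestBernoulli:
    @pytest.mark.parametrize("v,expected", [(2.5, 25.0), (0.0, 0.0), (1.0, 4.0)])
    def test_known_values(self, v, expected):
        assert sb.bernoulli_drop(v) == pytest.approx(expected)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            sb.bernoulli_drop(-0.1)


# ---------------------------------------------------------------------------
# pressure field
# ---------------------------------------------------------------------------

class TestPressureField:
    def test_quasi_steady_vena_contracta_drop(self):
        # Q = 250 ml/s through EOA = 1.018 cm2: v = 2.456 m/s, 4 v^2 = 24.1
        config = clean_config(n_samples=100)
        flow = np.full(100, 250.0)
        pressures, truth = pressure_field(flow, config)
        v = 250e-6 / (1.018e-4)
        expected = 4.0 * v**2
        i_vc = config.sensor_array.index_of(3)  # +30 mm, inside jet plateau
        pulse = (config.upstream_baseline_pressure_mmhg
                 + config.afterload_resistance_mmhg_per_ml_s * 250.0)
        drop = pulse - pressures[-1, i_vc]
        assert drop == pytest.approx(expected, rel=1e-9)
        assert truth.true_peak_drop_mmhg == pytest.approx(expected, rel=1e-9)

    def test_half_area_orifice_recovers_half_the_drop(self):
        # r = 0.5 gives 1 - 2 r (1 - r) = 0.5 exactly
        config = clean_config(valve_eoa_cm2=0.5 * sb.PhantomConfig().tube_area_cm2)
        flow = np.full(64, 200.0)
        _, truth = pressure_field(flow, config)
        assert truth.true_net_drop_mmhg == pytest.approx(
            0.5 * truth.true_peak_drop_mmhg
        )

    def test_zero_flow_leaves_baseline_everywhere(self):
        config = clean_config(n_samples=64)
        pressures, truth = pressure_field(np.zeros(64), config)
        np.testing.assert_allclose(
            pressures, config.upstream_baseline_pressure_mmhg
        )
        assert truth.true_peak_drop_mmhg == 0.0

    def test_no_stenosis_rejected(self):
        area = sb.PhantomConfig().tube_area_cm2
        with pytest.raises(ValueError, match="EOA"):
            clean_config(valve_eoa_cm2=area * 1.01)

    def test_spatial_recovery_complete_by_200mm(self):
        # noiseless drops at +200 and +500 mm agree to < 1%
        config = clean_config(n_samples=64)
        pressures, _ = pressure_field(np.full(64, 250.0), config)
        i7 = config.sensor_array.index_of(7)
        i8 = config.sensor_array.index_of(8)
        pulse = pressures[0, 0]
        d7 = pulse - pressures[0, i7]
        d8 = pulse - pressures[0, i8]
        assert abs(d7 - d8) / d7 < 0.01

    def test_ground_truth_monotone_in_flow(self):
        config = clean_config(n_samples=2000)
        cond = [sb.FlowCondition("pulsatile", q, 75.0) for q in FLOWS]
        peaks = []
        for c in cond:
            flow = sb.generate_flow_waveform(c, config.sampling_rate_hz,
                                             config.n_samples)
            _, truth = pressure_field(flow, config)
            peaks.append(truth.true_peak_drop_mmhg)
        assert np.all(np.diff(peaks) > 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=st.floats(min_value=0.01, max_value=0.99))
    def test_recovery_fraction_bounds(self, r):
        # net/peak = 1 - 2 r (1 - r) lies in [0.5, 1) for r in (0, 1),
        # with its minimum 0.5 at r = 0.5
        f = 1.0 - 2.0 * r * (1.0 - r)
        assert 0.5 <= f < 1.0


# ---------------------------------------------------------------------------
# wave reflection
# ---------------------------------------------------------------------------

class TestWaveReflection:
    def test_zero_gamma_is_identity(self):
        config = clean_config(reflection_coefficient=0.0, n_samples=512)
        pressures = np.random.default_rng(0).normal(size=(512, 8))
        out = sb.add_wave_reflection(pressures, config)
        np.testing.assert_array_equal(out, pressures)

    def test_gaussian_pulse_gains_delayed_echo(self):
        # a single Gaussian pulse at channel 7 (x = +200 mm) must reappear
        # scaled by Gamma after the round-trip delay 2 (site - x) / c
        fs, n = 4000.0, 8192
        config = sb.fast_config(
            reflection_coefficient=0.3, wave_speed_m_s=10.0,
            reflection_site_mm=600.0, sampling_rate_hz=fs, n_samples=n,
            **NOISELESS,
        )
        t = np.arange(n) / fs
        t0, sigma = 0.5, 0.02
        pulse = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        pressures = np.full((n, 8), config.upstream_baseline_pressure_mmhg)
        i7 = config.sensor_array.index_of(7)
        pressures[:, i7] += pulse
        out = sb.add_wave_reflection(pressures, config)
        echo = out[:, i7] - pressures[:, i7]
        tau = 2.0 * (600.0 - 200.0) / (10.0 * 1000.0)  # 0.08 s
        expected_centre = t0 + tau
        assert abs(t[np.argmax(echo)] - expected_centre) <= 1.0 / fs
        assert echo.max() == pytest.approx(0.3, rel=1e-6)

    def test_amplifying_reflection_rejected(self):
        with pytest.raises(ValueError):
            clean_config(reflection_coefficient=1.0)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

class TestNoise:
    def test_zero_amplitudes_are_identity(self):
        config = clean_config(n_samples=1024)
        cond = sb.FlowCondition("pulsatile", 250.0, 75.0)
        flow = sb.generate_flow_waveform(cond, config.sampling_rate_hz, 1024)
        pressures = np.zeros((1024, 8))
        out = sb.add_noise(pressures, flow, config, cond,
                           np.random.default_rng(0))
        np.testing.assert_array_equal(out, pressures)

    def test_noise_localised_near_valve(self):
        # residual variance at channels 2-3 (closest to the jet) exceeds
        # channel 8 (+500 mm) over >= 4 cycles
        config = sb.fast_config(rng_seed=5)
        cond = sb.FlowCondition("pulsatile", 250.0, 75.0)
        flow = sb.generate_flow_waveform(cond, config.sampling_rate_hz,
                                         config.n_samples)
        clean, _ = pressure_field(flow, config)
        noisy = sb.add_noise(clean, flow, config, cond,
                             np.random.default_rng(5))
        resid_var = (noisy - clean).var(axis=0)
        array = config.sensor_array
        for ch in (2, 3):
            assert resid_var[array.index_of(ch)] > resid_var[array.index_of(8)]

    def test_constant_flow_turbulence_scale_factor(self):
        # the near-valve turbulence amplitude is multiplied by the
        # configured factor (default 3x) under constant flow
        base = dict(noise_broadband_sd_mmhg=0.0,
                    pump_artifact_amplitude_mmhg=0.0, n_samples=8000)
        cond = sb.FlowCondition("constant", 250.0)
        sds = {}
        for factor in (1.0, 3.0):
            config = sb.fast_config(turbulence_constant_factor=factor, **base)
            flow = sb.generate_flow_waveform(cond, config.sampling_rate_hz,
                                             config.n_samples)
            clean, _ = pressure_field(flow, config)
            noisy = sb.add_noise(clean, flow, config, cond,
                                 np.random.default_rng(7))
            i2 = config.sensor_array.index_of(2)
            sds[factor] = (noisy - clean)[:, i2].std()
        assert sds[3.0] / sds[1.0] == pytest.approx(3.0, rel=0.05)

    def test_constant_flow_noisier_than_pulsatile_near_valve(self):
        base = dict(noise_broadband_sd_mmhg=0.0,
                    pump_artifact_amplitude_mmhg=0.0)
        resid = {}
        for mode in ("constant", "pulsatile"):
            config = sb.fast_config(**base)
            cond = sb.FlowCondition(mode, 250.0, 75.0)
            flow = sb.generate_flow_waveform(cond, config.sampling_rate_hz,
                                             config.n_samples)
            clean, _ = pressure_field(flow, config)
            noisy = sb.add_noise(clean, flow, config, cond,
                                 np.random.default_rng(11))
            i2 = config.sensor_array.index_of(2)
            resid[mode] = (noisy - clean)[:, i2].var()
        assert resid["constant"] > resid["pulsatile"]


# ---------------------------------------------------------------------------
# condition / session perturbations
# ---------------------------------------------------------------------------

class TestPerturbations:
    def test_condition_1_session_a_is_identity(self):
        config = sb.fast_config()
        out = sb.apply_condition_perturbation(
            config, 1, "A", np.random.default_rng(3)
        )
        assert out == config

    def test_deterministic_under_fixed_seed(self):
        config = sb.fast_config()
        a = sb.apply_condition_perturbation(config, 4, "A",
                                            np.random.default_rng(42))
        b = sb.apply_condition_perturbation(config, 4, "A",
                                            np.random.default_rng(42))
        assert a == b

    @pytest.mark.parametrize("peak_flow", FLOWS)
    def test_session_b_increases_obstruction(self, peak_flow):
        # day bias: EOA x 0.96 means a strictly larger ground-truth drop
        config = clean_config(n_samples=2000)
        cond = sb.FlowCondition("pulsatile", peak_flow, 75.0)
        flow = sb.generate_flow_waveform(cond, config.sampling_rate_hz, 2000)
        truths = {}
        for session in ("A", "B"):
            cfg = sb.apply_condition_perturbation(
                config, 1, session, np.random.default_rng(0)
            )
            _, truths[session] = pressure_field(flow, cfg)
        assert truths["B"].true_peak_drop_mmhg > truths["A"].true_peak_drop_mmhg

    def test_zero_offset_day_bias_mode(self):
        scales = sb.PerturbationScales(session_b_mode="zero_offset")
        config = sb.fast_config()
        out = sb.apply_condition_perturbation(
            config, 1, "B", np.random.default_rng(0), scales
        )
        assert out.valve_eoa_cm2 == config.valve_eoa_cm2
        assert out.channel_offsets_mmhg[0] == pytest.approx(
            scales.session_b_offset_mmhg
        )

    def test_unknown_labels_rejected(self):
        config = sb.fast_config()
        with pytest.raises(ValueError):
            sb.apply_condition_perturbation(config, 5, "A",
                                            np.random.default_rng(0))
        with pytest.raises(ValueError):
            sb.apply_condition_perturbation(config, 1, "C",
                                            np.random.default_rng(0))


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

class TestSimulateRecording:
    def test_default_recording_shape_and_span(self):
        rec = sb.simulate_recording(
            sb.PhantomConfig(), sb.FlowCondition("pulsatile", 250.0, 75.0)
        )
        assert rec.pressures_mmhg.shape == (50_000, 8)
        n_cycles = rec.time_s[-1] / 0.8
        assert n_cycles >= 5.0

    def test_bit_identical_under_same_seed(self):
        cfg = sb.fast_config(rng_seed=99)
        cond = sb.FlowCondition("pulsatile", 200.0, 75.0)
        a = sb.simulate_recording(cfg, cond)
        b = sb.simulate_recording(cfg, cond)
        np.testing.assert_array_equal(a.pressures_mmhg, b.pressures_mmhg)

    def test_different_seeds_differ(self):
        cond = sb.FlowCondition("pulsatile", 200.0, 75.0)
        a = sb.simulate_recording(sb.fast_config(rng_seed=1), cond)
        b = sb.simulate_recording(sb.fast_config(rng_seed=2), cond)
        assert not np.array_equal(a.pressures_mmhg, b.pressures_mmhg)

    def test_zero_constant_flow_yields_zero_metrics(self):
        rec = sb.simulate_recording(
            clean_config(n_samples=4000), sb.FlowCondition("constant", 0.0)
        )
        m = sb.analyze_recording(rec)
        assert m.peak_drop_mmhg == pytest.approx(0.0, abs=1e-9)
        assert m.net_drop_mmhg == pytest.approx(0.0, abs=1e-9)

    def test_net_never_exceeds_peak_in_ground_truth(self, clean_sweep):
        for (_, _), (_, truth) in clean_sweep.items():
            assert truth.true_net_drop_mmhg <= truth.true_peak_drop_mmhg
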