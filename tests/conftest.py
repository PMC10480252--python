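import numpy as np
import pytest

import stenobench as sb

#: overrides that switch off every stochastic disturbance
NOISELESS = dict(
    noise_broadband_sd_mmhg=0.0,
    turbulence_noise_amplitude_mmhg=0.0,
    pump_artifact_amplitude_mmhg=0.0,
)

FLOWS = (100.0, 150.0, 200.0, 250.0)


def clean_config(**overrides):
    """Reduced-size phantom with zero noise and no wave reflection."""
    params = dict(reflection_coefficient=0.0, **NOISELESS)
    params.update(overrides)
    return sb.fast_config(**params)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free, reflection-free pulsatile recording at 250 ml/s."""
    return sb.simulate_recording(
        clean_config(), sb.FlowCondition("pulsatile", 250.0)
    )


@pytest.fixture(scope="session")
def clean_sweep():
    """Extracted metrics + ground truth for 4 flow rates x 2 modes,
    noise-free and reflection-free."""
    out = {}
    for mode in ("pulsatile", "constant"):
        for q in FLOWS:
            rec = sb.simulate_recording(
                clean_config(), sb.FlowCondition(mode, q)
            )
            out[(mode, q)] = (sb.analyze_recording(rec), rec.ground_truth)
    return out


def synthetic_recording(pressures, fs=4000.0, mode="pulsatile",
                        peak_flow=250.0, positions=None):
    """Wrap a raw pressure matrix in a SensorRecording for pipeline tests."""
    pressures = np.asarray(pressures, dtype=float)
    n, c = pressures.shape
    array = (
        sb.SensorArray() if positions is None
        else sb.SensorArray(positions_mm=tuple(positions))
    )
    return sb.SensorRecording(
        time_s=np.arange(n) / fs,
        pressures_mmhg=pressures,
        sensor_array=array,
        condition=sb.FlowCondition(mode, peak_flow, 75.0),
        sampling_rate_hz=fs,
    )
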