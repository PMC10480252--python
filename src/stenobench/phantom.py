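"""Virtual aortic-stenosis flow phantom.

This module generates synthetic multi-channel pressure recordings with the
statistical and physical structure of a mock circulatory loop built around a
stenotic (or healthy) aortic valve mounted in a straight compliant tube:

* a pulsatile (or constant) volumetric flow waveform driven by a piston pump
  through a non-return valve;
* a one-dimensional parametric pressure field along the tube axis — a common
  driving pulse, a Bernoulli-type drop at the vena contracta with an
  inertial (unsteady) component, and exponential downstream pressure
  recovery toward the net (irreversible) drop;
* a backward-travelling wave reflected from the distal tube end, which
  augments and time-shifts the pressure peaks of downstream channels;
* measurement noise: broadband sensor noise, turbulence noise localised
  near the valve, and short high-frequency pump artifacts at the steepest
  and highest points of the pressure pulse;
* between-session/condition perturbations (afterload change, valve
  remounting, valve-to-valve variability, day bias) for test-retest
  experiments.

Every recording carries the noiseless ground-truth pressure drops, so the
downstream metric-extraction pipeline can be validated by parameter
recovery.

Units are mmHg, ml/s, mm and seconds throughout; the single conversion
constant is ``PA_PER_MMHG`` (1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: 1 mmHg expressed in pascal.  The only pressure-unit conversion used.
PA_PER_MMHG = 133.322

#: Default axial sensor positions in mm relative to the valve plane
#: (negative = upstream).  One upstream channel, seven downstream.
DEFAULT_POSITIONS_MM = (-30.0, 15.0, 30.0, 50.0, 75.0, 100.0, 200.0, 500.0)

#: Fraction of the cardiac cycle occupied by systolic ejection.
SYSTOLIC_FRACTION = 0.35


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorArray:
    """Axial positions (mm from the valve) and 1-based channel labels."""

    positions_mm: tuple = DEFAULT_POSITIONS_MM
    channel_ids: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        positions = tuple(float(x) for x in self.positions_mm)
        object.__setattr__(self, "positions_mm", positions)
        ids = self.channel_ids
        if ids is None:
            ids = tuple(range(1, len(positions) + 1))
        ids = tuple(int(i) for i in ids)
        object.__setattr__(self, "channel_ids", ids)
        if len(ids) != len(positions):
            raise ValueError(
                f"{len(ids)} channel ids for {len(positions)} positions"
            )
        diffs = np.diff(positions)
        if len(positions) and np.any(diffs <= 0):
            raise ValueError("sensor positions must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.positions_mm)

    def index_of(self, channel_id: int) -> int:
        """Column index of a 1-based channel label."""
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no channel with id {channel_id}") from None

    def position_of(self, channel_id: int) -> float:
        return self.positions_mm[self.index_of(channel_id)]


@dataclass(frozen=True)
class FlowCondition:
    """Pump regimen: mode, peak volumetric flow rate and heart rate."""

    mode: str  # "pulsatile" | "constant"
    peak_flow_ml_s: float
    heart_rate_bpm: Optional[float] = 75.0

    def __post_init__(self):
        if self.mode not in ("pulsatile", "constant"):
            raise ValueError(f"unknown flow mode {self.mode!r}")
        if self.peak_flow_ml_s < 0:
            raise ValueError("peak flow must be non-negative")
        if self.mode == "pulsatile":
            if self.heart_rate_bpm is None or self.heart_rate_bpm <= 0:
                raise ValueError("pulsatile mode requires heart_rate_bpm > 0")

    @property
    def period_s(self) -> Optional[float]:
        """Cardiac cycle length in seconds (None for constant flow)."""
        if self.mode != "pulsatile":
            return None
        return 60.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, valve, recovery, reflection, noise and fluid parameters.

    Defaults describe the healthy-valve straight-tube circuit: 32 mm i.d.
    silicone tube, water/glycerol blood-mimicking fluid, an effective
    orifice area of 1.018 cm2 with the vena contracta 25 mm downstream of
    the valve plane, and 50 000 samples at 10 kHz per channel.
    """

    sensor_array: SensorArray = field(default_factory=SensorArray)
    tube_internal_diameter_mm: float = 32.0
    fluid_density_g_cm3: float = 1.119
    fluid_viscosity_pa_s: float = 4.83e-3
    valve_eoa_cm2: float = 1.018
    vena_contracta_position_mm: float = 25.0
    jet_length_mm: float = 10.0
    recovery_length_mm: float = 35.0
    recovery_efficiency: float = 1.0
    upstream_baseline_pressure_mmhg: float = 5.0
    afterload_resistance_mmhg_per_ml_s: float = 0.16
    inertial_coefficient: float = 1.0
    effective_jet_length_mm: float = 30.0
    reflection_coefficient: float = 0.3
    reflection_site_mm: float = 600.0
    wave_speed_m_s: float = 10.0
    noise_broadband_sd_mmhg: float = 0.1
    turbulence_noise_amplitude_mmhg: float = 0.5
    turbulence_decay_length_mm: float = 30.0
    turbulence_constant_factor: float = 3.0
    turbulence_ref_velocity_m_s: float = 2.5
    pump_artifact_amplitude_mmhg: float = 0.3
    pump_artifact_freq_hz: float = 120.0
    pump_artifact_width_s: float = 0.005
    channel_offsets_mmhg: Optional[tuple] = None
    sampling_rate_hz: float = 10_000.0
    n_samples: int = 50_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.tube_internal_diameter_mm <= 0:
            raise ValueError("tube diameter must be positive")
        if not 0 < self.valve_eoa_cm2 < self.tube_area_cm2:
            raise ValueError(
                "valve EOA must be positive and smaller than the tube "
                f"cross-section ({self.tube_area_cm2:.3f} cm2)"
            )
        if not 0.0 <= self.reflection_coefficient < 1.0:
            raise ValueError("reflection coefficient must lie in [0, 1)")
        if self.sampling_rate_hz <= 0 or self.n_samples <= 0:
            raise ValueError("sampling rate and sample count must be positive")
        if self.recovery_length_mm <= 0:
            raise ValueError("recovery length must be positive")
        if self.channel_offsets_mmhg is not None:
            offs = tuple(float(o) for o in self.channel_offsets_mmhg)
            if len(offs) != self.sensor_array.n_channels:
                raise ValueError("one pressure offset per channel required")
            object.__setattr__(self, "channel_offsets_mmhg", offs)

    @property
    def tube_area_cm2(self) -> float:
        """Tube cross-sectional area pi d^2 / 4 in cm2."""
        d_cm = self.tube_internal_diameter_mm / 10.0
        return np.pi * d_cm**2 / 4.0

    @property
    def area_ratio(self) -> float:
        """r = EOA / tube area, the contraction ratio of the jet."""
        return self.valve_eoa_cm2 / self.tube_area_cm2

    @property
    def recovery_fraction(self) -> float:
        """Fraction of the vena-contracta drop that is irreversible.

        Standard orifice pressure-recovery relation 1 - 2 r (1 - r) with
        r = EOA / A, scaled by ``recovery_efficiency`` (1.0 = ideal
        recovery law; < 1 emulates extra distal losses, > 1 poorer
        recovery than the law predicts).
        """
        r = self.area_ratio
        return (1.0 - 2.0 * r * (1.0 - r)) * self.recovery_efficiency


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless reference values attached to a synthetic recording."""

    true_peak_drop_mmhg: float
    true_net_drop_mmhg: float
    true_peak_instant_s: float
    true_peak_location_mm: float
    flow_waveform_ml_s: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.true_peak_drop_mmhg < 0 or self.true_net_drop_mmhg < 0:
            raise ValueError("ground-truth drops must be non-negative")
        if self.true_net_drop_mmhg > self.true_peak_drop_mmhg * (1 + 1e-12):
            raise ValueError("net drop cannot exceed peak drop")


@dataclass
class SensorRecording:
    """Raw time-by-channel pressure traces plus acquisition metadata."""

    time_s: np.ndarray
    pressures_mmhg: np.ndarray  # [n_samples, n_channels]
    sensor_array: SensorArray
    condition: FlowCondition
    sampling_rate_hz: float
    ground_truth: Optional[GroundTruth] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressures_mmhg = np.asarray(self.pressures_mmhg, dtype=float)
        n, c = self.pressures_mmhg.shape
        if self.time_s.shape != (n,):
            raise ValueError("time vector and pressure matrix disagree")
        if c != self.sensor_array.n_channels:
            raise ValueError(
                f"{c} pressure channels but {self.sensor_array.n_channels} "
                "sensor positions"
            )

    @property
    def n_samples(self) -> int:
        return self.pressures_mmhg.shape[0]

    def channel(self, channel_id: int) -> np.ndarray:
        return self.pressures_mmhg[:, self.sensor_array.index_of(channel_id)]


# ---------------------------------------------------------------------------
# elementary physics
# ---------------------------------------------------------------------------

def bernoulli_drop(velocity_m_s):
    """Simplified Bernoulli pressure drop, mmHg, for a jet velocity in m/s.

    The clinical rule dP = 4 v^2 (v in m/s, dP in mmHg), i.e. the convective
    Bernoulli term 1/2 rho v^2 for blood-like density expressed in mmHg.
    """
    v = np.asarray(velocity_m_s, dtype=float)
    if np.any(v < 0):
        raise ValueError("jet velocity must be non-negative")
    out = 4.0 * v**2
    return float(out) if np.isscalar(velocity_m_s) else out


def generate_flow_waveform(
    condition: FlowCondition,
    sampling_rate_hz: float,
    n_samples: int,
    systolic_fraction: float = SYSTOLIC_FRACTION,
) -> np.ndarray:
    """Volumetric flow trace (ml/s) for a pump regimen.

    Pulsatile mode is a periodic half-period raised-cosine systole (a
    progressive upstroke to ``peak_flow`` followed by a symmetric decay)
    occupying ``systolic_fraction`` of the cycle, with zero diastolic flow —
    the non-return valve clips any backflow at zero.  Constant mode returns
    ``peak_flow`` at every sample.
    """
    if condition.peak_flow_ml_s < 0:
        raise ValueError("peak flow must be non-negative")
    t = np.arange(n_samples) / sampling_rate_hz
    if condition.mode == "constant":
        return np.full(n_samples, condition.peak_flow_ml_s, dtype=float)
    period = condition.period_s
    if period is None:
        raise ValueError("pulsatile mode requires a heart rate")
    t_sys = systolic_fraction * period
    tc = np.mod(t, period)
    q = np.where(
        tc < t_sys,
        condition.peak_flow_ml_s * 0.5 * (1.0 - np.cos(2.0 * np.pi * tc / t_sys)),
        0.0,
    )
    return np.clip(q, 0.0, None)


# ---------------------------------------------------------------------------
# pressure field
# ---------------------------------------------------------------------------

def _drop_weights(x_mm: float, config: PhantomConfig):
    """Spatial weights (w_vc, w_net) such that drop(x) = w_vc*dP_vc + w_net*dP_net.

    Upstream of the valve there is no drop; the drop builds linearly from
    the valve plane to the vena contracta, holds over a short jet plateau,
    then relaxes exponentially toward the fully recovered (net) level.
    """
    x_vc = config.vena_contracta_position_mm
    onset = x_vc + config.jet_length_mm
    if x_mm <= 0.0:
        return 0.0, 0.0
    if x_mm < x_vc:
        return x_mm / x_vc, 0.0
    if x_mm <= onset:
        return 1.0, 0.0
    e = np.exp(-(x_mm - onset) / config.recovery_length_mm)
    return e, 1.0 - e


def pressure_field(flow_ml_s: np.ndarray, config: PhantomConfig):
    """Noiseless pressure matrix [n, n_channels] plus ground truth.

    At each instant the upstream channels carry the driving pulse
    (baseline + afterload resistance x flow).  The drop at the vena
    contracta is the simplified Bernoulli term 4 v(t)^2 plus an inertial
    (unsteady) term K rho L_eff dv/dt; with v(t) = Q(t)/EOA.  Downstream,
    the drop relaxes exponentially toward the net drop
    dP_net = dP_vc (1 - 2 r (1 - r)), r = EOA/A.  The inertial term is
    identically zero under constant flow (dv/dt = 0), so constant-flow
    fields are quasi-steady automatically.
    """
    flow = np.asarray(flow_ml_s, dtype=float)
    fs = config.sampling_rate_hz
    # jet velocity in m/s: Q [ml/s -> m3/s] / EOA [cm2 -> m2]
    v = flow * 1e-6 / (config.valve_eoa_cm2 * 1e-4)
    dp_conv = 4.0 * v**2
    rho_si = config.fluid_density_g_cm3 * 1000.0  # kg/m3
    l_eff_m = config.effective_jet_length_mm * 1e-3
    dvdt = np.gradient(v, 1.0 / fs) if flow.size > 1 else np.zeros_like(v)
    dp_inert = (
        config.inertial_coefficient * rho_si * l_eff_m * dvdt / PA_PER_MMHG
    )
    dp_vc = dp_conv + dp_inert
    dp_net = dp_vc * config.recovery_fraction

    pulse = (
        config.upstream_baseline_pressure_mmhg
        + config.afterload_resistance_mmhg_per_ml_s * flow
    )
    n_ch = config.sensor_array.n_channels
    pressures = np.empty((flow.size, n_ch))
    for j, x in enumerate(config.sensor_array.positions_mm):
        w_vc, w_net = _drop_weights(x, config)
        pressures[:, j] = pulse - w_vc * dp_vc - w_net * dp_net

    i_peak = int(np.argmax(dp_vc))
    truth = GroundTruth(
        true_peak_drop_mmhg=float(max(dp_vc[i_peak], 0.0)),
        true_net_drop_mmhg=float(max(dp_net[i_peak], 0.0)),
        true_peak_instant_s=i_peak / fs,
        true_peak_location_mm=config.vena_contracta_position_mm,
        flow_waveform_ml_s=flow.copy(),
    )
    return pressures, truth


def add_wave_reflection(
    pressures_mmhg: np.ndarray,
    config: PhantomConfig,
    period_samples: Optional[int] = None,
) -> np.ndarray:
    """Superpose a backward wave reflected from the distal tube end.

    At a downstream position x the reflected component is
    Gamma x (forward pressure deviation from baseline) delayed by the
    round-trip time 2 (x_site - x) / c.  The upstream channel sits behind
    the valve and is shielded from the backward wave.  For pulsatile
    recordings the forward wave is treated as periodic (steady-state pump
    operation), so pre-recording samples are taken one cycle later in
    phase; for constant flow the leading edge is held.

    With Gamma > 0 the pressure peaks of distal channels are augmented and
    time-shifted relative to the no-reflection field — the mechanism that
    confounds the peak-to-peak pressure drop.
    """
    gamma = config.reflection_coefficient
    if not 0.0 <= gamma < 1.0:
        raise ValueError("reflection coefficient must lie in [0, 1)")
    out = np.array(pressures_mmhg, dtype=float, copy=True)
    if gamma == 0.0:
        return out
    fs = config.sampling_rate_hz
    n = out.shape[0]
    baseline = config.upstream_baseline_pressure_mmhg
    c_mm_s = config.wave_speed_m_s * 1000.0
    for j, x in enumerate(config.sensor_array.positions_mm):
        if x <= 0.0 or x >= config.reflection_site_mm:
            continue
        tau = 2.0 * (config.reflection_site_mm - x) / c_mm_s
        shift = int(round(tau * fs))
        if shift == 0:
            out[:, j] += gamma * (pressures_mmhg[:, j] - baseline)
            continue
        idx = np.arange(n) - shift
        neg = idx < 0
        if period_samples:
            idx[neg] = idx[neg] % period_samples
        else:
            idx[neg] = 0
        out[:, j] += gamma * (pressures_mmhg[idx, j] - baseline)
    return out


def add_noise(
    pressures_mmhg: np.ndarray,
    flow_ml_s: np.ndarray,
    config: PhantomConfig,
    condition: FlowCondition,
    rng: np.random.Generator,
) -> np.ndarray:
    """Measurement noise: broadband + valve-proximal turbulence + pump bursts.

    (i) iid Gaussian noise on every channel (sensor/electronics floor);
    (ii) turbulence noise with standard deviation
    amplitude x exp(-|x - x_vc| / decay) x (v(t)/v_ref)^2, multiplied by
    ``turbulence_constant_factor`` under constant flow, where turbulence
    has time to fully develop; (iii) pulsatile only: a short high-frequency
    burst at the instants of peak dp/dt and peak pressure of each cycle
    (limited pump power), identical on all channels.

    Zero amplitudes give the identity; all randomness comes from ``rng``.
    """
    out = np.array(pressures_mmhg, dtype=float, copy=True)
    n, n_ch = out.shape
    fs = config.sampling_rate_hz

    if config.noise_broadband_sd_mmhg > 0:
        out += rng.normal(0.0, config.noise_broadband_sd_mmhg, size=(n, n_ch))

    if config.turbulence_noise_amplitude_mmhg > 0:
        v = np.asarray(flow_ml_s) * 1e-6 / (config.valve_eoa_cm2 * 1e-4)
        mod = (v / config.turbulence_ref_velocity_m_s) ** 2
        amp = config.turbulence_noise_amplitude_mmhg * np.exp(
            -np.abs(np.asarray(config.sensor_array.positions_mm)
                    - config.vena_contracta_position_mm)
            / config.turbulence_decay_length_mm
        )
        if condition.mode == "constant":
            amp = amp * config.turbulence_constant_factor
        out += rng.normal(size=(n, n_ch)) * mod[:, None] * amp[None, :]

    if (
        condition.mode == "pulsatile"
        and config.pump_artifact_amplitude_mmhg > 0
    ):
        t = np.arange(n) / fs
        period_samples = int(round(fs * condition.period_s))
        dqdt = np.gradient(np.asarray(flow_ml_s, dtype=float), 1.0 / fs)
        centres = []
        start = 0
        while start + period_samples <= n:
            sl = slice(start, start + period_samples)
            centres.append(start + int(np.argmax(dqdt[sl])))
            centres.append(start + int(np.argmax(flow_ml_s[sl])))
            start += period_samples
        sigma = config.pump_artifact_width_s
        f_hf = config.pump_artifact_freq_hz
        burst = np.zeros(n)
        for ci in centres:
            lo = max(0, ci - int(6 * sigma * fs))
            hi = min(n, ci + int(6 * sigma * fs))
            dt = t[lo:hi] - ci / fs
            burst[lo:hi] += (
                config.pump_artifact_amplitude_mmhg
                * np.exp(-0.5 * (dt / sigma) ** 2)
                * np.sin(2.0 * np.pi * f_hf * dt)
            )
        out += burst[:, None]
    return out


# ---------------------------------------------------------------------------
# between-session / condition perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationScales:
    """Magnitudes of the experimental-handling perturbations.

    Condition 1 is the untouched baseline.  Condition 2 (purge and refill,
    lifting and percussing the tubing) perturbs the afterload: baseline
    pressure, reflection coefficient, effective reflection site and the
    efficiency of distal pressure recovery.  Condition 3 (dismantle,
    remove and remount the same valve) additionally jitters the vena
    contracta position and the mounted EOA.  Condition 4 (a second,
    nominally identical valve) adds a valve-manufacture EOA offset.
    Session B applies a systematic day effect, by default a small EOA
    reduction (increased obstruction); an additive per-channel zeroing
    offset is available as the alternative day-bias mechanism.

    All jitters are uniform on +/- the stated half-width; fractional
    fields are relative, *_mm fields absolute.
    """

    baseline_frac: float = 0.05
    reflection_frac: float = 0.05
    reflection_site_mm: float = 100.0
    recovery_frac: float = 0.06
    vc_position_mm: float = 3.0
    eoa_remount_frac: float = 0.02
    eoa_valve_frac: float = 0.03
    session_b_mode: str = "eoa"  # "eoa" | "zero_offset"
    session_b_eoa_factor: float = 0.96
    session_b_offset_mmhg: float = 0.3


def apply_condition_perturbation(
    config: PhantomConfig,
    condition_label: int,
    session: str,
    rng: np.random.Generator,
    scales: Optional[PerturbationScales] = None,
) -> PhantomConfig:
    """Perturbed copy of ``config`` for one experimental handling condition.

    ``condition_label`` is 1-4 (see :class:`PerturbationScales`);
    ``session`` is "A" or "B".  Seven uniform draws are always consumed
    from ``rng`` in a fixed order (baseline, reflection coefficient,
    reflection site, recovery efficiency, vena contracta position, EOA
    remount, EOA valve), so streams stay aligned across condition labels.
    """
    if condition_label not in (1, 2, 3, 4):
        raise ValueError(f"unknown condition label {condition_label!r}")
    if session not in ("A", "B"):
        raise ValueError(f"unknown session {session!r}")
    s = scales or PerturbationScales()
    u = rng.uniform(-1.0, 1.0, size=7)

    changes: dict = {}
    eoa = config.valve_eoa_cm2
    if condition_label >= 2:
        changes["upstream_baseline_pressure_mmhg"] = (
            config.upstream_baseline_pressure_mmhg * (1.0 + s.baseline_frac * u[0])
        )
        gamma = config.reflection_coefficient * (1.0 + s.reflection_frac * u[1])
        changes["reflection_coefficient"] = float(np.clip(gamma, 0.0, 0.95))
        changes["reflection_site_mm"] = (
            config.reflection_site_mm + s.reflection_site_mm * u[2]
        )
        changes["recovery_efficiency"] = (
            config.recovery_efficiency * (1.0 + s.recovery_frac * u[3])
        )
    if condition_label >= 3:
        changes["vena_contracta_position_mm"] = (
            config.vena_contracta_position_mm + s.vc_position_mm * u[4]
        )
        eoa = eoa * (1.0 + s.eoa_remount_frac * u[5])
    if condition_label == 4:
        eoa = eoa * (1.0 + s.eoa_valve_frac * u[6])
    if session == "B":
        if s.session_b_mode == "eoa":
            eoa = eoa * s.session_b_eoa_factor
        elif s.session_b_mode == "zero_offset":
            offsets = list(config.channel_offsets_mmhg
                           or (0.0,) * config.sensor_array.n_channels)
            offsets[0] += s.session_b_offset_mmhg  # re-zeroed upstream sensor
            changes["channel_offsets_mmhg"] = tuple(offsets)
        else:
            raise ValueError(f"unknown session-B mode {s.session_b_mode!r}")
    if eoa != config.valve_eoa_cm2:
        changes["valve_eoa_cm2"] = eoa
    return replace(config, **changes) if changes else config


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def simulate_recording(
    config: PhantomConfig,
    condition: FlowCondition,
    provenance: Optional[dict] = None,
) -> SensorRecording:
    """Full simulation: flow -> pressure field -> reflection -> noise.

    The returned recording carries the noiseless ground truth and a
    provenance dictionary (seed, condition labels, ...).
    """
    fs = config.sampling_rate_hz
    n = config.n_samples
    rng = np.random.default_rng(config.rng_seed)

    flow = generate_flow_waveform(condition, fs, n)
    pressures, truth = pressure_field(flow, config)
    period_samples = (
        int(round(fs * condition.period_s))
        if condition.mode == "pulsatile"
        else None
    )
    pressures = add_wave_reflection(pressures, config, period_samples)
    pressures = add_noise(pressures, flow, config, condition, rng)
    if config.channel_offsets_mmhg is not None:
        pressures = pressures + np.asarray(config.channel_offsets_mmhg)[None, :]

    meta = {"seed": config.rng_seed, "mode": condition.mode,
            "peak_flow_ml_s": condition.peak_flow_ml_s}
    if provenance:
        meta.update(provenance)
    return SensorRecording(
        time_s=np.arange(n) / fs,
        pressures_mmhg=pressures,
        sensor_array=config.sensor_array,
        condition=condition,
        sampling_rate_hz=fs,
        ground_truth=truth,
        provenance=meta,
    )


def fast_config(**overrides) -> PhantomConfig:
    """Reduced-size configuration (4 kHz, 12 800 samples = 4 cycles at
    75 bpm) for quick experiments and tests; physics parameters unchanged."""
    params = dict(sampling_rate_hz=4000.0, n_samples=12_800)
    params.update(overrides)
    return PhantomConfig(**params)
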