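# Methods

## The physical system being emulated

The virtual phantom emulates a mock circulatory loop: a pulsatile piston
pump drives a blood-mimicking fluid (60/40 water–glycerol; density
1.119 g/cm³, viscosity 4.83 mPa·s) through a non-return valve into a
straight 32 mm i.d. silicone tube holding an aortic-valve model, and back
to an open reservoir. Eight wall pressure ports at −30, +15, +30, +50,
+75, +100, +200 and +500 mm from the valve plane are transduced
simultaneously; a recording is 50 000 samples per channel at 10 kHz
(5–6 cardiac cycles at 75 bpm). All pressures are in mmHg, flows in
ml/s, lengths in mm; the single unit conversion is 1 mmHg = 133.322 Pa.

## Flow waveform

Pulsatile flow is a periodic raised-cosine systole,
Q(t) = Q_peak · ½(1 − cos 2πt/T_sys) for 0 ≤ t < T_sys, zero in
diastole, with T_sys = 0.35 of the cycle. This gives the progressive
upstroke of ventricular ejection; the non-return valve clips flow at
zero, so there is no diastolic backflow. Constant mode holds Q_peak at
every sample. The exact pump profile of a physical loop is proprietary
to its controller; the raised cosine is a deliberate stand-in with the
right gross features (smooth upstroke, single peak, zero diastole), not
a calibrated replica.

## Pressure field (the 1-D parametric model)

No flow equations are solved; the pressure field is parametric, which is
the point — it gives exactly known ground truth.

- **Common driving pulse.** Every channel carries
  P₀ + R·Q(t), with baseline P₀ = 5 mmHg (open reservoir head) and an
  afterload resistance R = 0.16 mmHg/(ml/s), giving a ≈ 40 mmHg pulse at
  250 ml/s. The upstream channel carries the pulse undiminished — in the
  physical loop all channels pulse together and separate only by the
  valve drop during ejection. (A formulation with a constant upstream
  pressure would make the peak-to-peak metric degenerate: both temporal
  maxima would sit at the baseline.)
- **Vena-contracta drop.** v(t) = Q(t)/EOA;
  ΔP_vc(t) = 4 v(t)² + K ρ L_eff dv/dt (in mmHg after conversion), with
  K = 1 and L_eff = 30 mm. The first term is the convective (simplified
  Bernoulli) drop; the second is the inertial term of unsteady Bernoulli,
  which vanishes identically under constant flow and makes the pulsatile
  peak drop exceed the constant-flow drop at matched peak flow — the
  transient jet never settles into the efficient steady configuration.
- **Spatial structure.** The drop builds linearly from the valve plane
  (x = 0) to the vena contracta at x_vc = +25 mm (between the sensors at
  +15 and +30 mm), holds over a short 10 mm jet plateau, then relaxes
  exponentially (length scale 35 mm) toward the net drop
  ΔP_net(t) = ΔP_vc(t) · (1 − 2r(1−r)), r = EOA/A — the standard
  orifice pressure-recovery relation. With these defaults recovery is
  ≥ 99% complete by the +200 mm sensor, and the drops at +200 and
  +500 mm agree to < 1%. The jet plateau puts one sensor (+30 mm) at the
  full vena-contracta level, so the spatial interpolation of 8 discrete
  sensors can recover the true peak drop to well under 2%; without a
  plateau the reconstruction error is bounded by the sampling of a
  single-point minimum, not by the method.
- **Ground truth.** true peak = max_t ΔP_vc(t); true net = recovery
  fraction × true peak; the peak instant and the vena-contracta position
  are recorded alongside, from the noiseless field.

## Wave reflection

The distal tube end is an impedance mismatch: each downstream channel at
position x receives Γ × its own forward pressure deviation delayed by
the round-trip time 2(x_site − x)/c, with Γ = 0.3, x_site = 600 mm and
wave speed c = 10 m/s by default (aortic-range values). The upstream
channel is shielded by the valve. The superposed backward wave augments
and time-shifts the distal pressure maxima, which is precisely the
mechanism that corrupts the peak-to-peak metric while leaving the
same-instant peak and net drops nearly untouched. Pulsatile recordings
are treated as periodic steady-state when shifting (pre-recording
samples are taken one cycle later in phase); constant-flow recordings
hold the leading edge.

## Measurement noise

Three components, all drawn from one seeded generator:

1. broadband Gaussian sensor noise, sd 0.1 mmHg, every channel;
2. turbulence noise localized at the jet: sd = 0.5 mmHg ×
   exp(−|x − x_vc|/30 mm) × (v(t)/2.5 m s⁻¹)², tripled under constant
   flow, where turbulence has time to develop fully (channels 2–3 are
   visibly the noisiest, as in a physical loop);
3. pump artifacts (pulsatile only): 120 Hz bursts of 0.3 mmHg with a
   5 ms Gaussian envelope at the instants of peak dp/dt and peak
   pressure of every cycle, identical across channels (limited pump
   power is a channel-independent effect).

## Between-session and condition perturbations

The reproducibility protocol re-measures the same valve under four
handling conditions on two occasions (sessions A and B), four constant
and four pulsatile flow rates each: 8 condition–session combinations, 64
runs. The handling perturbations (uniform jitter, redrawn per run —
every regimen change involves operator interaction with the loop):

| condition | emulates | perturbation (defaults) |
|---|---|---|
| 1 | untouched baseline | none |
| 2 | purge/refill, tubing repositioned | baseline ±5%, Γ ±5%, reflection site ±100 mm, recovery efficiency ±6% |
| 3 | valve removed and remounted | + vena contracta ±3 mm, EOA ±2% |
| 4 | second, nominally identical valve | + EOA ±3% |

Session B additionally applies a systematic day effect, by default
EOA × 0.96 (a small obstruction increase, e.g. material change at the
leaflets); an additive per-channel zeroing offset is available as the
alternative day-bias mechanism (`session_b_mode="zero_offset"`), since a
re-zeroing error produces the same one-signed bias — the two hypotheses
are deliberately both on offer rather than resolved.

The reflection-site and recovery-efficiency jitters are this package's
own stand-ins for the distal factors a bench operator cannot control —
tubing curvature and support set the effective reflection site, and jet
angulation / wall deformation modulate how much pressure is actually
recovered. They act only on distal quantities, which is what makes the
net drop slightly less repeatable than the valve-local peak drop and the
peak-to-peak drop (reflection-timing-dependent) the least repeatable.
The magnitudes are order-of-magnitude choices, not calibrated to any
physical loop; all of them are configurable (`PerturbationScales`).

## Extraction pipeline numerics

- **Filter**: 4th-order Butterworth low-pass at 50 Hz, applied
  forward–backward (`sosfiltfilt`) so phase (and hence peak timing) is
  untouched and DC gain is exactly 1. Filtering precedes cycle
  segmentation because pump artifacts are not phase-locked to the
  upstroke anchor.
- **Segmentation**: the cycle length is known (60/HR); the phase anchor
  is the first rising crossing of 20% of the reference channel's swing.
  Only complete cycles are kept; fewer than two is an error.
- **Averaging**: pointwise mean over cycles; per-channel beat variance
  (sample variance across cycles, averaged over phase) is reported as
  the beat-to-beat reproducibility readout.
- **Peak instant** t*: argmax of P_ref(t) − P_recovery(t) on the
  averaged tracing, channels 1 and 7 by default (channel 7 is after
  recovery and less disturbed by end-reflections than channel 8); ties
  break to the earliest instant.
- **Spatial reconstruction**: modified-Akima ("makima") piecewise-cubic
  interpolation of the 8 samples at t*, evaluated on a 1 mm grid over
  the sensor span; the minimum gives the peak drop magnitude and
  location. The grid search is used instead of analytic root-finding
  because it is robust to the interpolant's piecewise structure; the
  spacing is configurable. Makima is exact at the nodes, reproduces
  linear data, and does not overshoot the way an unconstrained cubic
  spline does.
- **Metrics**: peak = P_ref(t*) − spatial minimum at t*;
  net = P_ref(t*) − P_rec(t*); peak-to-peak = |max_t P_ref − max_t
  P_rec| on the same averaged tracing. The wording "maximum difference
  across time between channel 1 and the interpolated value" is resolved
  as: find t* from channels 1 vs 7, then take the spatial minimum at t*
  (`instant_search="reference"`); the exhaustive alternative — maximize
  the interpolated drop over every instant — is available as
  `instant_search="global"` and agrees with the default on clean data.
- **Constant flow**: channels are time-averaged over the whole recording
  (the steady estimate; no cycles exist) and the same spatial analysis
  is applied; peak-to-peak is reported as absent, and is excluded from
  pooled statistics rather than imputed.

## Agreement statistics

Session comparisons pool conditions and flow rates within a flow mode
(A vs B, matched by condition and flow). Regression is OLS of B on A;
r² is the coefficient of determination (identical to squared Pearson r
for simple OLS); the slope CI is t-based from the OLS standard errors.
Bland–Altman: d = B − A, bias = mean(d), limits of agreement bias ±
1.96 sd(d) (sample sd), percent bias = 100 × bias / grand mean of the
pairwise means. Degenerate inputs (zero x-variance, n below the minimum)
are rejected with explicit messages rather than returning NaNs.

## Problem sizes

Full-scale recordings are 50 000 samples at 10 kHz. The test suite and
the acceptance script use the reduced `fast_config()` (12 800 samples at
4 kHz = 4 cycles, 3 complete after anchoring; 8 000 samples for
constant flow), which leaves every ratio in the physics unchanged —
only the beat-averaging depth and filter resolution differ, neither of
which is near its limit at this scale. The 20-replicate reliability
check (20 × 32 pulsatile runs) completes in well under a minute on one
CPU at this size.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis relies on:
Bernoulli scaling with a known recovery fraction, inertial pulsatile
excess, reflection-shifted distal peaks, valve-proximal noise, and
one-signed day bias. Passing tests therefore demonstrate that the
pipeline and statistics are correct and that the claimed mechanisms
(reflection confounds peak-to-peak; peak and net recover ground truth)
behave as described *within this model*. They do not validate the model
against a physical loop: no fluid–structure interaction, no compliant
wall mechanics, no anatomic geometry, no imaging chain, and the
perturbation magnitudes are stand-ins. Quantities that depend on those
magnitudes (the specific r² and bias values of a harness run) are
illustrative, not predictions.

One known divergence from bench behaviour: because the peak-to-peak and
net drops share the distal-coupling jitter in this model, they remain
strongly correlated with each other *within* a pooled run table, whereas
physical phantoms find the peak-to-peak poorly related to both other
metrics. The model expresses the peak-to-peak pathology in the
between-session comparison (where the coupling changes) and in its
weaker relation to the valve-local peak drop, not in the p2p–net
relation. Emulating the bench-observed decorrelation would require an
additional peak-specific corruption mechanism (e.g. under-damped
sensor-line resonance at the pressure maxima) that is deliberately out
of scope.

## Degenerate inputs and tie rules

Zero flow produces a flat field at baseline and all metrics zero. A
flat reference channel anchors segmentation at sample 0. Equal reference
and recovery channels give drop 0 at the earliest instant (tie rule).
Reflection with Γ = 0 and noise with zero amplitudes are exact
identities, bit for bit. EOA ≥ tube area (no stenosis), Γ ≥ 1
(amplifying reflection), cut-off ≥ Nyquist, duplicate sensor positions
and non-increasing time bases are rejected with messages.
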