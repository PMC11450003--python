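# Methods

This note records the models, parameter choices and numerical decisions
behind `ldvpa`, and what the synthetic experiments do and do not show
about real measurements.

## Acoustic forward model

The wave engine integrates the linear 2D acoustic system
∂v/∂t = −(1/ρ)∇p, ∂p/∂t = −ρc²∇·v on a staggered grid (pressure at
cell centres, velocity components on faces) with leapfrog time
stepping. The time step is dt = CFL·dx/c_max with CFL = 0.3, well
inside the 2D stability bound 1/√2. The default spacing dx = 20 µm
gives ≥10 cells per wavelength at 5 MHz in PDMS (λ = 204 µm);
`build_medium` refuses grids coarser than `min_ppw` cells per
wavelength at the declared `f_max`, and test-scale runs (dx = 40–50 µm)
declare correspondingly lower band limits.

Media are maps of (c, ρ). Density is 1000 kg/m³ everywhere so the sound
speed alone fixes the impedance: 1020 m/s → 1.02 MRayl for PDMS,
1500 m/s → 1.5 MRayl for the water/ink channels — matching both
impedances with a single free field. Channel interiors take the
water-like c = 1500 m/s; only the impedance, not the interior speed, is
directly known for the real samples, but the split of the backside
reflection into an earlier through-channel and a later around-channel
contribution requires a faster channel and 1500 m/s reproduces it.

Boundaries: the detection surface (z = 0) and slab backside are
pressure-release (p = 0), the correct idealisation of a solid/air
interface; they reflect with inverted polarity, which is what creates
both the backside echo and the mirror artifact. Lateral edges (and the
bottom of reconstruction media) use a 40-cell sponge with a cubic
damping ramp (~e⁻³ one-way attenuation) to emulate unbounded extent.

The LDV observable is the normal particle velocity half a cell inside
the soft surface (pressure on the boundary itself is identically zero);
displacement is its cumulative trapezoidal integral. Solver-rate traces
are resampled to the 65 MS/s acquisition rate by polyphase filtering
(`resample_poly`); Fourier resampling was rejected because its implicit
periodicity wraps trailing signal into the pre-arrival quiet zone.

## Initial pressure and illumination

`initial_pressure_from_absorption` scales the deposited pressure
linearly with the ink absorption coefficient (12.5 cm⁻¹ at 0.1 % v/v;
Beer–Lambert linearity in concentration). Two deposition geometries:

* `uniform` (default): constant pressure across each channel disc —
  the idealisation used for the wave-splitting study, where the
  channel acts as one coherent source.
* `backside`: the excitation beam arrives from the side opposite the
  detector and decays as exp(−µ_a·path) inside the ink. At 1 % ink
  (µ_a = 125 cm⁻¹) the source collapses to an ~80 µm crescent on the
  channel's far boundary.

The distinction matters for arrival times. A *uniform* 2 mm disc at
7 mm depth produces a surface signal with two nearly equal envelope
lobes — the near-edge arrival at (7−1) mm/1020 m/s = 5.88 µs and the
far-edge arrival at 7.84 µs — and its Hilbert-envelope peak sits on the
near-edge lobe (~5.9–6.0 µs at any realisable bandwidth; verified
against an exact free-field solution of the 2D wave equation built from
the Poisson retarded-integral formula). The *backside-illuminated*
channel instead radiates from its far side and the pulse crosses the
faster water channel, arriving at 2 mm/1500 + 6 mm/1020 ≈ 7.2 µs; the
simulated envelope peak is 7.23–7.28 µs across dx ∈ {12.5, 20, 25} µm.
The ~7 µs delay observed on real samples is therefore a signature of
the physical (attenuated, far-side) deposition, not of a uniform disc,
and the arrival-time analyses in `analysis/01` and
`scripts/acceptance.py` use the `backside` model. The
scalar `fluence_scale` (default 40 Pa·cm) lumps fluence and Grüneisen
efficiency; it was chosen so a 1 % channel yields ~0.9 kPa surface
pressure, giving post-averaging SNRs of order 10 — comparable imaging
quality to the published scans, whose absolute amplitudes are
hardware-specific and not reproducible.

## I/Q synthesis and demodulation

The homodyne model produces I = g_I·2µ|rm|cos θ' + o_I and
Q = g_Q·2µ|rm|sin(θ'+ε) + o_Q with θ' = 4π d/λ. Defaults carry the
distortions the real chain shows: gain imbalance g_I/g_Q = 1.2, offsets
0.1 of the unit locus radius, quadrature error ε = 5°. Additive
per-channel Gaussian noise has σ = 0.0054 (locus radius 1), calibrated
*through the full demodulation chain* so a single-segment still-sample
recording integrates to the measured noise floor, NEV ≈ 4 mm/s over
0–5 MHz (hence NEP = Z_s/2·NEV ≈ 2 kPa); a back-of-envelope white-noise
value (0.0046) undershoots because the zero-phase Butterworth removes
part of the band-edge noise. An additive decaying burst at each trigger
(amplitude 0.3·radius, ~0.5 µs, 3 MHz) emulates the excitation's
electrical interference at t = 0.

Demodulation: each segment is corrected onto the unit circle
(translate by the fitted centre, rotate by the tilt, rescale the axes,
rotate back — Heydemann correction; the quadrature error is absorbed
into the tilt), phase-demodulated with `arctan2`, 2π-unwrapped, and
converted to displacement; segments are averaged *after* demodulation
(averaging raw I/Q would bias the arctangent nonlinearity). Samples
with locus radius < 0.05 are treated as dropouts, interpolated
linearly, and counted. Velocity is the central-difference derivative
followed by a zero-phase 4th-order Butterworth at 5 MHz (the published
processing names only the cutoff; family and order are ours). The
ellipse fit itself is the numerically stable direct least-squares conic
fit (via `skimage.measure.EllipseModel`), which recovers noiseless
parameters to machine precision — the end-to-end
synthesize-then-demodulate chain is exact (≪1 nm RMS) for gain ratios
to 1.5, offsets to 0.3 and ε to 10°.

The t = 0 burst corrupts only the θ'(0) phase reference (a constant
displacement offset; velocity and pressure are unaffected once it
decays), so displacement identities are stated relative to the first
sample and pipeline reconstruction inputs are time-gated
(`mute_t0 = 1.5 µs`, cosine ramp) — the standard excitation-interference
mute.

## Characterization statistics

NEV spectra use Welch's method (Hann, 50 % overlap, 2¹⁴-sample
segments at 65 MS/s); total NEV over a band is the square root of the
integrated PSD, NEP = Z_s/2·NEV. Sensitivity S(f) = |C(f)|/|P(f)| is
masked where the reference magnitude is below 5× its noise floor
(median magnitude when no floor is supplied); the 3 dB bandwidth is the
interpolated first crossing of the sub-1 MHz plateau minus 3 dB, with a
flag when no crossing exists. The pulse SNR is the Hilbert-envelope
maximum over the RMS of a pre-arrival noise window. Two practical
details: the window must end before the pulse *onset* (the envelope
peak of a band-limited N-wave lags its leading edge by 1–2.5 µs, so
"peak − 1 µs" windows overlap the pulse), and the peak search should
exclude the first and last ~0.5 µs, where zero-phase filtering and the
Hilbert transform produce edge transients. For synthetic geometries the
scripts use the analytically known pre-arrival interval. Below the
detection limit the statistic saturates at the noise-envelope floor
(max of envelope noise / RMS ≈ 3–4), so SNR-vs-concentration is
monotone only above it — mirroring how weak-absorber points cluster at
low SNR in real data.

## Time-reversal reconstruction

Measured (or synthesized) surface pressure traces are time-reversed and
enforced as Dirichlet pressure values at the sensor cells one half-cell
inside the soft surface while the solver runs forward; the final-time
field estimates the initial pressure. The reconstruction medium is
homogeneous 1020 m/s — channel heterogeneity is *not* modelled in
reversal, as in the published processing — with a soft detection
surface over an absorbing-bottom half-space deeper than
2·thickness − source depth. Modelling the real backside in reversal
would refocus the echo onto the source; omitting it (as the published
reconstructions evidently did) reproduces the mirror artifact: a
duplicate focus at the depth mirrored about the backside, weaker than
the true focus, which this package deliberately keeps.

Envelope images back-propagate the traces and their Hilbert quadrature
separately and take the pointwise magnitude of the two final fields —
envelope detection in image space, nonnegative by construction.
`localize` applies non-maximum suppression (radius = one channel
diameter) and refines each maximum to the intensity²-weighted centroid
of its focal blob (window of half the suppression radius): the
band-limited image of an *extended* 2 mm absorber is edge-weighted and
its raw argmax sits ~0.35 mm off-centre; centroid refinement centres
compact and extended sources alike (raw maxima via `refine="none"`).
With the 80-sensor, 125 µm-pitch aperture the round trip localizes a
2 mm channel at 7 mm depth to well within the 230 µm resolution limit,
and still within twice that limit at double pitch.

## Problem sizes

Production settings are dx = 20 µm (≈600×700 cells for the 12 mm
phantom), 65 MS/s, 80 positions, 1 s (1000-segment) averaging. The test
suite and analysis scripts run desk-scale versions — dx = 40–50 µm with
matching declared band limits, 20 µs windows, 20–1000 segments — chosen
so the full suite completes in about a minute while every physical
check (time-of-flight, round-trip localization, √N averaging, noise
calibration) retains its discriminating power.

## What the synthetic data does not capture

Optical speckle and surface-roughness collection loss (only a lognormal
per-position efficiency knob, default off), frequency-dependent
acoustic attenuation, shear waves and 3D diffraction (the model is 2D,
appropriate for line-like channels but quantitatively different in
geometric spreading), fluence heterogeneity beyond a scalar per-channel
scale, and electronics nonlinearity/saturation. Passing tests therefore
demonstrate the correctness of the processing chain and the 2D acoustic
phenomenology, not absolute signal amplitudes of any specific hardware.
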