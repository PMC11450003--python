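# ldvpa — non-contact photoacoustic imaging with a laser Doppler vibrometer

Conventional photoacoustic imaging reads the ultrasound generated by
pulsed optical absorption with contact transducers. `ldvpa` models and
analyses the contactless alternative: a homodyne laser Doppler
vibrometer (LDV) pointed at the surface of a tissue-mimicking silicone
(PDMS) phantom detects the tiny surface vibrations produced by
light-absorbing, ink-filled channels buried millimetres deep, and a line
scan of such measurements is turned into a 2D image of the absorbers.
The package is aimed at researchers who want to study or extend this
detection chain quantitatively without the optical bench: every stage of
the experiment — acoustics, interferometry, electronics noise,
demodulation, image formation — has a tested software counterpart.

## The model

**Acoustics.** A pulsed 905 nm diode deposits energy in the ink
(extinction 12.5 cm⁻¹ at 0.1 % v/v), launching a pressure wave governed
by the 2D first-order acoustic system

    ∂v/∂t = −(1/ρ) ∇p,    ∂p/∂t = −ρc² ∇·v,

solved by a staggered-grid leapfrog FDTD scheme (CFL 0.3) on a medium
with c = 1020 m/s in PDMS and water-like c = 1500 m/s inside the
channels (ρ = 1000 kg/m³, so Z = 1.02 and 1.5 MRayl). The detection
surface and slab backside are pressure-release ("soft") boundaries;
lateral edges carry an absorbing sponge.

**Interferometry.** The homodyne LDV mixes a reference field
R = r·exp(iθ₀) with the probe return M(t) = m·exp(i(θ₁+θ(t))) in a
90° optical hybrid, giving photocurrent pairs

    I(t) = 2µ|rm| cos θ'(t),    Q(t) = 2µ|rm| sin θ'(t),

with θ'(t) = 4π d(t)/λ + (θ₁−θ₀) for surface displacement d(t) at
λ = 1550 nm. Hardware imperfections distort the circular I/Q locus into
an offset, tilted ellipse; a large-amplitude reference vibration is fit
with a direct least-squares conic and all points are projected back onto
the unit circle (Heydemann correction) before four-quadrant arctangent
demodulation. Then

    d = λ·Δθ'/(4π),    u = d′ (low-passed at 5 MHz),    p = (Z_s/2)·u.

**Imaging.** Per-position averaged pressure traces are time-reversed and
re-emitted through the same solver; the final-time field estimates the
initial pressure. The diffraction-limited resolution is
0.8·c/f_c ≈ 230 µm at the 3.5 MHz detection bandwidth.

## Worked example

```python
import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from ldvpa import (PhantomSpec, Channel, build_medium,
                   initial_pressure_from_absorption, simulate_forward)

phantom = PhantomSpec(thickness=12e-3, channels=[Channel(depth=7e-3)],
                      ink_concentration=1.0)
medium = build_medium(phantom, dx=20e-6, width=8e-3)
p0 = initial_pressure_from_absorption(phantom, medium,
                                      illumination="backside")
rec = simulate_forward(medium, p0, duration=10e-6,
                       sensor_positions=[0.0])
sos = butter(4, 5e6, fs=rec.fs, output="sos")
env = np.abs(hilbert(sosfiltfilt(sos, rec.velocity[0])))
print(f"arrival: {rec.time[np.argmax(env)] * 1e6:.2f} us")
```

prints `arrival: 7.25 us` — the surface above a channel centred 7 mm
deep first moves about 7 µs after the laser fires, the delay encoding
the absorber depth (7.25 µs ≈ 2 mm/1500 m/s through the water channel
plus 6 mm/1020 m/s of PDMS).

The numbered scripts under `analysis/` run the full study and write
tables to `results/`:

| script | what it found |
|---|---|
| `01_simulate_phantom.py` | envelope-peak arrival 7.25 µs for the backside-illuminated channel (5.98 µs for an idealised uniform disc) |
| `02_characterize_detector.py` | NEV 4.01 mm/s over 0–5 MHz → NEP 2.04 kPa; 3 dB bandwidth 3.50 MHz; 100-segment averaging cuts noise 10.2× |
| `03_demodulate_scan.py` | 80-position scan demodulated; centre-trace SNR 6.3 at 50-segment averaging |
| `04_reconstruct_images.py` | single channel localized at (−0.00, 6.99) mm vs true (0, 7) mm, mirror artifact at 12.3 mm ≈ 2·10−7 mm; dual channels at (−2.00, 6.06) and (+2.00, 7.06) mm |
| `05_concentration_series.py` | pulse SNR rises 3.0 → 10.8 from 0.01 % to 1 % ink, saturating at the noise floor below ~0.1 % |

A `ldvpa` console command exposes the same stages
(`simulate`, `synthesize`, `demod`, `characterize`, `reconstruct`,
`pipeline`) over YAML/JSON configs:

```bash
ldvpa pipeline --config config.yaml --seed 1 --out out/
```

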