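# Pipeline configuration schema

A pipeline config (YAML or JSON, loaded by `PipelineConfig.load`) mirrors
the dataclass fields verbatim. All physical quantities are SI.

```yaml
phantom:                  # PhantomSpec
  thickness: 12.0e-3      # slab thickness, m
  channels:               # list of Channel
    - depth: 7.0e-3       # centre depth below the detection surface, m
      offset: 0.0         # lateral centre offset from scan centre, m
      diameter: 2.0e-3    # m
  ink_concentration: 1.0  # % v/v (12.5 1/cm absorption at 0.1 %)
  reference_extinction: 12.5   # 1/cm at 0.1 % concentration

scan:                     # ScanConfig
  pitch: 125.0e-6         # scan pitch, m
  n_positions: 80
  averaging_duration: 1.0 # triggered averaging per position, s
  rep_rate: 1000.0        # excitation repetition rate, Hz
  fs: 65.0e6              # acquisition rate, samples/s
  window: 20.0e-6         # recorded span after each trigger, s
  seed: 0

iq:                       # IQModel (homodyne detection chain)
  r: 1.0                  # reference-arm field amplitude (arb.)
  m: 1.0                  # measurement-arm field amplitude (arb.)
  theta0: 0.0             # static reference phase, rad
  theta1: 0.0             # static measurement phase, rad
  mu: 0.5                 # photodiode responsivity (gain)
  g_i: 1.2                # I-channel gain
  g_q: 1.0                # Q-channel gain
  o_i: 0.1                # I DC offset (units of the locus radius = 1)
  o_q: 0.1                # Q DC offset
  quad_error: 0.0872665   # quadrature error, rad (5 deg)
  noise_sigma: 0.0054     # additive noise std per sample per channel
  wavelength: 1550.0e-9   # probe wavelength, m
  artifact_amplitude: 0.3 # t=0 interference burst, fraction of radius
  artifact_duration: 0.5e-6   # s
  artifact_frequency: 3.0e6   # Hz

demod:                    # DemodConfig
  wavelength: 1550.0e-9   # m
  fs: 65.0e6              # samples/s
  cutoff: 5.0e6           # low-pass cutoff, Hz
  filter_order: 4
  impedance: 1.02e6       # slab acoustic impedance Z_s, Rayl
  dropout_threshold: 0.05 # corrected-locus radius below which samples drop out

solver:                   # SolverConfig
  dx: 20.0e-6             # grid spacing, m
  width: 14.0e-3          # lateral extent of interest, m
  margins: null           # sponge width, m (null -> 40 cells)
  cfl: 0.3
  f_max: 5.0e6            # highest frequency the grid must resolve, Hz
  min_ppw: 10             # minimum cells per wavelength at f_max
  fluence_scale: 40.0     # initial pressure per unit absorption, Pa·cm

recon:                    # ReconConfig
  envelope_mode: true     # nonnegative envelope image
  n_peaks: 2
  suppression_radius: 2.0e-3  # non-maximum suppression radius, m
  mute_t0: 1.5e-6         # time-gate for the t=0 transient, s

seed: 0                   # global seed
outdir: ldvpa_out
trace_format: csv         # csv | hdf5
```
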