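"""End-to-end experiment driver and its configuration.

``run_pipeline`` reproduces the whole measurement chain on synthetic
data: acoustic forward simulation of the phantom, per-position I/Q
synthesis, ellipse calibration + demodulation to surface pressure,
detector characterization (NEV/NEP, sensitivity, bandwidth, per-position
SNR) and time-reversal image reconstruction with peak localization.  All
stages are deterministic for a fixed seed and every intermediate is
written to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import characterization, demodulation, reconstruction, synthetic_data, wave_engine
from .io import write_medium, write_traces
from .synthetic_data import Channel, IQModel, PhantomSpec, ScanConfig

log = logging.getLogger("ldvpa")

__all__ = ["SolverConfig", "ReconConfig", "PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class SolverConfig:
    dx: float = 20e-6  # grid spacing (m)
    width: float = 14e-3  # lateral extent of interest (m)
    margins: float | None = None  # sponge width (m); None -> 40 cells
    cfl: float = 0.3
    f_max: float = 5e6  # highest frequency the grid must resolve (Hz)
    min_ppw: int = 10
    fluence_scale: float = 40.0  # Pa per 1/cm of absorption


@dataclass
class ReconConfig:
    envelope_mode: bool = True
    n_peaks: int = 2
    suppression_radius: float = 2e-3  # m
    # time-gate for the t=0 excitation-interference transient before
    # back-propagation (cosine ramp after the gate)
    mute_t0: float = 1.5e-6  # s


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    scan: ScanConfig = field(default_factory=ScanConfig)
    iq: IQModel = field(default_factory=IQModel)
    demod: demodulation.DemodConfig = field(default_factory=demodulation.DemodConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    seed: int = 0
    outdir: str = "ldvpa_out"
    trace_format: str = "csv"

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d:
            ph = dict(d["phantom"])
            ph["channels"] = [Channel(**c) for c in ph.get("channels", [])]
            d["phantom"] = PhantomSpec(**ph)
        for key, typ in (
            ("scan", ScanConfig),
            ("iq", IQModel),
            ("demod", demodulation.DemodConfig),
            ("solver", SolverConfig),
            ("recon", ReconConfig),
        ):
            if key in d and not isinstance(d[key], typ):
                d[key] = typ(**d[key])
        return cls(**d)

    def save(self, path) -> Path:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)
        return path

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class PipelineResult:
    dataset: reconstruction.ScanDataset
    truth: wave_engine.SurfaceRecord
    image: reconstruction.Image
    metrics: dict
    outdir: Path


def default_noise_window(
    time: np.ndarray,
    onset: float,
    lo: float = 0.5e-6,
    guard: float = 0.5e-6,
) -> np.ndarray:
    """Pre-arrival noise window: [lo, pulse onset - guard].

    Excludes both the t = 0 excitation-interference transient (via
    ``lo``) and the pulse; falls back to the 1.5 us right after ``lo``
    when the onset leaves no room.
    """
    m = (time >= lo) & (time <= onset - guard)
    if m.sum() < 16:
        m = (time >= lo) & (time <= lo + 1.5e-6)
    return m


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute simulate -> synthesize -> demodulate -> characterize -> reconstruct."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    scan = config.scan
    sol = config.solver

    log.info("=== stage: simulate ===")
    synth = synthetic_data.generate_scan_dataset(
        config.phantom,
        scan,
        config.iq,
        seed=rng_seed,
        dx=sol.dx,
        fluence_scale=sol.fluence_scale,
        f_max=sol.f_max,
        min_ppw=sol.min_ppw,
        cfl=sol.cfl,
        width=max(sol.width, scan.scan_length + 4e-3),
    )
    medium = synth.medium
    log.info(
        "grid %d x %d cells, dx = %.1f um, dt(CFL=%.2f) = %.2f ns",
        medium.nx, medium.nz, medium.dx * 1e6, sol.cfl,
        sol.cfl * medium.dx / medium.c_map.max() * 1e9,
    )
    write_medium(out / "medium.h5", medium)
    ext = "h5" if config.trace_format == "hdf5" else "csv"
    write_traces(out / f"surface_truth.{ext}", synth.truth, fmt=config.trace_format)

    log.info("=== stage: calibrate (reference vibration -> ellipse) ===")
    ref = synthetic_data.make_reference_vibration(
        config.iq, seed=(rng_seed * 1000003 + 1) % 2**31
    )
    ellipse = demodulation.fit_ellipse(ref.points(0))
    log.info(
        "ellipse: center (%.3f, %.3f), a = %.3f, b = %.3f, tilt %.1f deg",
        *ellipse.center, ellipse.a, ellipse.b, np.rad2deg(ellipse.phi),
    )

    log.info(
        "=== stage: demodulate (%d positions x %d segments) ===",
        scan.n_positions, scan.n_segments,
    )
    cfg = dataclasses.replace(config.demod, fs=scan.fs)
    pressures = []
    dropouts = 0
    for i in range(scan.n_positions):
        res = demodulation.demodulate_record(synth.record(i), ellipse, cfg)
        pressures.append(res.pressure)
        dropouts += res.meta["dropouts"]
    traces = np.vstack(pressures)
    log.info("total dropout samples interpolated: %d", dropouts)
    mute = config.recon.mute_t0
    if mute > 0:
        t_axis = synth.truth.time
        ramp = 0.2e-6
        gate = np.clip((t_axis - mute) / ramp, 0.0, 1.0)
        traces = traces * (0.5 - 0.5 * np.cos(np.pi * gate))
    dataset = reconstruction.ScanDataset(
        positions=synth.positions,
        time=synth.truth.time,
        traces=traces,
        meta={"pitch": scan.pitch, "seed": rng_seed, "units": "Pa"},
    )
    write_traces(out / f"pressure_traces.{ext}", dataset, fmt=config.trace_format)

    log.info("=== stage: characterize ===")
    noise_model = dataclasses.replace(config.iq, artifact_amplitude=0.0)
    still = synthetic_data.synthesize_iq(
        np.zeros(4 * 2**14),
        noise_model,
        segments=1,
        fs=scan.fs,
        seed=(rng_seed * 1000003 + 2) % 2**31,
        artifact=False,
    )
    noise_res = demodulation.demodulate_record(still, ellipse, cfg)
    spec = characterization.nev_spectrum(noise_res.velocity, fs=scan.fs)
    nev, nep = characterization.integrate_nev(
        spec, band=(0.0, cfg.cutoff), impedance=cfg.impedance
    )
    log.info("NEV (0-%.0f MHz) = %.2f mm/s, NEP = %.2f kPa",
             cfg.cutoff / 1e6, nev * 1e3, nep / 1e3)

    center = int(np.argmin(np.abs(dataset.positions)))
    ref_pressure = demodulation.velocity_to_pressure(
        synth.truth.velocity[center], cfg
    )
    sens = characterization.sensitivity_spectrum(
        traces[center], ref_pressure, fs=scan.fs
    )
    bw = characterization.bandwidth_3db(sens)
    env_c = demodulation.envelope(traces[center])
    # search the trace interior: skip the muted transient and the filter
    # edge transient at the very end
    t_axis = dataset.time
    interior = (t_axis > mute + 0.3e-6) & (t_axis < t_axis[-1] - 0.5e-6)
    onset, arrival = characterization.detect_arrival(t_axis, env_c, interior)
    noise_win = default_noise_window(
        t_axis, onset, lo=max(0.5e-6, mute + 0.3e-6)
    )
    snrs = [
        float(characterization.snr(tr, noise_win, search=interior))
        for tr in traces
    ]
    log.info("arrival at center %.2f us, SNR(center) = %.1f",
             arrival * 1e6, snrs[center])

    log.info("=== stage: reconstruct ===")
    recon_medium = reconstruction.reconstruction_medium(
        depth=1.6 * config.phantom.thickness,
        width=max(sol.width, scan.scan_length + 4e-3),
        dx=sol.dx,
    )
    image = reconstruction.reconstruct(
        dataset, recon_medium, envelope_mode=config.recon.envelope_mode, cfl=sol.cfl
    )
    peaks = reconstruction.localize(
        image,
        n_peaks=config.recon.n_peaks,
        suppression_radius=config.recon.suppression_radius,
    )
    for x, z, amp in peaks:
        log.info("peak: x = %+.2f mm, z = %.2f mm, amplitude %.3g",
                 x * 1e3, z * 1e3, amp)
    np.save(out / "image.npy", image.values)

    metrics = {
        "nev_m_per_s": nev,
        "nep_pa": nep,
        "bandwidth_hz": bw.frequency,
        "bandwidth_flagged": bw.flagged,
        "arrival_time_s": arrival,
        "snr_center": snrs[center],
        "snr_per_position": snrs,
        "dropout_samples": dropouts,
        "peaks_x_z_amp": [[x, z, a] for x, z, a in peaks],
        "resolution_limit_m": reconstruction.resolution_limit(
            float(np.median(medium.c_map)), 3.5e6
        ),
        "seed": rng_seed,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return PipelineResult(
        dataset=dataset, truth=synth.truth, image=image, metrics=metrics, outdir=out
    )
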