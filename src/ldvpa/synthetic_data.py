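"""Synthetic stand-in for the photoacoustic lab setup.

Generates PDMS-slab phantoms with ink-filled channels, the initial
pressure maps their optical absorption would produce under pulsed
905 nm illumination, and realistic homodyne-LDV I/Q records — including
the ellipse distortion, DC offsets, quadrature error, additive noise and
the t=0 excitation-interference transient the real detection chain shows.

The homodyne model: reference field R = r exp(i*theta0) and measurement
field M(t) = m exp(i*(theta1 + theta(t))) interfere in a 90-degree optical
hybrid; the four photocurrents combine pairwise into

    I(t) = 2 mu |r m| cos(theta'(t)),   Q(t) = 2 mu |r m| sin(theta'(t)),

with theta'(t) = theta(t) + theta1 - theta0 and theta(t) = 4 pi d(t) / lambda
for a surface displacement d(t) probed at wavelength lambda = 1550 nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np

from . import wave_engine
from .wave_engine import Medium, SurfaceRecord

__all__ = [
    "Channel",
    "PhantomSpec",
    "IQModel",
    "IQRecord",
    "ScanConfig",
    "ScanSynthesis",
    "initial_pressure_from_absorption",
    "synthesize_iq",
    "make_reference_vibration",
    "generate_scan_dataset",
    "pulse_energy",
    "average_power",
    "REFERENCE_EXTINCTION",
    "REFERENCE_CONCENTRATION",
]

#: Measured extinction coefficient (1/cm) of a 0.1 % India-ink solution at 905 nm.
REFERENCE_EXTINCTION = 12.5
REFERENCE_CONCENTRATION = 0.1  # % v/v


@dataclass
class Channel:
    """A cylindrical ink-filled channel, seen in cross-section as a disc."""

    depth: float  # centre depth below the detection surface (m)
    offset: float = 0.0  # lateral centre offset from the scan centre (m)
    diameter: float = 2e-3  # m

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("channel diameter must be positive")


@dataclass
class PhantomSpec:
    """PDMS slab with embedded absorbing channels.

    ``ink_concentration`` is in % v/v; absorption scales linearly with
    concentration from the 12.5 1/cm reference at 0.1 %.
    """

    thickness: float = 12e-3
    channels: list[Channel] = field(
        default_factory=lambda: [Channel(depth=7e-3)]
    )
    ink_concentration: float = 1.0
    reference_extinction: float = REFERENCE_EXTINCTION

    def __post_init__(self) -> None:
        if self.ink_concentration < 0:
            raise ValueError("ink concentration must be non-negative")
        for ch in self.channels:
            r = ch.diameter / 2
            if ch.depth + r >= self.thickness or ch.depth - r <= 0:
                raise ValueError(
                    f"channel at {ch.depth * 1e3:.2f} mm does not fit the slab"
                )

    @property
    def absorption_coefficient(self) -> float:
        """Optical absorption mu_a (1/cm) at the configured concentration."""
        return self.reference_extinction * (
            self.ink_concentration / REFERENCE_CONCENTRATION
        )


@dataclass
class IQModel:
    """Parameters of the homodyne I/Q detection chain.

    The distortion defaults (gain imbalance, offsets, quadrature error)
    reflect the imperfect hybrid/amplifier chain of the real device; with
    ``g_i = g_q``, zero offsets and ``quad_error = 0`` the I/Q locus is a
    centred circle of radius ``2 mu |r m|``.

    ``noise_sigma`` is the per-sample additive noise std on each channel
    (same units as I/Q); the default is calibrated so that a demodulated
    1-segment noise recording integrates to a noise-equivalent velocity of
    ~4 mm/s over the 0–5 MHz detection band.
    """

    r: float = 1.0
    m: float = 1.0
    theta0: float = 0.0
    theta1: float = 0.0
    mu: float = 0.5
    g_i: float = 1.2
    g_q: float = 1.0
    o_i: float = 0.1
    o_q: float = 0.1
    quad_error: float = math.radians(5.0)
    noise_sigma: float = 0.0054
    wavelength: float = 1550e-9
    artifact_amplitude: float = 0.3  # fraction of the locus radius
    artifact_duration: float = 0.5e-6  # s
    artifact_frequency: float = 3e6  # Hz

    def __post_init__(self) -> None:
        if min(self.r, self.m, self.mu) <= 0:
            raise ValueError("r, m and mu must be positive")

    @property
    def radius(self) -> float:
        """Undistorted I/Q locus radius 2 mu |r m|."""
        return 2.0 * self.mu * abs(self.r * self.m)

    @classmethod
    def ideal(cls, noise_sigma: float = 0.0) -> "IQModel":
        """Distortion-free, artifact-free model (centred circular locus)."""
        return cls(
            g_i=1.0,
            g_q=1.0,
            o_i=0.0,
            o_q=0.0,
            quad_error=0.0,
            noise_sigma=noise_sigma,
            artifact_amplitude=0.0,
        )


@dataclass
class IQRecord:
    """Triggered, segmented I/Q acquisition.

    ``i`` and ``q`` have shape ``(n_segments, n_samples)``; segments share
    the same underlying signal and differ only in their noise realisation,
    mirroring the 1 kHz-triggered acquisition of the lab system.
    """

    fs: float  # samples/s
    i: np.ndarray
    q: np.ndarray
    trigger_times: np.ndarray  # s, one per segment
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.i.shape != self.q.shape:
            raise ValueError("I and Q arrays must share a shape")
        if self.i.ndim != 2:
            raise ValueError("segments must form a 2D array")

    @property
    def n_segments(self) -> int:
        return self.i.shape[0]

    @property
    def n_samples(self) -> int:
        return self.i.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Per-segment time axis (s), t = 0 at the trigger."""
        return np.arange(self.n_samples) / self.fs

    def points(self, segment: int = 0) -> np.ndarray:
        """(n_samples, 2) array of I/Q points for one segment."""
        return np.column_stack([self.i[segment], self.q[segment]])


@dataclass
class ScanConfig:
    """Line-scan acquisition settings.

    Defaults follow the lab protocol: 125 um pitch, 80 positions (~1 cm
    line), 1 s of triggered averaging per position at a 1 kHz repetition
    rate, 65 MS/s acquisition.
    """

    pitch: float = 125e-6
    n_positions: int = 80
    averaging_duration: float = 1.0  # s per position
    rep_rate: float = 1e3  # Hz
    fs: float = 65e6  # samples/s
    window: float = 20e-6  # recorded span after each trigger (s)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.n_positions < 1:
            raise ValueError("need at least one scan position")

    @property
    def n_segments(self) -> int:
        return max(1, int(round(self.rep_rate * self.averaging_duration)))

    @property
    def positions(self) -> np.ndarray:
        """Scan positions (m), centred on x = 0."""
        n = self.n_positions
        return (np.arange(n) - (n - 1) / 2) * self.pitch

    @property
    def scan_length(self) -> float:
        return self.pitch * (self.n_positions - 1)


def initial_pressure_from_absorption(
    phantom: PhantomSpec,
    grid: Medium,
    fluence_scale: float = 40.0,
    illumination: str = "uniform",
) -> np.ndarray:
    """Initial photoacoustic pressure map from optical absorption.

    With ``illumination="uniform"`` (default) every channel disc carries
    a uniform initial pressure proportional to its absorption
    coefficient,

        p0 = fluence_scale [Pa cm] * mu_a [1/cm],

    and zero elsewhere — the idealisation used for the wave-splitting
    phenomenology.  With ``illumination="backside"`` the excitation light
    arrives from the side opposite the detection surface and Beer-Lambert
    attenuation inside the ink weights the deposition toward each
    channel's deep boundary,

        p0 = fluence_scale * mu_a * exp(-mu_a * path),

    ``path`` being the in-channel optical path from the entry point — at
    1 % ink (mu_a = 125 1/cm) the source collapses to a ~80 um crescent
    on the far side of the channel, as in the real measurement.
    ``fluence_scale`` lumps fluence and the Grueneisen conversion
    efficiency into one scalar knob.
    """
    if phantom.ink_concentration < 0:
        raise ValueError("ink concentration must be non-negative")
    if illumination not in {"uniform", "backside"}:
        raise ValueError(f"unknown illumination model {illumination!r}")
    p0 = np.zeros((grid.nx, grid.nz))
    amp = fluence_scale * phantom.absorption_coefficient
    xg = grid.x[:, None]
    zg = grid.z[None, :]
    for ch in phantom.channels:
        r = ch.diameter / 2
        mask = (xg - ch.offset) ** 2 + (zg - ch.depth) ** 2 <= r**2
        if illumination == "uniform":
            p0[mask] = amp
        else:
            mu_m = phantom.absorption_coefficient * 100.0  # 1/m
            with np.errstate(invalid="ignore"):
                z_entry = ch.depth + np.sqrt(
                    np.maximum(r**2 - (xg - ch.offset) ** 2, 0.0)
                )
            path = np.clip(z_entry - zg, 0.0, None)
            p0[mask] = (amp * np.exp(-mu_m * path))[mask]
    return p0


def _artifact_burst(model: IQModel, n: int, fs: float) -> np.ndarray:
    """Decaying oscillatory transient coupled in at the excitation trigger."""
    if model.artifact_amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    tau = model.artifact_duration / 3.0
    burst = (
        model.artifact_amplitude
        * model.radius
        * np.exp(-t / tau)
        * np.cos(2 * np.pi * model.artifact_frequency * t)
    )
    burst[t > 2 * model.artifact_duration] = 0.0
    return burst


def synthesize_iq(
    displacement: np.ndarray,
    model: IQModel,
    segments: int = 1,
    fs: float = 65e6,
    seed: int | None = None,
    rep_rate: float = 1e3,
    artifact: bool = True,
) -> IQRecord:
    """Homodyne I/Q record for a given surface displacement trace.

    The interferometric phase is ``theta'(t) = 4 pi d(t) / lambda +
    (theta1 - theta0)``; distortion enters as per-channel gains, DC
    offsets and a quadrature error on Q:

        I = g_i * 2 mu |r m| cos(theta') + o_i + n_i
        Q = g_q * 2 mu |r m| sin(theta' + eps) + o_q + n_q

    Every segment carries the identical signal with an independent noise
    realisation (the lab's triggered averaging geometry).
    """
    d = np.asarray(displacement, float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("displacement must be a non-empty 1D trace")
    if segments < 1:
        raise ValueError("need at least one segment")
    theta = 4 * np.pi * d / model.wavelength + (model.theta1 - model.theta0)
    sig_i = model.radius * np.cos(theta)
    sig_q = model.radius * np.sin(theta + model.quad_error)
    if artifact:
        burst = _artifact_burst(model, d.size, fs)
        sig_i = sig_i + burst
        sig_q = sig_q + burst
    rng = np.random.default_rng(seed)
    shape = (segments, d.size)
    i_arr = model.g_i * sig_i[None, :] + model.o_i
    q_arr = model.g_q * sig_q[None, :] + model.o_q
    if model.noise_sigma > 0:
        i_arr = i_arr + rng.normal(0.0, model.noise_sigma, shape)
        q_arr = q_arr + rng.normal(0.0, model.noise_sigma, shape)
    else:
        i_arr = np.broadcast_to(i_arr, shape).copy()
        q_arr = np.broadcast_to(q_arr, shape).copy()
    return IQRecord(
        fs=fs,
        i=i_arr,
        q=q_arr,
        trigger_times=np.arange(segments) / rep_rate,
        seed=seed,
        meta={"artifact": bool(artifact and model.artifact_amplitude > 0)},
    )


def make_reference_vibration(
    model: IQModel,
    amplitude: float = 2e-6,
    fs: float = 65e6,
    n_samples: int = 4096,
    cycles: int = 3,
    seed: int | None = None,
) -> IQRecord:
    """Large-amplitude calibration vibration used for ellipse fitting.

    A sinusoidal displacement larger than the probe wavelength sweeps the
    interferometric phase over more than a full fringe, so the recorded
    I/Q points cover the whole (possibly distorted) locus.  Amplitudes
    below 1550 nm leave the locus incomplete and trigger a warning.
    """
    if amplitude <= model.wavelength:
        warnings.warn(
            "reference vibration amplitude below the 1550 nm probe wavelength; "
            "the I/Q locus will not close",
            stacklevel=2,
        )
    t = np.arange(n_samples) / fs
    f_vib = cycles * fs / n_samples
    d = amplitude * np.sin(2 * np.pi * f_vib * t)
    return synthesize_iq(d, model, segments=1, fs=fs, seed=seed, artifact=False)


@dataclass
class ScanSynthesis:
    """Lazy container for a synthetic line scan.

    Per-position I/Q records are synthesised on demand (a full 1 s
    acquisition at 65 MS/s is too large to hold for all positions at
    once) and are bit-reproducible for a fixed seed.
    """

    truth: SurfaceRecord
    phantom: PhantomSpec
    scan: ScanConfig
    model: IQModel
    medium: Medium
    seed: int
    _m_factors: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._m_factors is None:
            self._m_factors = np.ones(self.scan.n_positions)

    @property
    def positions(self) -> np.ndarray:
        return self.truth.positions

    def record(self, i: int) -> IQRecord:
        """Synthesise the I/Q record for scan position ``i``."""
        seed_i = (int(self.seed) * 1000003 + 7919 * i) % (2**31)
        model_i = replace(self.model, m=self.model.m * float(self._m_factors[i]))
        return synthesize_iq(
            self.truth.displacement[i],
            model_i,
            segments=self.scan.n_segments,
            fs=self.scan.fs,
            seed=seed_i,
            rep_rate=self.scan.rep_rate,
        )

    def __iter__(self) -> Iterator[IQRecord]:
        for i in range(self.scan.n_positions):
            yield self.record(i)

    def materialize(self) -> list[IQRecord]:
        return list(self)


def generate_scan_dataset(
    phantom: PhantomSpec,
    scan: ScanConfig,
    model: IQModel,
    seed: int | None = None,
    dx: float = 20e-6,
    fluence_scale: float = 40.0,
    collection_spread: float = 0.0,
    medium: Medium | None = None,
    width: float | None = None,
    f_max: float = 5e6,
    min_ppw: int = 10,
    cfl: float = 0.3,
    p0_filter: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ScanSynthesis:
    """Run the forward model once and set up per-position I/Q synthesis.

    ``collection_spread`` > 0 adds a per-position log-normal multiplier on
    the measurement-arm amplitude ``m``, mimicking position-dependent
    optical collection efficiency (dust/impurities on the surface).
    ``p0_filter`` may smooth the initial pressure map (e.g. to keep the
    source band-limited on coarse test grids).
    """
    if seed is None:
        seed = scan.seed
    if width is None:
        width = max(14e-3, scan.scan_length + 4e-3)
    if medium is None:
        medium = wave_engine.build_medium(
            phantom, dx=dx, width=width, f_max=f_max, min_ppw=min_ppw
        )
    p0 = initial_pressure_from_absorption(phantom, medium, fluence_scale)
    if p0_filter is not None:
        p0 = p0_filter(p0)
    truth = wave_engine.simulate_forward(
        medium,
        p0,
        duration=scan.window,
        sensor_positions=scan.positions,
        fs_out=scan.fs,
        cfl=cfl,
    )
    truth.meta["seed"] = seed
    rng = np.random.default_rng(seed)
    if collection_spread > 0:
        m_factors = rng.lognormal(0.0, collection_spread, scan.n_positions)
    else:
        m_factors = np.ones(scan.n_positions)
    return ScanSynthesis(
        truth=truth,
        phantom=phantom,
        scan=scan,
        model=model,
        medium=medium,
        seed=int(seed),
        _m_factors=m_factors,
    )


def pulse_energy(peak_power: float = 500.0, duration: float = 400e-9) -> float:
    """Optical pulse energy (J) of the excitation laser diode."""
    return peak_power * duration


def average_power(energy: float = 200e-6, rep_rate: float = 1e3) -> float:
    """Average optical power (W) at the given pulse repetition rate."""
    return energy * rep_rate
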