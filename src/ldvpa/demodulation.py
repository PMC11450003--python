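"""From raw I/Q records to calibrated surface pressure.

Processing chain, mirroring the lab pipeline:

1. fit an ellipse to a large-amplitude reference recording
   (gain imbalance, DC offsets and quadrature error distort the ideal
   circular I/Q locus into an offset, tilted ellipse);
2. project measurement points onto the unit circle (Heydemann-style
   correction: translate, rotate, rescale the axes, rotate back);
3. four-quadrant arctangent + 2*pi unwrapping -> interferometric phase;
4. displacement d = lambda * dtheta / (4 pi), lambda = 1550 nm;
5. velocity by time differentiation and zero-phase low-pass (5 MHz);
6. pressure p = (Z_s / 2) * u with the slab impedance Z_s = 1.02 MRayl;
7. Hilbert envelope for arrival-time and image processing.

Segments of a triggered acquisition are demodulated individually and the
resulting displacement traces averaged — averaging raw I/Q first would
bias the arctangent nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from skimage.measure import EllipseModel

from .synthetic_data import IQRecord

__all__ = [
    "EllipseParams",
    "DemodConfig",
    "DemodResult",
    "EllipseFitError",
    "fit_ellipse",
    "correct_iq",
    "demodulate_phase",
    "phase_to_displacement",
    "displacement_to_velocity",
    "velocity_to_pressure",
    "average_segments",
    "envelope",
    "demodulate_record",
]


class EllipseFitError(ValueError):
    """Degenerate input (collinear points / tiny arc) for the ellipse fit."""


@dataclass
class EllipseParams:
    """Fitted I/Q calibration ellipse.

    ``a >= b > 0`` are the semi-axes, ``phi`` the tilt of the major axis,
    ``residual`` the RMS geometric distance of the fit points.
    """

    center: tuple[float, float]
    a: float
    b: float
    phi: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse axes must satisfy a >= b > 0")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    @classmethod
    def identity(cls) -> "EllipseParams":
        """Unit circle — the no-distortion calibration."""
        return cls(center=(0.0, 0.0), a=1.0, b=1.0, phi=0.0)


@dataclass
class DemodConfig:
    """Constants of the demodulation chain (SI units)."""

    wavelength: float = 1550e-9  # probe wavelength (m)
    fs: float = 65e6  # acquisition rate (samples/s)
    cutoff: float = 5e6  # low-pass cutoff (Hz)
    filter_order: int = 4
    impedance: float = 1.02e6  # slab acoustic impedance Z_s (Rayl)
    dropout_threshold: float = 0.05  # |I/Q| radius below which samples are flagged

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.cutoff < self.fs / 2:
            raise ValueError("cutoff must lie below the Nyquist frequency")


@dataclass
class DemodResult:
    """Calibrated traces derived from one averaged acquisition."""

    time: np.ndarray  # s
    phase: np.ndarray  # unwrapped theta'(t), rad
    displacement: np.ndarray  # m
    velocity: np.ndarray  # m/s
    pressure: np.ndarray  # Pa
    envelope: np.ndarray  # |analytic pressure|, Pa
    meta: dict = field(default_factory=dict)


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit to I/Q samples.

    Wraps the numerically stable conic fit constrained to an ellipse and
    normalises the result so that ``a >= b``; the residual reported is the
    RMS geometric (point-to-ellipse) distance.

    Raises
    ------
    EllipseFitError
        For fewer than 6 points or degenerate (collinear / tiny-arc)
        configurations where the constrained fit has no solution.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 6:
        raise EllipseFitError(f"need >= 6 points, got {pts.shape[0]}")
    spread = pts.std(axis=0)
    try:
        model = EllipseModel.from_estimate(pts)
        ok = bool(model)
    except Exception:
        ok = False
    if not ok:
        raise EllipseFitError(
            "degenerate I/Q configuration: points are collinear or span too "
            f"small an arc (spread: I = {spread[0]:.3g}, Q = {spread[1]:.3g})"
        )
    (xc, yc) = (float(v) for v in model.center)
    a, b = (float(v) for v in model.axis_lengths)
    phi = float(model.theta)
    if not all(np.isfinite([xc, yc, a, b, phi])):
        raise EllipseFitError("ellipse fit returned non-finite parameters")
    if a <= 0 or b <= 0:
        raise EllipseFitError("fit collapsed to a degenerate conic")
    if b > a:
        a, b = b, a
        phi += np.pi / 2
    phi = (phi + np.pi / 2) % np.pi - np.pi / 2
    residual = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    return EllipseParams(center=(xc, yc), a=a, b=b, phi=phi, residual=residual)


def correct_iq(points: np.ndarray, ellipse: EllipseParams) -> np.ndarray:
    """Project I/Q points onto the unit circle using the fitted ellipse.

    Translate by the centre, rotate the major axis onto I, rescale the two
    axes to unit length, rotate back.  Noiseless on-ellipse points land on
    the unit circle to numerical precision.
    """
    pts = np.asarray(points, float)
    c, s = np.cos(ellipse.phi), np.sin(ellipse.phi)
    rot = np.array([[c, s], [-s, c]])
    out = (pts - np.asarray(ellipse.center)) @ rot.T
    out[:, 0] /= ellipse.a
    out[:, 1] /= ellipse.b
    return out @ np.array([[c, -s], [s, c]]).T


def demodulate_phase(
    points: np.ndarray,
    dropout_threshold: float = 0.05,
    return_dropouts: bool = False,
):
    """Four-quadrant phase extraction with 2*pi unwrapping.

    Samples whose radius falls below ``dropout_threshold`` (signal
    dropouts) are flagged, linearly interpolated from their neighbours
    after unwrapping, and counted.
    """
    pts = np.asarray(points, float)
    i, q = pts[:, 0], pts[:, 1]
    radius = np.hypot(i, q)
    bad = radius < dropout_threshold
    theta = np.unwrap(np.arctan2(q, i))
    n_bad = int(bad.sum())
    if 0 < n_bad < theta.size:
        idx = np.arange(theta.size)
        theta[bad] = np.interp(idx[bad], idx[~bad], theta[~bad])
    if return_dropouts:
        return theta, n_bad
    return theta


def phase_to_displacement(theta: np.ndarray, cfg: DemodConfig) -> np.ndarray:
    """Surface displacement from the unwrapped interferometric phase.

    d(t) = lambda * (theta'(t) - theta'(0)) / (4 pi); only relative motion
    is meaningful, so the first sample defines zero displacement.
    """
    theta = np.asarray(theta, float)
    return cfg.wavelength * (theta - theta[0]) / (4 * np.pi)


def _lowpass_sos(cfg: DemodConfig):
    return butter(cfg.filter_order, cfg.cutoff, fs=cfg.fs, output="sos")


def displacement_to_velocity(d: np.ndarray, cfg: DemodConfig) -> np.ndarray:
    """Surface velocity: central-difference derivative + zero-phase low-pass."""
    d = np.asarray(d, float)
    sos = _lowpass_sos(cfg)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if d.size <= padlen:
        raise ValueError(
            f"trace of {d.size} samples is shorter than the filter warm-up "
            f"({padlen + 1} samples)"
        )
    u = np.gradient(d, 1.0 / cfg.fs)
    return sosfiltfilt(sos, u)


def velocity_to_pressure(u: np.ndarray, cfg: DemodConfig) -> np.ndarray:
    """Surface pressure from surface velocity: p = (Z_s / 2) * u.

    Valid for a slab whose impedance dominates that of the surrounding air.
    """
    return (cfg.impedance / 2.0) * np.asarray(u, float)


def average_segments(segments: np.ndarray) -> np.ndarray:
    """Trigger-aligned mean across segments of equal length."""
    seg = np.asarray(segments, float)
    if seg.ndim == 1:
        return seg.copy()
    if seg.ndim != 2 or seg.shape[0] < 1:
        raise ValueError("segments must form a (n_segments, n_samples) array")
    return seg.mean(axis=0)


def envelope(trace: np.ndarray) -> np.ndarray:
    """Nonnegative amplitude envelope: magnitude of the analytic signal."""
    trace = np.asarray(trace, float)
    return np.abs(hilbert(trace))


def demodulate_record(
    record: IQRecord,
    ellipse: EllipseParams | None = None,
    cfg: DemodConfig | None = None,
) -> DemodResult:
    """Full chain for a segmented acquisition.

    Each segment is corrected, demodulated and converted to displacement
    individually; the displacement traces are then trigger-aligned
    averaged before differentiation, filtering and pressure conversion.
    """
    if cfg is None:
        cfg = DemodConfig(fs=record.fs)
    if ellipse is None:
        ellipse = EllipseParams.identity()
    disp = np.empty((record.n_segments, record.n_samples))
    dropouts = 0
    for k in range(record.n_segments):
        pts = correct_iq(record.points(k), ellipse)
        theta, n_bad = demodulate_phase(
            pts, dropout_threshold=cfg.dropout_threshold, return_dropouts=True
        )
        dropouts += n_bad
        disp[k] = phase_to_displacement(theta, cfg)
    d_avg = average_segments(disp)
    u = displacement_to_velocity(d_avg, cfg)
    p = velocity_to_pressure(u, cfg)
    theta_avg = 4 * np.pi * d_avg / cfg.wavelength
    return DemodResult(
        time=record.time,
        phase=theta_avg,
        displacement=d_avg,
        velocity=u,
        pressure=p,
        envelope=envelope(p),
        meta={
            "n_segments": record.n_segments,
            "dropouts": dropouts,
            "ellipse": ellipse,
        },
    )
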