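"""Detector performance metrics.

Noise-equivalent velocity (NEV) spectra via the Welch method, band
integration to a total NEV and its pressure equivalent (NEP = Z_s/2 * NEV),
sensitivity spectra against a flat-response reference detector, the 3 dB
bandwidth, and the pulse SNR statistic (Hilbert-envelope peak over the
pre-arrival noise RMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import hilbert, welch

__all__ = [
    "NoiseSpectrum",
    "SensitivitySpectrum",
    "BandwidthResult",
    "nev_spectrum",
    "integrate_nev",
    "sensitivity_spectrum",
    "bandwidth_3db",
    "detect_arrival",
    "snr",
]


@dataclass
class NoiseSpectrum:
    """One-sided velocity noise power spectral density.

    ``psd`` in (m/s)^2/Hz; ``nev_density`` is its square root, the
    noise-equivalent-velocity density in (m/s)/sqrt(Hz).
    """

    freq: np.ndarray  # Hz
    psd: np.ndarray
    nperseg: int
    overlap: float
    window: str

    @property
    def nev_density(self) -> np.ndarray:
        return np.sqrt(self.psd)


@dataclass
class SensitivitySpectrum:
    """Amplitude-spectrum ratio S(f) = C(f)/P(f) of two detectors.

    ``valid`` masks bins where the reference magnitude sits above the
    noise floor; S is NaN elsewhere.
    """

    freq: np.ndarray
    c_mag: np.ndarray
    p_mag: np.ndarray
    s: np.ndarray
    valid: np.ndarray


@dataclass
class BandwidthResult:
    frequency: float  # Hz
    flagged: bool = False  # True when S never crosses -3 dB in the valid band
    plateau: float = field(default=np.nan)


def nev_spectrum(
    velocity: np.ndarray,
    fs: float,
    nperseg: int = 2**14,
    overlap: float = 0.5,
    window: str = "hann",
) -> NoiseSpectrum:
    """Welch estimate of the velocity noise PSD.

    Defaults: Hann window, 50 % overlap, 2^14-sample segments at the
    65 MS/s acquisition rate.
    """
    v = np.asarray(velocity, float)
    if v.size < nperseg:
        raise ValueError(
            f"trace of {v.size} samples shorter than one Welch segment ({nperseg})"
        )
    freq, psd = welch(
        v,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
    )
    return NoiseSpectrum(
        freq=freq, psd=psd, nperseg=nperseg, overlap=overlap, window=window
    )


def integrate_nev(
    spec: NoiseSpectrum,
    band: tuple[float, float] = (0.0, 5e6),
    impedance: float = 1.02e6,
) -> tuple[float, float]:
    """Total NEV over a band and the corresponding NEP.

    NEV = sqrt(integral of the PSD over the band) (m/s);
    NEP = (Z_s / 2) * NEV (Pa), the surface-pressure relation applied to
    the velocity noise floor.
    """
    f_lo, f_hi = band
    if f_hi > spec.freq[-1] + 1e-9:
        raise ValueError(
            f"band edge {f_hi / 1e6:.2f} MHz beyond the spectrum's "
            f"{spec.freq[-1] / 1e6:.2f} MHz"
        )
    m = (spec.freq >= f_lo) & (spec.freq <= f_hi)
    nev = float(np.sqrt(trapezoid(spec.psd[m], spec.freq[m])))
    return nev, impedance / 2.0 * nev


def sensitivity_spectrum(
    candidate: np.ndarray,
    reference: np.ndarray,
    fs: float,
    noise_floor: float | np.ndarray | None = None,
    floor_factor: float = 5.0,
) -> SensitivitySpectrum:
    """Sensitivity of a detector against a flat-response reference.

    With P(f) and C(f) the FFT magnitude spectra of the reference and
    candidate recordings of the same pulse, S(f) = C(f)/P(f) wherever the
    reference magnitude exceeds ``floor_factor`` times the noise floor
    (estimated as the median reference magnitude when not given).
    """
    c = np.asarray(candidate, float)
    p = np.asarray(reference, float)
    if c.shape != p.shape:
        raise ValueError("candidate and reference must share a time base")
    if not np.any(p):
        raise ValueError("reference trace is identically zero")
    freq = np.fft.rfftfreq(p.size, d=1.0 / fs)
    c_mag = np.abs(np.fft.rfft(c))
    p_mag = np.abs(np.fft.rfft(p))
    if noise_floor is None:
        noise_floor = np.median(p_mag)
    valid = p_mag > floor_factor * np.asarray(noise_floor)
    s = np.full_like(p_mag, np.nan)
    s[valid] = c_mag[valid] / p_mag[valid]
    return SensitivitySpectrum(freq=freq, c_mag=c_mag, p_mag=p_mag, s=s, valid=valid)


def bandwidth_3db(
    spec: SensitivitySpectrum, plateau_band: float = 1e6
) -> BandwidthResult:
    """Lowest frequency where S(f) drops 3 dB below its DC plateau.

    The plateau is the median of S over the valid bins below
    ``plateau_band``; the crossing is linearly interpolated between bins.
    When S never falls below the -3 dB level inside the valid band, the
    highest valid frequency is returned with ``flagged=True``.
    """
    m = spec.valid & np.isfinite(spec.s)
    if not np.any(m):
        raise ValueError("no valid bins in the sensitivity spectrum")
    low = m & (spec.freq <= plateau_band)
    if not np.any(low):
        raise ValueError("sensitivity undefined near DC; cannot set the plateau")
    plateau = float(np.median(spec.s[low]))
    target = plateau * 10 ** (-3 / 20)
    f = spec.freq[m]
    s = spec.s[m]
    below = np.nonzero(s < target)[0]
    if below.size == 0:
        return BandwidthResult(frequency=float(f[-1]), flagged=True, plateau=plateau)
    j = below[0]
    if j == 0:
        return BandwidthResult(frequency=float(f[0]), flagged=True, plateau=plateau)
    # linear interpolation of the crossing between bins j-1 and j
    f_c = f[j - 1] + (target - s[j - 1]) * (f[j] - f[j - 1]) / (s[j] - s[j - 1])
    return BandwidthResult(frequency=float(f_c), flagged=False, plateau=plateau)


def detect_arrival(
    time: np.ndarray,
    env: np.ndarray,
    search: np.ndarray | None = None,
    onset_frac: float = 0.3,
) -> tuple[float, float]:
    """Pulse onset and envelope-peak times from an envelope trace.

    The peak is the envelope maximum (optionally restricted to a
    ``search`` mask); the onset is the first time the envelope exceeds
    ``onset_frac`` of that peak.  The onset, not the peak, bounds valid
    pre-arrival noise windows — the envelope of a band-limited pulse
    peaks well after its leading edge.
    """
    time = np.asarray(time, float)
    env = np.asarray(env, float)
    if search is None:
        search = np.ones(env.size, dtype=bool)
    idx = np.nonzero(search)[0]
    peak_local = idx[np.argmax(env[idx])]
    thresh = onset_frac * env[peak_local]
    above = idx[(env[idx] > thresh) & (idx <= peak_local)]
    onset_idx = above[0] if above.size else peak_local
    return float(time[onset_idx]), float(time[peak_local])


def snr(
    pulse_trace: np.ndarray,
    noise_window: slice | np.ndarray,
    search: slice | np.ndarray | None = None,
) -> float:
    """Pulse SNR: Hilbert-envelope maximum over the noise-window RMS.

    ``noise_window`` (a slice or index/boolean array) must select a
    pre-arrival interval that excludes both the pulse and the t = 0
    excitation-interference transient.  ``search`` optionally restricts
    the envelope-peak search (e.g. to the trace interior, away from
    filter edge transients).
    """
    x = np.asarray(pulse_trace, float)
    noise = x[noise_window]
    if noise.size == 0:
        raise ValueError("empty noise window")
    rms = float(np.sqrt(np.mean(noise**2)))
    if rms == 0.0:
        raise ValueError("noise window has zero RMS; cannot form an SNR")
    env = np.abs(hilbert(x))
    if search is not None:
        env = env[search]
        if env.size == 0:
            raise ValueError("empty search window")
    return float(env.max() / rms)
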