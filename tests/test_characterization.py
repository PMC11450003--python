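"""Noise spectra, NEV/NEP, sensitivity, bandwidth and SNR statistics."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from ldvpa import characterization as ch


@pytest.fixture(scope="module")
def white_noise():
    fs = 65e6
    sigma = 2e-3
    v = np.random.default_rng(0).normal(0, sigma, 2**18)
    return fs, sigma, v


class TestNevSpectrum:
    def test_white_noise_psd_is_flat_at_two_sigma_sq_over_fs(self, white_noise):
        fs, sigma, v = white_noise
        spec = ch.nev_spectrum(v, fs)
        band = spec.freq > 0
        assert np.median(spec.psd[band]) == pytest.approx(
            2 * sigma**2 / fs, rel=0.10
        )

    def test_parseval_consistency(self, white_noise):
        fs, sigma, v = white_noise
        spec = ch.nev_spectrum(v, fs)
        var_from_psd = np.trapezoid(spec.psd, spec.freq)
        assert var_from_psd == pytest.approx(np.var(v), rel=0.05)

    def test_pure_tone_concentrates_in_one_bin(self):
        fs = 65e6
        t = np.arange(2**16) / fs
        spec = ch.nev_spectrum(np.sin(2 * np.pi * 1e6 * t), fs, nperseg=2**13)
        assert spec.freq[np.argmax(spec.psd)] == pytest.approx(1e6, rel=0.01)

    def test_zero_trace_gives_zero_spectrum(self):
        spec = ch.nev_spectrum(np.zeros(2**15), 65e6, nperseg=2**14)
        assert np.all(spec.psd == 0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ch.nev_spectrum(np.zeros(100), 65e6)


class TestIntegrateNev:
    def test_nev_4mm_per_s_gives_nep_2kpa(self):
        # flat PSD whose 0-5 MHz integral is (4 mm/s)^2
        freq = np.linspace(0, 5e6, 501)
        psd = np.full_like(freq, (4e-3) ** 2 / 5e6)
        spec = ch.NoiseSpectrum(freq, psd, nperseg=0, overlap=0, window="-")
        nev, nep = ch.integrate_nev(spec, band=(0, 5e6), impedance=1.02e6)
        assert nev == pytest.approx(4e-3, rel=1e-6)
        assert nep == pytest.approx(2.04e3, rel=1e-6)

    def test_white_noise_full_band_nev_equals_sigma(self, white_noise):
        fs, sigma, v = white_noise
        spec = ch.nev_spectrum(v, fs)
        nev, _ = ch.integrate_nev(spec, band=(0, fs / 2))
        assert nev == pytest.approx(sigma, rel=0.10)

    def test_zero_spectrum_gives_zero_nev(self):
        freq = np.linspace(0, 5e6, 64)
        spec = ch.NoiseSpectrum(freq, np.zeros_like(freq), 0, 0, "-")
        nev, nep = ch.integrate_nev(spec, band=(0, 5e6))
        assert nev == 0 and nep == 0

    def test_band_beyond_spectrum_rejected(self):
        freq = np.linspace(0, 1e6, 64)
        spec = ch.NoiseSpectrum(freq, np.ones_like(freq), 0, 0, "-")
        with pytest.raises(ValueError):
            ch.integrate_nev(spec, band=(0, 5e6))


@pytest.fixture(scope="module")
def pulse_pair():
    """Reference pulse and its 2nd-order 3.5 MHz low-pass as candidate."""
    fs = 65e6
    t = np.arange(2**14) / fs
    ref = np.exp(-((t - 3e-6) ** 2) / (2 * (0.15e-6) ** 2)) * np.sin(
        2 * np.pi * 2e6 * (t - 3e-6)
    )
    sos = butter(2, 3.5e6, fs=fs, output="sos")
    from scipy.signal import sosfilt

    cand = sosfilt(sos, ref)
    return fs, ref, cand, sos


class TestSensitivity:
    def test_identical_traces_give_unit_sensitivity(self, pulse_pair):
        fs, ref, _, _ = pulse_pair
        spec = ch.sensitivity_spectrum(ref, ref, fs)
        assert np.allclose(spec.s[spec.valid], 1.0)

    def test_half_amplitude_gives_half_sensitivity(self, pulse_pair):
        fs, ref, _, _ = pulse_pair
        spec = ch.sensitivity_spectrum(0.5 * ref, ref, fs)
        assert np.allclose(spec.s[spec.valid], 0.5)

    def test_known_filter_response_recovered(self, pulse_pair):
        fs, ref, cand, sos = pulse_pair
        from scipy.signal import sosfreqz

        spec = ch.sensitivity_spectrum(cand, ref, fs)
        m = spec.valid & (spec.freq < 6e6)
        _, h = sosfreqz(sos, worN=spec.freq[m], fs=fs)
        assert np.allclose(spec.s[m], np.abs(h), rtol=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ch.sensitivity_spectrum(np.ones(64), np.zeros(64), 65e6)


class TestBandwidth:
    def test_second_order_lowpass_cutoff_recovered(self, pulse_pair):
        fs, ref, cand, _ = pulse_pair
        spec = ch.sensitivity_spectrum(cand, ref, fs)
        bw = ch.bandwidth_3db(spec)
        assert not bw.flagged
        assert bw.frequency == pytest.approx(3.5e6, rel=0.05)

    def test_flat_sensitivity_returns_band_edge_with_flag(self, pulse_pair):
        fs, ref, _, _ = pulse_pair
        spec = ch.sensitivity_spectrum(ref, ref, fs)
        bw = ch.bandwidth_3db(spec)
        assert bw.flagged
        assert bw.frequency == pytest.approx(spec.freq[spec.valid][-1])

    def test_bandwidth_scales_with_cutoff(self, pulse_pair):
        fs, ref, _, _ = pulse_pair
        from scipy.signal import sosfilt

        bws = []
        for fc in (1.5e6, 3.0e6):
            sos = butter(2, fc, fs=fs, output="sos")
            spec = ch.sensitivity_spectrum(sosfilt(sos, ref), ref, fs)
            bws.append(ch.bandwidth_3db(spec).frequency)
        assert bws[1] / bws[0] == pytest.approx(2.0, rel=0.05)


class TestSnr:
    def test_constructed_pulse_gives_amplitude_over_rms(self):
        fs = 65e6
        t = np.arange(2**14) / fs
        amp, sigma = 5.0, 0.25
        pulse = amp * np.exp(-((t - 150e-6) ** 2) / (2 * (2e-6) ** 2)) * np.sin(
            2 * np.pi * 2e6 * t
        )
        noise = np.random.default_rng(1).normal(0, sigma, t.size)
        trace = pulse + noise
        window = slice(1000, 5000)  # pre-arrival
        got = ch.snr(trace, window)
        assert got == pytest.approx(amp / np.sqrt(np.mean(noise[window] ** 2)),
                                    rel=0.10)

    def test_snr_doubles_with_pulse_amplitude(self):
        fs = 65e6
        t = np.arange(2**13) / fs
        pulse = np.exp(-((t - 80e-6) ** 2) / (2 * (2e-6) ** 2))
        trace = pulse.copy()
        w = slice(0, 2000)
        trace[w] = np.random.default_rng(2).normal(0, 0.05, 2000)
        trace2 = 2 * pulse
        trace2[w] = trace[w]  # same noise window, doubled pulse
        assert ch.snr(trace2, w) / ch.snr(trace, w) == pytest.approx(2.0, rel=0.05)

    def test_zero_noise_window_rejected(self):
        trace = np.zeros(1000)
        trace[700] = 1.0
        with pytest.raises(ValueError):
            ch.snr(trace, slice(0, 100))

    def test_snr_increases_with_ink_concentration(self, tr_setup):
        """Above the detection floor, more ink -> more absorption -> higher SNR."""
        import dataclasses

        from ldvpa import demodulation as dm
        from ldvpa import synthetic_data as sd

        center = int(np.argmin(np.abs(tr_setup["positions"])))
        d_full = tr_setup["record"].displacement[center]
        model = sd.IQModel()
        ell = dm.fit_ellipse(
            sd.make_reference_vibration(
                dataclasses.replace(model, artifact_amplitude=0.0), seed=5
            ).points(0)
        )
        cfg = dm.DemodConfig()
        mean_snr = []
        for conc in (0.25, 0.5, 1.0):
            vals = []
            for rep in range(3):
                rec = sd.synthesize_iq(
                    d_full * conc, model, segments=400, seed=100 * rep + int(conc * 8)
                )
                res = dm.demodulate_record(rec, ell, cfg)
                gate = np.clip((res.time - 1.8e-6) / 0.2e-6, 0.0, 1.0)
                p = res.pressure * (0.5 - 0.5 * np.cos(np.pi * gate))
                t = res.time
                interior = (t > 2.1e-6) & (t < t[-1] - 0.5e-6)
                # known geometry: the 7 mm channel's pulse cannot arrive
                # before (7-1) mm / 1020 m/s = 5.9 us
                win = (t > 2.1e-6) & (t < 4.8e-6)
                vals.append(ch.snr(p, win, search=interior))
            mean_snr.append(np.mean(vals))
        assert mean_snr[0] < mean_snr[1] < mean_snr[2]

    def test_noise_only_trace_gives_order_unity_snr(self):
        rng = np.random.default_rng(3)
        vals = [
            ch.snr(rng.normal(0, 1, 4096), slice(0, 1024)) for _ in range(20)
        ]
        assert 1.0 < np.mean(vals) < 6.0
        assert max(vals) < 10.0
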