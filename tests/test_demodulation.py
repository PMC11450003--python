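"""Ellipse calibration, phase demodulation and the pressure chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldvpa import demodulation as dm
from ldvpa import synthetic_data as sd


def ellipse_points(center, a, b, phi, n=400, noise=0.0, seed=0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(phi), np.sin(phi)
    pts = np.column_stack([c * x - s * y + center[0], s * x + c * y + center[1]])
    if noise:
        pts += np.random.default_rng(seed).normal(0, noise, pts.shape)
    return pts


class TestFitEllipse:
    def test_unit_circle(self):
        ell = dm.fit_ellipse(ellipse_points((0, 0), 1, 1, 0))
        assert ell.center == pytest.approx((0, 0), abs=1e-9)
        assert ell.a == pytest.approx(1, rel=1e-9)
        assert ell.b == pytest.approx(1, rel=1e-9)
        assert ell.residual < 1e-9

    def test_generate_and_refit_recovers_parameters(self):
        true = ((0.1, -0.05), 1.2, 0.8, np.deg2rad(30))
        ell = dm.fit_ellipse(ellipse_points(*true))
        assert ell.center == pytest.approx(true[0], abs=1e-6)
        assert ell.a == pytest.approx(true[1], abs=1e-6)
        assert ell.b == pytest.approx(true[2], abs=1e-6)
        assert ell.phi == pytest.approx(true[3], abs=1e-6)

    def test_noisy_fit_within_tolerance(self):
        true = ((0.1, -0.05), 1.2, 0.8, np.deg2rad(30))
        ell = dm.fit_ellipse(ellipse_points(*true, noise=0.01, seed=42))
        assert ell.center == pytest.approx(true[0], abs=1e-2)
        assert ell.a == pytest.approx(true[1], abs=1e-2)
        assert ell.b == pytest.approx(true[2], abs=1e-2)

    def test_collinear_points_raise(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(dm.EllipseFitError):
            dm.fit_ellipse(np.column_stack([t, 2 * t]))

    def test_too_few_points_raise(self):
        with pytest.raises(dm.EllipseFitError):
            dm.fit_ellipse(np.ones((5, 2)))


class TestCorrectIQ:
    def test_on_ellipse_points_land_on_unit_circle(self):
        true = ((0.3, 0.1), 1.4, 0.6, np.deg2rad(-20))
        pts = ellipse_points(*true)
        ell = dm.fit_ellipse(pts)
        out = dm.correct_iq(pts, ell)
        assert np.abs(np.hypot(out[:, 0], out[:, 1]) - 1).max() < 1e-9

    def test_identity_ellipse_leaves_points_unchanged(self):
        pts = ellipse_points((0, 0), 1, 1, 0, n=64)
        out = dm.correct_iq(pts, dm.EllipseParams.identity())
        assert np.allclose(out, pts)

    def test_corrected_distorted_record_has_small_phase_error(
        self, distorted_model
    ):
        fs = 65e6
        t = np.arange(2000) / fs
        d = 40e-9 * np.sin(2 * np.pi * 1.5e6 * t)
        rec = sd.synthesize_iq(d, distorted_model, fs=fs, artifact=False)
        ell = dm.fit_ellipse(
            sd.make_reference_vibration(distorted_model, seed=0).points(0)
        )
        theta = dm.demodulate_phase(dm.correct_iq(rec.points(0), ell))
        theta_true = 4 * np.pi * d / distorted_model.wavelength
        err = (theta - theta[0]) - (theta_true - theta_true[0])
        assert np.sqrt(np.mean(err**2)) < 1e-3  # <= 1 mrad RMS


class TestPhaseDemodulation:
    def test_ramp_recovered_without_wraps(self):
        ramp = np.linspace(0, 6 * np.pi, 500)
        pts = np.column_stack([np.cos(ramp), np.sin(ramp)])
        theta = dm.demodulate_phase(pts)
        assert np.allclose(theta, ramp, atol=1e-9)

    def test_constant_point_gives_constant_phase(self):
        pts = np.tile([np.cos(np.pi / 4), np.sin(np.pi / 4)], (64, 1))
        assert np.allclose(dm.demodulate_phase(pts), np.pi / 4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_unwrap_never_leaves_two_pi_jumps(self, seed):
        """Any phase walk with sub-pi steps unwraps to sub-pi steps."""
        rng = np.random.default_rng(seed)
        steps = rng.uniform(-3.0, 3.0, 300)
        phase = np.cumsum(steps)
        pts = np.column_stack([np.cos(phase), np.sin(phase)])
        theta = dm.demodulate_phase(pts)
        assert np.abs(np.diff(theta)).max() < np.pi

    def test_dropouts_flagged_and_interpolated(self):
        ramp = np.linspace(0, np.pi, 100)
        pts = np.column_stack([np.cos(ramp), np.sin(ramp)])
        pts[40:43] *= 1e-4  # dropout samples
        theta, n_bad = dm.demodulate_phase(pts, return_dropouts=True)
        assert n_bad == 3
        assert np.allclose(theta, ramp, atol=1e-2)


class TestDisplacementChain:
    cfg = dm.DemodConfig()

    @pytest.mark.parametrize(
        "dtheta, expected",
        [(4 * np.pi, 1550e-9), (0.0, 0.0), (np.pi, 387.5e-9)],
    )
    def test_phase_to_displacement_values(self, dtheta, expected):
        theta = np.array([0.0, dtheta])
        d = dm.phase_to_displacement(theta, self.cfg)
        assert d[-1] == pytest.approx(expected, abs=1e-15)

    def test_sine_derivative_amplitude(self):
        f, amp = 1e6, 5e-9
        t = np.arange(4096) / self.cfg.fs
        u = dm.displacement_to_velocity(amp * np.sin(2 * np.pi * f * t), self.cfg)
        interior = u[500:-500]
        assert np.abs(interior).max() == pytest.approx(2 * np.pi * f * amp, rel=0.01)

    def test_constant_displacement_gives_zero_velocity(self):
        u = dm.displacement_to_velocity(np.full(2048, 3e-9), self.cfg)
        assert np.abs(u).max() < 1e-18

    def test_above_cutoff_attenuated_20db(self):
        f = 10e6  # above the 5 MHz cutoff
        t = np.arange(4096) / self.cfg.fs
        u = dm.displacement_to_velocity(1e-9 * np.sin(2 * np.pi * f * t), self.cfg)
        assert np.abs(u[500:-500]).max() < 0.1 * (2 * np.pi * f * 1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            dm.displacement_to_velocity(np.zeros(10), self.cfg)

    def test_pressure_from_velocity_eq7(self):
        u = np.array([4e-3])
        p = dm.velocity_to_pressure(u, self.cfg)
        assert p[0] == pytest.approx(2.04e3)
        assert np.allclose(dm.velocity_to_pressure(2 * u, self.cfg), 2 * p)


class TestAveragingAndEnvelope:
    def test_single_segment_is_identity(self):
        x = np.random.default_rng(0).normal(size=128)
        assert np.array_equal(dm.average_segments(x), x)

    def test_noise_averaging_follows_sqrt_n(self):
        rng = np.random.default_rng(1)
        seg = rng.normal(0, 1.0, (100, 4096))
        avg = dm.average_segments(seg)
        assert np.std(avg) == pytest.approx(0.1, rel=0.15)

    def test_snr_gain_sqrt_n_for_repeated_signal(self):
        rng = np.random.default_rng(2)
        t = np.arange(2048)
        signal = np.sin(2 * np.pi * t / 64)
        n = 64
        seg = signal + rng.normal(0, 1.0, (n, t.size))
        noise_before = np.std(seg[0] - signal)
        noise_after = np.std(dm.average_segments(seg) - signal)
        assert noise_before / noise_after == pytest.approx(np.sqrt(n), rel=0.15)

    def test_sine_envelope_is_flat_amplitude(self):
        t = np.arange(8192) / 65e6
        env = dm.envelope(0.7 * np.sin(2 * np.pi * 2e6 * t))
        assert np.allclose(env[500:-500], 0.7, rtol=0.02)

    def test_zero_trace_zero_envelope_and_nonnegativity(self):
        assert np.all(dm.envelope(np.zeros(64)) == 0)
        x = np.random.default_rng(3).normal(size=512)
        assert np.all(dm.envelope(x) >= 0)


class TestEndToEnd:
    fs = 65e6

    def _displacement(self, n=3000):
        t = np.arange(n) / self.fs
        return 30e-9 * np.sin(2 * np.pi * 1.2e6 * t) + 15e-9 * np.sin(
            2 * np.pi * 2.7e6 * t + 1.0
        )

    @pytest.mark.parametrize(
        "g_i, offset, eps_deg",
        [(1.2, 0.1, 5.0), (1.5, 0.3, 10.0)],
    )
    def test_identity_under_distortion(self, g_i, offset, eps_deg):
        """Synthesize -> demodulate returns the displacement within 1 nm RMS."""
        model = dataclasses.replace(
            sd.IQModel(),
            g_i=g_i, g_q=1.0, o_i=offset, o_q=offset,
            quad_error=np.deg2rad(eps_deg),
            noise_sigma=0.0, artifact_amplitude=0.0,
        )
        d = self._displacement()
        rec = sd.synthesize_iq(d, model, fs=self.fs, artifact=False)
        ell = dm.fit_ellipse(sd.make_reference_vibration(model, seed=0).points(0))
        res = dm.demodulate_record(rec, ell)
        # displacement is relative to the first sample by construction
        err = res.displacement - (d - d[0])
        assert np.sqrt(np.mean(err**2)) < 1e-9

    def test_artifact_only_offsets_displacement_not_velocity(self):
        model = dataclasses.replace(sd.IQModel(), noise_sigma=0.0)
        d = self._displacement()
        with_art = sd.synthesize_iq(d, model, fs=self.fs, artifact=True)
        without = sd.synthesize_iq(d, model, fs=self.fs, artifact=False)
        ell = dm.fit_ellipse(sd.make_reference_vibration(model, seed=0).points(0))
        ra = dm.demodulate_record(with_art, ell)
        rb = dm.demodulate_record(without, ell)
        late = ra.time > 1.5e-6  # after the transient
        d_err = ra.displacement[late] - rb.displacement[late]
        assert np.ptp(d_err) < 1e-10  # constant offset only
        v_err = ra.velocity[late] - rb.velocity[late]
        # zero-phase IIR filtering leaves only a tiny decaying residue
        assert np.abs(v_err).max() < 1e-4 * np.abs(rb.velocity).max()

    def test_global_phase_rotation_leaves_displacement_unchanged(self):
        model_a = sd.IQModel.ideal()
        model_b = dataclasses.replace(sd.IQModel.ideal(), theta1=0.8)
        d = self._displacement()
        ra = dm.demodulate_record(sd.synthesize_iq(d, model_a, artifact=False))
        rb = dm.demodulate_record(sd.synthesize_iq(d, model_b, artifact=False))
        assert np.allclose(ra.displacement, rb.displacement, atol=1e-15)

    def test_pressure_equals_direct_single_expression(self):
        """p(t) == (Z_s/2) * lowpass(d'(t)) computed independently."""
        from scipy.signal import butter, sosfiltfilt

        cfg = dm.DemodConfig()
        model = sd.IQModel.ideal()
        d = self._displacement()
        rec = sd.synthesize_iq(d, model, fs=self.fs, artifact=False)
        res = dm.demodulate_record(rec, cfg=cfg)
        sos = butter(4, 5e6, fs=self.fs, output="sos")
        expected = 1.02e6 / 2 * sosfiltfilt(sos, np.gradient(d, 1 / self.fs))
        assert np.allclose(res.pressure, expected, atol=1e-6 * np.abs(expected).max())
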