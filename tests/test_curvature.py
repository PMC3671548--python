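"""Spectral parameterization, filtering and curvature of the midline."""

import numpy as np
import pytest

import memcurv as mc
from memcurv.core import Box
from memcurv.curvature import unwrap_periodic
from memcurv.errors import MemcurvError, SpectraError
from memcurv.midline import Midline


def circle_midline(radius, s=1.0, center=(60.0, 60.0), box_len=120.0):
    """Closed circle sampled at N = round(2πR/s) uniform points."""
    n = int(round(2 * np.pi * radius / s))
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([
        center[0] + radius * np.cos(th),
        np.full(n, 5.0),
        center[1] + radius * np.sin(th),
    ])
    return Midline(points=pts, s=s, box=Box([box_len, 10.0, box_len]))


def synthetic_line_midline(n=64, s=1.0):
    """Straight midline winding the box once in X."""
    pts = np.column_stack([
        np.arange(n) * s, np.full(n, 5.0), np.full(n, 10.0)
    ])
    return Midline(points=pts, s=s, box=Box([n * s, 10.0, 20.0]))


class TestUnwrapPeriodic:
    def test_single_wrap(self):
        out = unwrap_periodic([99.0, 100.0, 1.0, 2.0], 100.0)
        assert out == pytest.approx([99.0, 100.0, 101.0, 102.0])

    def test_identity_on_continuous_series(self):
        x = np.array([1.0, 2.5, 3.0, 2.0])
        assert unwrap_periodic(x, 100.0) == pytest.approx(x)

    def test_ambiguous_jump_is_error(self):
        with pytest.raises(SpectraError):
            unwrap_periodic([0.0, 50.0], 100.0)

    def test_trace_residual_is_periodic(self, sinusoid_membrane):
        frame, _ = sinusoid_membrane
        leaflets = mc.assign_leaflets(frame)
        ml = mc.trace_midline(frame, leaflets)
        sp = mc.midline_spectra(ml, lambda_c=0.0)
        x, _ = sp.reconstruct()
        resid = x - sp.offset_x - sp.slope_x * np.arange(sp.n) * sp.s
        assert abs(resid[-1] - resid[0]) < ml.s


class TestFilterContracts:
    def test_lambda_zero_is_identity(self):
        ml = circle_midline(20.0)
        sp = mc.midline_spectra(ml, lambda_c=0.0)
        x, z = sp.reconstruct()
        assert x == pytest.approx(ml.points[:, 0], abs=1e-9)
        assert z == pytest.approx(ml.points[:, 2], abs=1e-9)

    def test_passband_component_preserved(self):
        n, s = 120, 1.0
        l = np.arange(n) * s
        z = 10.0 + 3.0 * np.sin(2 * np.pi * l / 30.0)  # 30 nm wavelength
        pts = np.column_stack([l, np.full(n, 5.0), z])
        ml = Midline(points=pts, s=s, box=Box([n * s, 10.0, 20.0]))
        _, zf = mc.midline_spectra(ml, lambda_c=15.0).reconstruct()
        assert np.abs(zf - z).max() < 1e-8

    def test_stopband_component_removed(self):
        n, s = 120, 1.0
        l = np.arange(n) * s
        keep = 3.0 * np.sin(2 * np.pi * l / 30.0)
        kill = 0.5 * np.sin(2 * np.pi * l / 5.0)
        pts = np.column_stack([l, np.full(n, 5.0), 10.0 + keep + kill])
        ml = Midline(points=pts, s=s, box=Box([n * s, 10.0, 20.0]))
        _, zf = mc.midline_spectra(ml, lambda_c=15.0).reconstruct()
        assert np.abs(zf - (10.0 + keep)).max() < 1e-8

    def test_filter_is_idempotent_projection(self):
        rng = np.random.default_rng(3)
        n, s = 100, 1.0
        pts = np.column_stack([
            np.arange(n) * s, np.full(n, 5.0),
            10.0 + rng.normal(0, 0.5, n),
        ])
        ml = Midline(points=pts, s=s, box=Box([n * s, 10.0, 20.0]))
        sp1 = mc.midline_spectra(ml, lambda_c=15.0)
        x1, z1 = sp1.reconstruct()
        ml2 = Midline(points=np.column_stack([x1, pts[:, 1], z1]), s=s,
                      box=ml.box)
        sp2 = mc.midline_spectra(ml2, lambda_c=15.0)
        x2, z2 = sp2.reconstruct()
        assert x2 == pytest.approx(x1, abs=1e-9)
        assert z2 == pytest.approx(z1, abs=1e-9)

    def test_parseval_energy_never_increases(self):
        rng = np.random.default_rng(4)
        n, s = 128, 1.0
        pts = np.column_stack([
            np.arange(n) * s, np.full(n, 5.0),
            10.0 + rng.normal(0, 1.0, n),
        ])
        ml = Midline(points=pts, s=s, box=Box([n * s, 10.0, 20.0]))
        raw = mc.midline_spectra(ml, lambda_c=0.0)
        filt = mc.midline_spectra(ml, lambda_c=15.0)
        assert np.sum(np.abs(filt.S_Z) ** 2) <= np.sum(np.abs(raw.S_Z) ** 2)

    def test_too_few_points_is_error(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        ml = Midline(points=pts, s=1.0, box=Box([5.0, 10.0, 10.0]))
        with pytest.raises(SpectraError):
            mc.midline_spectra(ml)


class TestCurvatureProfile:
    def test_straight_line_has_zero_curvature(self):
        ml = synthetic_line_midline()
        prof = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=0.0))
        assert np.abs(prof.kappa).max() < 1e-10

    def test_circle_curvature_is_inverse_radius(self):
        ml = circle_midline(20.0)  # N = 126
        assert ml.n_points == 126
        prof = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=0.0))
        assert np.abs(prof.kappa) == pytest.approx(np.full(126, 0.05), rel=0.01)

    def test_sign_flips_under_orientation_reversal(self):
        ml = circle_midline(20.0)
        rev = Midline(points=ml.points[::-1].copy(), s=ml.s, box=ml.box)
        k_fwd = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=0.0)).kappa
        k_rev = mc.curvature_profile(mc.midline_spectra(rev, lambda_c=0.0)).kappa
        assert np.sign(k_fwd.mean()) == -np.sign(k_rev.mean())
        assert np.mean(np.abs(k_fwd)) == pytest.approx(np.mean(np.abs(k_rev)),
                                                       rel=1e-6)

    def test_sinusoid_crest_curvature(self):
        spec = mc.sinusoid_spec(5.0, 50.0, seed=11)
        frame, gt = mc.generate_membrane(spec)
        leaflets = mc.assign_leaflets(frame)
        ml = mc.trace_midline(frame, leaflets)
        prof = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=15.0))
        crest = 5.0 * (2 * np.pi / 50.0) ** 2  # A (2π/L)², slope = 0 at crest
        assert np.abs(prof.kappa).max() == pytest.approx(crest, rel=0.05)

    def test_spectral_derivative_matches_finite_differences(self):
        n, s = 200, 1.0
        l = np.arange(n) * s
        z = 10.0 + 4.0 * np.sin(2 * np.pi * l / 50.0) + np.cos(2 * np.pi * l / 25.0)
        pts = np.column_stack([l, np.full(n, 5.0), z])
        ml = Midline(points=pts, s=s, box=Box([n * s, 10.0, 20.0]))
        sp = mc.midline_spectra(ml, lambda_c=0.0)
        _, zd, _, _ = sp.derivatives()
        fd = (np.roll(z, -1) - np.roll(z, 1)) / (2 * s)
        # central differences carry O(s²) truncation error; compare both to
        # the analytic derivative instead of each other at 1e-3
        zd_true = (4.0 * 2 * np.pi / 50 * np.cos(2 * np.pi * l / 50)
                   - 2 * np.pi / 25 * np.sin(2 * np.pi * l / 25))
        assert np.abs(zd - zd_true).max() < 1e-9
        assert np.abs(fd - zd_true).max() < 0.05
        scale = np.abs(zd_true).max()
        assert np.abs(zd - fd).max() / scale < 0.05


class TestMeanCurvature:
    def test_circle_radius_16_7(self):
        ml = circle_midline(16.7)
        prof = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=15.0))
        assert mc.mean_curvature(prof) == pytest.approx(0.06, rel=0.01)

    def test_flat_is_zero(self):
        ml = synthetic_line_midline()
        prof = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=0.0))
        assert mc.mean_curvature(prof) < 1e-10

    def test_sinusoid_matches_quadrature(self):
        spec = mc.sinusoid_spec(5.0, 50.0, seed=12)
        frame, gt = mc.generate_membrane(spec)
        leaflets = mc.assign_leaflets(frame)
        ml = mc.trace_midline(frame, leaflets)
        prof = mc.curvature_profile(mc.midline_spectra(ml, lambda_c=15.0))
        l_dense = np.linspace(0, gt.arclength, 20001)
        quad = np.trapezoid(
            np.abs(gt.curve.curvature_at_arclength(l_dense)), l_dense
        ) / gt.arclength
        assert mc.mean_curvature(prof) == pytest.approx(quad, rel=0.02)


class TestCurvatureTimeseries:
    def test_flat_frames_give_zero(self):
        specs = [mc.preset("flat", seed=21)] * 3
        frames_gt, _ = mc.generate_trajectory(specs, frame_dt=4.0)
        table = mc.curvature_timeseries([f for f, _ in frames_gt])
        assert len(table) == 3
        assert (table["mean_abs_curvature"] < 1e-3).all()
        assert table["time"].tolist() == [0.0, 4.0, 8.0]

    def test_amplitude_ramp_increases_mean_curvature(self):
        amps = [1e-6, 1.5, 3.0, 4.5]  # same curve family keeps topology shared
        specs = [
            mc.SyntheticMembraneSpec(curve=mc.SinusoidCurve(a, 50.0), seed=22)
            for a in amps
        ]
        frames_gt, _ = mc.generate_trajectory(specs, frame_dt=4.0)
        table = mc.curvature_timeseries([f for f, _ in frames_gt])
        k = table["mean_abs_curvature"].to_numpy()
        assert np.all(np.diff(k) > -0.05 * k[1:])  # non-decreasing within 5%
        assert k[-1] > 5 * max(k[0], 1e-4)

    def test_single_frame(self, sinusoid_membrane):
        frame, _ = sinusoid_membrane
        table = mc.curvature_timeseries([frame])
        assert len(table) == 1

    def test_empty_trajectory_is_error(self):
        with pytest.raises(MemcurvError):
            mc.curvature_timeseries([])
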