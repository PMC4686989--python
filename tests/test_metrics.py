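"""Velocity-gradient estimation, vorticity, profiles, correlations."""

import numpy as np
import pytest

from camsim import Domain
from camsim.connectivity import build_triangulation
from camsim.metrics import (alignment_score, fluidisation_diagnostics,
                            mean_vorticity, radial_speed_profile,
                            rotation_sign, velocity_correlation,
                            velocity_gradient)


def rigid_rotation(points, omega):
    """v = omega ẑ × r."""
    return omega * np.column_stack([-points[:, 1], points[:, 0]])


class TestVelocityGradient:
    def test_rigid_rotation_recovered_exactly(self, rng):
        pts = rng.uniform(-5, 5, (40, 2))
        tri = build_triangulation(pts)
        f = velocity_gradient(pts, rigid_rotation(pts, 0.7), tri)
        assert np.allclose(f.vorticity, 0.7, atol=1e-12)
        assert np.allclose(f.shear_rate_xy, 0.0, atol=1e-12)

    def test_simple_shear(self, rng):
        gam = 0.4
        pts = rng.uniform(-5, 5, (40, 2))
        v = np.column_stack([gam * pts[:, 1], np.zeros(len(pts))])
        f = velocity_gradient(pts, v, build_triangulation(pts))
        assert np.allclose(f.gradients[:, 0, 1], gam, atol=1e-12)
        assert np.allclose(f.vorticity, -gam / 2, atol=1e-12)
        assert np.allclose(f.shear_rate_xy, gam / 2, atol=1e-12)
        assert np.allclose(f.principal_shear, gam / 2, atol=1e-12)

    def test_uniform_translation_zero(self, rng):
        pts = rng.uniform(-5, 5, (30, 2))
        v = np.tile([0.3, -1.2], (30, 1))
        f = velocity_gradient(pts, v, build_triangulation(pts))
        assert np.allclose(f.gradients, 0.0, atol=1e-12)

    def test_affine_field_exact_any_triangulation(self, rng):
        """The linear-shape-function estimator is exact on affine fields."""
        A = np.array([[0.3, -1.1], [0.8, 0.25]])
        for seed in range(3):
            r = np.random.default_rng(seed)
            pts = r.uniform(-3, 3, (25, 2))
            v = pts @ A.T + np.array([0.5, -0.2])
            f = velocity_gradient(pts, v, build_triangulation(pts))
            assert np.allclose(f.gradients, A, atol=1e-10)

    def test_principal_shear_frame_invariant(self, rng):
        pts = rng.uniform(-3, 3, (30, 2))
        A = np.array([[0.2, 0.9], [-0.4, -0.1]])
        v = pts @ A.T
        th = 0.6
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        f1 = velocity_gradient(pts, v, build_triangulation(pts))
        f2 = velocity_gradient(pts @ rot.T, v @ rot.T,
                               build_triangulation(pts @ rot.T))
        assert np.mean(f1.principal_shear) == pytest.approx(
            np.mean(f2.principal_shear), rel=1e-9)


class TestMeanVorticity:
    def test_rigid_rotation(self, lattice):
        pts = lattice(5.0, 0.5)
        f = velocity_gradient(pts, rigid_rotation(pts, -1.3),
                              build_triangulation(pts))
        assert mean_vorticity(f) == pytest.approx(-1.3)

    def test_sign_flips_under_reflection(self, rng):
        pts = rng.uniform(-4, 4, (50, 2))
        v = rigid_rotation(pts, 0.9)
        m = np.array([1.0, -1.0])
        f1 = velocity_gradient(pts, v, build_triangulation(pts))
        f2 = velocity_gradient(pts * m, v * m, build_triangulation(pts * m))
        assert mean_vorticity(f2) == pytest.approx(-mean_vorticity(f1))

    def test_uniform_tangential_speed_gives_v0_over_R(self, lattice):
        """Stokes: ½ (2πR v0)/(πR²) = v0/R for unit tangential flow."""
        pts = lattice(5.0, 0.25)
        pts = pts[np.linalg.norm(pts, axis=1) > 0.4]
        r = np.linalg.norm(pts, axis=1)
        v = np.column_stack([-pts[:, 1], pts[:, 0]]) / r[:, None]
        f = velocity_gradient(pts, v, build_triangulation(pts))
        assert mean_vorticity(f) == pytest.approx(1.0 / 5.0, rel=0.05)

    def test_annulus_rim_speeds(self, lattice):
        """Mean vorticity from any tangential profile matches the
        closed-form rim-speed expression on the annulus."""
        from camsim.theory import annulus_mean_vorticity

        R_out, R_in, v_out, v_in = 5.0, 2.5, 1.0, 0.4
        pts = lattice(R_out, 0.2)
        r = np.linalg.norm(pts, axis=1)
        keep = (r >= R_in) & (r <= R_out)
        pts, r = pts[keep], r[keep]
        speed = v_in + (v_out - v_in) * (r - R_in) / (R_out - R_in)
        v = speed[:, None] * np.column_stack([-pts[:, 1], pts[:, 0]]) / r[:, None]
        dom = Domain(kind="annulus", R=R_out, R_in=R_in)
        f = velocity_gradient(pts, v, build_triangulation(pts), domain=dom)
        expected = annulus_mean_vorticity(R_out, R_in, v_out, v_in)
        assert mean_vorticity(f) == pytest.approx(expected, rel=0.05)


class TestProfilesAndAlignment:
    def test_rigid_profile_linear(self, lattice):
        pts = lattice(5.0, 0.5)
        v = rigid_rotation(pts, 0.5)
        prof = radial_speed_profile(pts, v, np.arange(0, 5.5, 0.5))
        good = prof.dropna()
        fit = np.polyfit(good.r_mid, good.speed, 1)
        assert fit[0] == pytest.approx(0.5, rel=0.05)
        assert abs(fit[1]) < 0.05

    def test_flat_profile_for_uniform_tangential_speed(self, lattice):
        pts = lattice(5.0, 0.5)
        pts = pts[np.linalg.norm(pts, axis=1) > 0.4]
        r = np.linalg.norm(pts, axis=1)
        v = np.column_stack([-pts[:, 1], pts[:, 0]]) / r[:, None]
        prof = radial_speed_profile(pts, v, np.arange(0.5, 5.5, 0.5)).dropna()
        assert np.allclose(prof.speed, 1.0, atol=1e-9)

    def test_empty_bins_are_nan(self):
        pts = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        v = np.ones((3, 2))
        prof = radial_speed_profile(pts, v, np.array([0.0, 0.5, 1.5]))
        assert np.isnan(prof.speed.iloc[0])
        assert prof.speed.iloc[1] == pytest.approx(np.sqrt(2))

    def test_alignment_extremes(self, rng):
        v = rng.normal(size=(20, 2))
        vhat = v / np.linalg.norm(v, axis=1)[:, None]
        assert alignment_score(vhat, v) == pytest.approx(1.0)
        perp = np.column_stack([-vhat[:, 1], vhat[:, 0]])
        assert alignment_score(perp, v) == pytest.approx(0.0, abs=1e-12)


class TestVelocityCorrelation:
    def test_uniform_translation_degenerate(self, rng):
        pts = rng.uniform(-5, 5, (30, 2))
        v = np.tile([1.0, 0.5], (30, 1))
        _, length, degenerate = velocity_correlation(pts, v, np.arange(0, 12, 1.0))
        assert degenerate
        from scipy.spatial.distance import pdist
        assert length == pytest.approx(pdist(pts).max())

    def test_counter_rotating_halves_cross_zero_near_half_width(self, lattice):
        pts = lattice(6.0, 0.4)
        v = rigid_rotation(pts, 1.0)
        v[pts[:, 0] > 0] *= -1.0
        _, length, degenerate = velocity_correlation(pts, v, np.arange(0, 13, 0.5))
        assert not degenerate
        assert 2.0 < length < 8.0

    def test_rigid_disc_rotation_length_comparable_to_R(self, lattice):
        for R in (5.0, 10.0):
            pts = lattice(R, R / 8)
            v = rigid_rotation(pts, 1.0)
            _, length, _ = velocity_correlation(pts, v, np.arange(0, 2.2 * R, R / 10))
            assert 0.5 * R < length < 1.8 * R


class TestFluidisationDiagnostics:
    def test_equilateral_quality_and_symmetric_lengths(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        tri = build_triangulation(pts)
        d = fluidisation_diagnostics(pts, tri)
        assert d["triangle_quality"][0] == pytest.approx(1.0)
        assert d["spring_length_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_radial_distance_and_centroid(self, lattice):
        pts = lattice(4.0) + np.array([2.0, 0.0])
        tri = build_triangulation(pts)
        d = fluidisation_diagnostics(pts, tri, center=(2.0, 0.0))
        assert d["centroid"] == pytest.approx([2.0, 0.0], abs=1e-9)
        r = np.linalg.norm(pts - np.array([2.0, 0.0]), axis=1)
        assert d["mean_radial_distance"] == pytest.approx(r.mean())


class TestRotationSign:
    def test_sign_and_window(self):
        t = np.linspace(0, 10, 101)
        w = np.where(t < 5, 1.0, -1.0)
        assert rotation_sign(t, w, (6.0, 10.0)) == -1
        assert rotation_sign(t, w, (0.0, 4.0)) == 1


class TestSteadyPlateau:
    def test_detects_plateau_after_transient(self):
        from camsim.metrics import steady_plateau
        t = np.linspace(0, 30, 301)
        w = 0.25 * (1 - np.exp(-t / 3.0))      # saturating rise
        onset = steady_plateau(t, w, window=5.0, rel_tol=0.05)
        assert onset is not None
        assert 2.0 < onset < 20.0

    def test_no_plateau_in_linear_ramp(self):
        from camsim.metrics import steady_plateau
        t = np.linspace(0, 30, 301)
        assert steady_plateau(t, 0.1 * t, window=5.0, rel_tol=0.01) is None
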