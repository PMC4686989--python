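"""Spring forces, polarization alignment and the forward-Euler step."""

import numpy as np
import pytest

from camsim import Domain, ModelParams, TissueState
from camsim.connectivity import build_triangulation, force_neighbors
from camsim.dynamics import (net_forces, pairwise_forces, spring_forces, step,
                             update_polarization)


def make_state(positions, polar=None, motile=True):
    n = len(positions)
    if polar is None:
        polar = np.tile([1.0, 0.0], (n, 1))
    return TissueState(
        positions=np.asarray(positions, dtype=float),
        polarizations=np.asarray(polar, dtype=float),
        motile=np.full(n, motile),
        mobility_scale=np.ones(n),
        cycle=np.zeros(n),
        ids=np.arange(n, dtype=np.int64),
    )


def brute_force_oracle(positions, edges, params):
    """Slow per-pair re-evaluation of the piecewise spring law."""
    f = np.zeros_like(positions)
    for i, j in edges:
        d = positions[j] - positions[i]
        sep = np.linalg.norm(d)
        delta = sep - params.a0
        if params.cutoff_on == "deformation" and delta > params.d_max:
            continue
        k = params.k_c if delta <= 0 else params.k_t
        e = d / sep
        f[i] += k * delta * e
        f[j] -= k * delta * e
    return f


class TestSpringForces:
    def test_rest_length_pair_zero(self, params):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        f = spring_forces(pts, np.array([[0, 1]]), np.array([0.0]), params)
        assert np.all(f == 0)

    def test_compressed_pair_repels(self):
        """k_c |delta| = 10 * 0.5 = 5, pushing the two cells apart."""
        p = ModelParams(k_c=10.0, k_t=3.0)
        pts = np.array([[0.0, 0.0], [0.5, 0.0]])
        f = spring_forces(pts, np.array([[0, 1]]), np.array([-0.5]), p)
        assert f[0] == pytest.approx([-5.0, 0.0])
        assert f[1] == pytest.approx([5.0, 0.0])

    def test_equilateral_triangle_balanced(self, params):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        tri = build_triangulation(pts)
        edges, deform = force_neighbors(tri, pts, params)
        f = spring_forces(pts, edges, deform, params)
        assert np.allclose(f, 0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        p = ModelParams(k_c=7.0, k_t=2.5)
        pts = rng.uniform(-2.5, 2.5, (20, 2))
        tri = build_triangulation(pts)
        edges, deform = force_neighbors(tri, pts, p)
        f = spring_forces(pts, edges, deform, p)
        assert np.abs(f - brute_force_oracle(pts, tri.edges, p)).max() < 1e-12

    def test_reciprocity_random_frames(self, rng, params):
        for _ in range(5):
            pts = rng.uniform(-4, 4, (35, 2))
            tri = build_triangulation(pts)
            edges, deform = force_neighbors(tri, pts, params)
            f = spring_forces(pts, edges, deform, params)
            assert np.abs(f.sum(axis=0)).max() < 1e-12


class TestUpdatePolarization:
    def test_parallel_fixed_point(self):
        p = np.array([1.0, 0.0])
        out = update_polarization(p, np.array([2.0, 0.0]), xi=1.0, dt=0.01)
        assert out == pytest.approx(p)

    def test_antiparallel_unstable_fixed_point(self):
        p = np.array([-1.0, 0.0])
        out = update_polarization(p, np.array([2.0, 0.0]), xi=1.0, dt=0.01)
        assert out == pytest.approx(p)

    def test_zero_velocity_skipped(self):
        p = np.array([0.0, 1.0])
        out = update_polarization(p, np.zeros(2), xi=1.0, dt=0.01)
        assert out == pytest.approx(p)

    def test_closed_form_angle_decay(self):
        """dtheta/dt = -xi sin(theta)  =>  tan(theta/2) = tan(theta0/2) e^{-xi t}."""
        xi, dt, t_end = 1.0, 1e-4, 1.0
        p = np.array([0.0, 1.0])                  # theta0 = pi/2 from v̂ = +x
        v = np.array([1.0, 0.0])
        for _ in range(int(t_end / dt)):
            p = update_polarization(p, v, xi, dt)
        theta = np.arctan2(p[1], p[0])
        expected = 2 * np.arctan(np.tan(np.pi / 4) * np.exp(-xi * t_end))
        assert theta == pytest.approx(expected, abs=1e-3)

    def test_unit_norm_preserved(self, rng):
        p = rng.normal(size=(50, 2))
        p /= np.linalg.norm(p, axis=1)[:, None]
        v = rng.normal(size=(50, 2))
        out = update_polarization(p, v, xi=2.0, dt=0.05)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)


class TestStep:
    def test_isolated_motile_cell_advances_along_polarization(self):
        p = ModelParams(v0=1.0, dt=0.001)
        st = make_state(np.array([[0.0, 0.0], [50.0, 0.0], [25.0, 40.0]]),
                        polar=np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]))
        step(st, Domain(kind="unbounded"), p)
        assert st.positions[0] == pytest.approx([0.0, 0.001])

    def test_passive_cell_moves_by_mu_F_dt(self):
        p = ModelParams(v0=1.0, k_c=10.0, dt=0.001)
        # compressed pair (+ far third cell): passive cell 0 moves mu*F*dt
        pts = np.array([[0.0, 0.0], [0.5, 0.0], [25.0, 40.0]])
        st = make_state(pts, motile=False)
        tri = build_triangulation(pts)
        field = pairwise_forces(st, tri, p, Domain(kind="unbounded"))
        expected = pts[0] + p.mu * field.forces[0] * p.dt
        step(st, Domain(kind="unbounded"), p, tri)
        assert st.positions[0] == pytest.approx(expected)

    def test_equilibrated_passive_state_fixed_point(self, lattice):
        p = ModelParams(v0=0.0)
        pts = lattice(3.0)
        st = make_state(pts, motile=False)
        before = st.positions.copy()
        step(st, Domain(kind="unbounded"), p)
        assert np.allclose(st.positions, before, atol=1e-15)

    def test_euler_first_order_convergence(self, rng, lattice):
        """Halving dt roughly halves the endpoint error.

        A compressed, slightly jittered cluster keeps every spring away
        from the d_max cutoff and every quad away from cocircularity, so
        the right-hand side stays smooth over the test horizon.
        """
        base = lattice(1.6) * 0.92
        base += rng.uniform(-0.02, 0.02, base.shape)
        ang = rng.uniform(0, 2 * np.pi, len(base))
        polar = np.column_stack([np.cos(ang), np.sin(ang)])
        dom = Domain(kind="unbounded")

        def run(dt, t_end=0.05):
            p = ModelParams(v0=1.0, k_c=5.0, k_t=5.0, dt=dt)
            st = make_state(base.copy(), polar=polar.copy())
            for _ in range(int(round(t_end / dt))):
                step(st, dom, p)
            return st.positions

        ref = run(6.25e-5)
        e1 = np.abs(run(1e-3) - ref).max()
        e2 = np.abs(run(5e-4) - ref).max()
        assert e1 / e2 == pytest.approx(2.0, rel=0.4)

    def test_mirrored_initial_conditions_mirror_trajectories(self, rng):
        """Reflection symmetry: y -> -y flips the rotation direction."""
        p = ModelParams(v0=1.0, k_c=8.0, k_t=8.0, dt=0.001)
        dom = Domain(kind="disc", R=3.0)
        pts = rng.uniform(-2, 2, (25, 2))
        pts = pts[np.linalg.norm(pts, axis=1) < 2.8][:20]
        ang = rng.uniform(0, 2 * np.pi, len(pts))
        polar = np.column_stack([np.cos(ang), np.sin(ang)])
        mirror = np.array([1.0, -1.0])
        st1 = make_state(pts.copy(), polar=polar.copy())
        st2 = make_state(pts * mirror, polar=polar * mirror)
        for _ in range(300):
            step(st1, dom, p)
            step(st2, dom, p)
        assert np.allclose(st2.positions, st1.positions * mirror, atol=1e-10)
        assert np.allclose(st2.polarizations, st1.polarizations * mirror, atol=1e-10)

    def test_nonfinite_positions_reported(self):
        p = ModelParams(dt=0.001)
        st = make_state(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]))
        st.positions[1, 0] = np.inf
        with pytest.raises((FloatingPointError, ValueError)):
            step(st, Domain(kind="unbounded"), p)
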