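"""Overdamped dynamics: spring forces, polarization evolution, Euler step.

Each cell obeys  v_i = v0 p̂_i [motile] + mu F_i  with F_i the sum of
piecewise-linear spring forces from its Delaunay neighbours plus the
soft-wall force.  The polarization relaxes toward the velocity direction
at rate xi:  dp̂/dt = xi (p̂ × v̂ · ẑ) p̂⊥, i.e. the angle from v̂ to p̂
decays as dθ/dt = -xi sin θ.  Positions advance by forward Euler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import Triangulation, build_triangulation, force_neighbors
from .geometry import Domain, boundary_force
from .params import ModelParams
from .state import TissueState

__all__ = ["ForceField", "spring_forces", "net_forces", "pairwise_forces",
           "velocities", "update_polarization", "step"]

log = logging.getLogger(__name__)

_COINCIDENT_JITTER = 1e-9


@dataclass
class ForceField:
    """Per-cell net force and velocity at one instant."""

    forces: np.ndarray      # (n, 2)
    velocities: np.ndarray  # (n, 2)


def spring_forces(
    positions: np.ndarray,
    edges: np.ndarray,
    deform: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Net spring force per cell from the force-bearing edge list.

    Compressed springs (deformation <= 0) push with stiffness k_c,
    stretched ones (0 < deformation <= cutoff) pull with stiffness k_t.
    Newton's third law holds pairwise by construction.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    forces = np.zeros((n, 2))
    if len(edges) == 0:
        return forces
    i, j = edges[:, 0], edges[:, 1]
    dvec = positions[j] - positions[i]
    sep = deform + params.a0
    bad = sep <= 0
    if np.any(bad):
        log.warning("coincident cell centres on %d edge(s); applying +x jitter",
                    int(bad.sum()))
        dvec = dvec.copy()
        sep = sep.copy()
        dvec[bad] = (_COINCIDENT_JITTER * params.a0, 0.0)
        sep[bad] = _COINCIDENT_JITTER * params.a0
    k = np.where(deform <= 0, params.k_c, params.k_t)
    scale = k * deform / sep              # force on i, toward j when stretched
    fx = scale * dvec[:, 0]
    fy = scale * dvec[:, 1]
    forces[:, 0] = np.bincount(i, weights=fx, minlength=n) - \
        np.bincount(j, weights=fx, minlength=n)
    forces[:, 1] = np.bincount(i, weights=fy, minlength=n) - \
        np.bincount(j, weights=fy, minlength=n)
    return forces


def net_forces(
    positions: np.ndarray,
    edges: np.ndarray,
    deform: np.ndarray,
    params: ModelParams,
    domain: Domain,
) -> np.ndarray:
    """Spring forces plus the soft-wall boundary force."""
    f = spring_forces(positions, edges, deform, params)
    if domain.kind != "unbounded":
        f += boundary_force(positions, domain, params.k_c)
    return f


def velocities(state: TissueState, forces: np.ndarray, params: ModelParams) -> np.ndarray:
    """v_i = v0 p̂_i (motile cells) + mu * mobility_scale_i * F_i."""
    v = params.mu * state.mobility_scale[:, None] * forces
    v[state.motile] += params.v0 * state.polarizations[state.motile]
    return v


def pairwise_forces(
    state: TissueState,
    triangulation: Triangulation,
    params: ModelParams,
    domain: Domain,
) -> ForceField:
    """Convenience wrapper: forces and velocities for the current frame."""
    edges, deform = force_neighbors(triangulation, state.positions, params)
    f = net_forces(state.positions, edges, deform, params, domain)
    return ForceField(forces=f, velocities=velocities(state, f, params))


def update_polarization(
    polarizations: np.ndarray,
    vel: np.ndarray,
    xi: float,
    dt: float,
) -> np.ndarray:
    """One Euler step of the alignment rule, renormalized to unit length.

    Rows with zero velocity are left unchanged (the velocity direction is
    undefined there; no noise is injected).
    """
    p = np.atleast_2d(np.asarray(polarizations, dtype=float)).copy()
    v = np.atleast_2d(np.asarray(vel, dtype=float))
    speed = np.linalg.norm(v, axis=1)
    ok = speed > 1e-12
    if np.any(ok):
        vhat = v[ok] / speed[ok, None]
        cross = p[ok, 0] * vhat[:, 1] - p[ok, 1] * vhat[:, 0]   # p̂ × v̂ · ẑ
        perp = np.column_stack([-p[ok, 1], p[ok, 0]])           # p̂ rotated +90°
        p[ok] += dt * xi * cross[:, None] * perp
        p[ok] /= np.linalg.norm(p[ok], axis=1)[:, None]
    return p if polarizations.ndim == 2 else p[0]


def step(
    state: TissueState,
    domain: Domain,
    params: ModelParams,
    triangulation: Triangulation | None = None,
) -> TissueState:
    """Advance the tissue by one time step dt (in place).

    Order within a step: forces → velocities → position update →
    polarization update with the just-computed velocities → clock.  The
    caller owns the re-triangulation stride; when ``triangulation`` is
    None a fresh one is built for this step.
    """
    if triangulation is None:
        triangulation = build_triangulation(state.positions, time=state.time)
    field = pairwise_forces(state, triangulation, params, domain)
    state.positions += field.velocities * params.dt
    if not np.all(np.isfinite(state.positions)):
        bad = np.where(~np.isfinite(state.positions).all(axis=1))[0]
        raise FloatingPointError(
            f"non-finite position for cell id(s) {state.ids[bad][:5].tolist()} "
            f"at t={state.time:.3f}"
        )
    state.polarizations = update_polarization(
        state.polarizations, field.velocities, params.xi, params.dt
    )
    state.time += params.dt
    return state
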