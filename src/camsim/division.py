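"""Cell division: cycle progression, area gating and daughter placement.

A cell whose cycle number reaches 1 divides, provided its Voronoi area
exceeds a critical area (crowded cells defer, keeping the cycle
saturated).  The two daughters are placed symmetrically along the major
principal axis of the mother's Voronoi polygon and receive equal and
opposite polarizations in a fresh random direction (or two independent
random directions under the alternative policy).  Division stops when
the population reaches the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import VoronoiGeometry
from .params import DivisionPolicy
from .state import TissueState

__all__ = ["DivisionEvent", "assign_initial_cycles", "progress_cycles",
           "execute_divisions"]


@dataclass
class DivisionEvent:
    time: float
    mother_id: int
    daughter_ids: tuple[int, int]
    axis_angle: float


def assign_initial_cycles(
    state: TissueState, policy: DivisionPolicy, rng: np.random.Generator
) -> TissueState:
    """Seed cycle numbers: all 0 (synchronous) or uniform [0,1) (asynchronous)."""
    if policy.mode == "off":
        return state
    if policy.mode == "synchronous":
        state.cycle[:] = 0.0
    else:
        state.cycle[:] = rng.uniform(0.0, 1.0, size=state.n)
    return state


def progress_cycles(state: TissueState, dt: float, policy: DivisionPolicy) -> TissueState:
    """Advance every cycle by dt/T_div, saturating at 1."""
    if policy.mode == "off":
        return state
    np.minimum(state.cycle + dt / policy.T_div, 1.0, out=state.cycle)
    return state


def execute_divisions(
    state: TissueState,
    voronoi: VoronoiGeometry,
    policy: DivisionPolicy,
    rng: np.random.Generator,
    a0: float = 1.0,
) -> tuple[TissueState, list[DivisionEvent]]:
    """Divide every mature, large-enough cell; respect the population cap.

    Candidates are processed in cell-ID order; if dividing all of them
    would exceed ``n_cap``, the excess candidates are deferred with their
    cycles left saturated.  Each mother is replaced by two daughters at
    ±offset_each along her area major principal axis, with cycles reset
    to 0 and inherited motility/mobility.
    """
    if policy.mode == "off" or state.n >= policy.n_cap:
        return state, []
    mature = np.where((state.cycle >= 1.0) & (voronoi.areas > policy.area_min))[0]
    if len(mature) == 0:
        return state, []
    if len(voronoi.areas) != state.n:
        raise ValueError("Voronoi geometry is stale relative to the state")
    order = mature[np.argsort(state.ids[mature])]
    budget = policy.n_cap - state.n
    order = order[:budget]

    events: list[DivisionEvent] = []
    keep = np.ones(state.n, dtype=bool)
    new_pos, new_pol, new_motile, new_mob, new_ids = [], [], [], [], []
    next_id = state.next_id
    for i in order:
        axis = voronoi.major_axis(int(i))
        offset = policy.offset_each * a0
        r0 = state.positions[i]
        if policy.daughter_polarization == "opposite_random":
            ang = rng.uniform(0.0, 2 * np.pi)
            u = np.array([np.cos(ang), np.sin(ang)])
            pols = (u, -u)
        else:
            angs = rng.uniform(0.0, 2 * np.pi, size=2)
            pols = (np.array([np.cos(angs[0]), np.sin(angs[0])]),
                    np.array([np.cos(angs[1]), np.sin(angs[1])]))
        d_ids = (next_id, next_id + 1)
        next_id += 2
        for sgn, pol, did in zip((+1.0, -1.0), pols, d_ids):
            new_pos.append(r0 + sgn * offset * axis)
            new_pol.append(pol)
            new_motile.append(bool(state.motile[i]))
            new_mob.append(float(state.mobility_scale[i]))
            new_ids.append(did)
        keep[i] = False
        events.append(DivisionEvent(
            time=state.time,
            mother_id=int(state.ids[i]),
            daughter_ids=d_ids,
            axis_angle=float(np.arctan2(axis[1], axis[0])),
        ))

    state.positions = np.vstack([state.positions[keep], np.asarray(new_pos)])
    state.polarizations = np.vstack([state.polarizations[keep], np.asarray(new_pol)])
    state.motile = np.concatenate([state.motile[keep], np.asarray(new_motile, dtype=bool)])
    state.mobility_scale = np.concatenate([state.mobility_scale[keep], np.asarray(new_mob)])
    state.cycle = np.concatenate([state.cycle[keep], np.zeros(len(new_ids))])
    state.ids = np.concatenate([state.ids[keep], np.asarray(new_ids, dtype=np.int64)])
    state.next_id = next_id
    return state, events
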