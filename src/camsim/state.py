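"""Tissue state, random initialization and mechanical equilibration.

The tissue is a structure-of-arrays: positions (n, 2), unit polarization
vectors (n, 2), per-cell motility flags, mobility multipliers, cell-cycle
numbers and stable integer IDs.  IDs survive division and neighbour
changes, so lineage and T1 events are traceable across frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .geometry import Domain, boundary_force
from .params import ModelParams

__all__ = ["CellState", "TissueState", "initialize_tissue", "equilibrate",
           "EquilibrationError"]

log = logging.getLogger(__name__)


class CellState(NamedTuple):
    """Read-only view of one cell (see :class:`TissueState`)."""

    position: np.ndarray
    polarization: np.ndarray
    motile: bool
    mobility_scale: float
    cycle: float
    cell_type: str
    cell_id: int


@dataclass
class TissueState:
    """State of the whole monolayer at one instant."""

    positions: np.ndarray                 # (n, 2) float
    polarizations: np.ndarray             # (n, 2) float, unit rows
    motile: np.ndarray                    # (n,) bool
    mobility_scale: np.ndarray            # (n,) float
    cycle: np.ndarray                     # (n,) float in [0, 1]
    ids: np.ndarray                       # (n,) int64, stable
    time: float = 0.0
    next_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.polarizations = np.asarray(self.polarizations, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.next_id <= (self.ids.max() if len(self.ids) else -1):
            self.next_id = int(self.ids.max()) + 1 if len(self.ids) else 0

    @property
    def n(self) -> int:
        return len(self.positions)

    def cell(self, i: int) -> CellState:
        return CellState(
            position=self.positions[i],
            polarization=self.polarizations[i],
            motile=bool(self.motile[i]),
            mobility_scale=float(self.mobility_scale[i]),
            cycle=float(self.cycle[i]),
            cell_type="active" if self.motile[i] else "passive",
            cell_id=int(self.ids[i]),
        )

    def copy(self) -> "TissueState":
        return TissueState(
            positions=self.positions.copy(),
            polarizations=self.polarizations.copy(),
            motile=self.motile.copy(),
            mobility_scale=self.mobility_scale.copy(),
            cycle=self.cycle.copy(),
            ids=self.ids.copy(),
            time=self.time,
            next_id=self.next_id,
        )


class EquilibrationError(RuntimeError):
    """Raised when passive relaxation fails to bring speeds below tolerance."""

    def __init__(self, max_speed: float, steps: int):
        self.max_speed = max_speed
        self.steps = steps
        super().__init__(
            f"equilibration did not converge in {steps} steps "
            f"(final max speed {max_speed:.3e})"
        )


def _sample_uniform(n: int, domain: Domain, rng: np.random.Generator) -> np.ndarray:
    """Uniform rejection sampling of n points inside a bounded domain."""
    if domain.kind == "unbounded":
        raise ValueError("cannot sample uniformly in an unbounded domain")
    if domain.area() <= 0:
        raise ValueError("domain has zero area")
    out = np.empty((n, 2))
    filled = 0
    cx, cy = domain.center
    while filled < n:
        m = max(2 * (n - filled), 16)
        cand = rng.uniform(-domain.R, domain.R, size=(m, 2)) + (cx, cy)
        cand = cand[domain.contains(cand)]
        take = min(len(cand), n - filled)
        out[filled:filled + take] = cand[:take]
        filled += take
    return out


def initialize_tissue(
    n: int,
    domain: Domain,
    params: ModelParams,
    rng: np.random.Generator,
    cycle_mode: str | None = None,
) -> TissueState:
    """Place n cells uniformly at random in the domain.

    Polarizations get independent uniform-random angles.  ``cycle_mode``
    seeds the cell-cycle numbers: ``'synchronous'`` (all 0),
    ``'asynchronous'`` (uniform [0, 1)) or None (all 0, dormant).
    """
    if n < 3:
        raise ValueError("need at least 3 cells for a triangulation")
    positions = _sample_uniform(n, domain, rng)
    angles = rng.uniform(0.0, 2 * np.pi, size=n)
    polar = np.column_stack([np.cos(angles), np.sin(angles)])
    if cycle_mode == "asynchronous":
        cycle = rng.uniform(0.0, 1.0, size=n)
    else:
        cycle = np.zeros(n)
    return TissueState(
        positions=positions,
        polarizations=polar,
        motile=np.ones(n, dtype=bool),
        mobility_scale=np.ones(n),
        cycle=cycle,
        ids=np.arange(n, dtype=np.int64),
        next_id=n,
    )


def equilibrate(
    state: TissueState,
    domain: Domain,
    params: ModelParams,
    tol: float = 1e-3,
    max_steps: int = 1_000_000,
    stall_window: int = 20_000,
) -> TissueState:
    """Relax the packing passively (v0 treated as 0) until near rest.

    Steps the overdamped dynamics with self-propulsion off until the
    largest cell speed |mu F_i| drops below ``tol`` (in v0 units).
    Idempotent for converged packings: re-running performs 0 steps.

    Over-confluent packings cannot reach mechanical silence: Delaunay
    flips keep re-wiring the springs, so the max speed stalls at a
    residual floor (a precursor of fluidisation).  When the best speed
    seen has not improved by 5% within ``stall_window`` steps, the state
    is accepted at that floor.  Exhausting ``max_steps`` without either
    exit raises :class:`EquilibrationError`.
    """
    from .connectivity import build_triangulation, force_neighbors
    from .dynamics import net_forces

    state = state.copy()
    if state.n == 1:
        return state
    mob = params.mu * state.mobility_scale[:, None]
    best = np.inf
    best_step = 0
    # the triangulation can only change when points actually move; rebuild
    # once the cumulative displacement since the last build is appreciable
    rebuild_threshold = 0.005 * params.a0
    tri = None
    anchor = None
    for step_count in range(max_steps + 1):
        if state.n >= 3:
            if tri is None or np.max(np.abs(state.positions - anchor)) > rebuild_threshold:
                tri = build_triangulation(state.positions)
                anchor = state.positions.copy()
            edges, deform = force_neighbors(tri, state.positions, params)
        else:  # a lone pair: the single spring is the whole network
            edges = np.array([[0, 1]], dtype=np.intp)
            sep = float(np.linalg.norm(state.positions[1] - state.positions[0]))
            deform = np.array([sep - params.a0])
            limit = params.d_max if params.cutoff_on == "deformation" \
                else params.d_max - params.a0
            if deform[0] > limit:
                edges, deform = np.empty((0, 2), dtype=np.intp), np.empty(0)
        forces = net_forces(state.positions, edges, deform, params, domain)
        vel = mob * forces
        max_speed = float(np.max(np.linalg.norm(vel, axis=1))) if state.n else 0.0
        if max_speed < tol:
            return state
        if max_speed < 0.95 * best:
            best = max_speed
            best_step = step_count
        elif step_count - best_step > stall_window:
            log.info("equilibration stalled at max speed %.3e after %d steps "
                     "(flip-frustrated packing); accepting state",
                     max_speed, step_count)
            return state
        if step_count == max_steps:
            raise EquilibrationError(max_speed, max_steps)
        state.positions += vel * params.dt
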