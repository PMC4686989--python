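"""Model parameters, division policy and run configuration.

All quantities are expressed in simulation units: lengths in units of the
spring rest length a0, time in units of a0/v0 and force in units of
v0/mu.  With the physiological anchors a0 = 20 um and v0 = 20 um/hr one
simulation time unit is one hour (see :mod:`camsim.theory` for the
conversions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .geometry import Domain

__all__ = ["ModelParams", "DivisionPolicy", "RunConfig"]

# default critical Voronoi area for division: half the relaxed hexagonal
# cell area (sqrt(3)/2 a0^2) of a triangular packing at rest length.
_HEX_AREA = 3**0.5 / 2


@dataclass
class ModelParams:
    """Mechanical and dynamical parameters of the cell-centre model.

    a0      spring rest length (length; sets the unit of length)
    v0      self-propelled speed of a motile cell (length/time)
    mu      substrate mobility: velocity per unit force (length/(force*time))
    k_c     compressive spring stiffness — bulk cell stiffness (force/length)
    k_t     tensile spring stiffness — cell-cell cohesivity (force/length)
    d_max   cutoff on spring deformation beyond which no force is
            transferred (length); default 1.3*a0
    xi      polarization coordination constant: rate at which p̂ turns
            toward the velocity direction (1/time)
    dt      forward-Euler time step (time)
    cutoff_on  'deformation' (default): an edge is broken when
            |r_j - r_i| - a0 > d_max; 'separation': when |r_j - r_i| > d_max.
    """

    a0: float = 1.0
    v0: float = 1.0
    mu: float = 1.0
    k_c: float = 10.0
    k_t: float = 10.0
    d_max: Optional[float] = None
    xi: float = 1.0
    dt: float = 0.001
    seed: int = 0
    cutoff_on: str = "deformation"

    def __post_init__(self) -> None:
        if self.d_max is None:
            self.d_max = 1.3 * self.a0
        if not (self.a0 > 0 and self.mu > 0 and self.dt > 0 and self.d_max > 0):
            raise ValueError("a0, mu, dt, d_max must be positive")
        if self.v0 < 0 or self.k_c < 0 or self.k_t < 0 or self.xi < 0:
            raise ValueError("v0, k_c, k_t, xi must be non-negative")
        if self.cutoff_on not in ("deformation", "separation"):
            raise ValueError("cutoff_on must be 'deformation' or 'separation'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        keys = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in keys})


@dataclass
class DivisionPolicy:
    """Cell-division rules.

    mode     'synchronous' (all cycles start at 0), 'asynchronous'
             (cycles start uniform in [0,1)) or 'off'
    T_div    cell-cycle duration (time units = hours); default 24
    n_cap    population cap: division stops once n reaches this
    area_min critical Voronoi area below which a mature cell defers
             division (length^2)
    daughter_polarization 'opposite_random' (±û, fresh random û) or
             'independent_random'
    offset_each  displacement of each daughter from the mother along the
             mother's area major principal axis; default a0/4 so the
             inter-daughter separation is a0/2
    """

    mode: str = "off"
    T_div: float = 24.0
    n_cap: int = 80
    area_min: float = 0.5 * _HEX_AREA
    daughter_polarization: str = "opposite_random"
    offset_each: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("synchronous", "asynchronous", "off"):
            raise ValueError(f"unknown division mode {self.mode!r}")
        if not self.T_div > 0:
            raise ValueError("T_div must be positive")
        if self.area_min < 0:
            raise ValueError("area_min must be non-negative")
        if self.daughter_polarization not in ("opposite_random", "independent_random"):
            raise ValueError("unknown daughter_polarization")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DivisionPolicy":
        keys = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in keys})


@dataclass
class RunConfig:
    """Full description of one simulation run.

    Scenario events (division window, confinement removal, connectivity
    lock) are given as times on the production clock, which starts at 0
    when motility is switched on after equilibration.
    """

    params: ModelParams = field(default_factory=ModelParams)
    domain: Domain = field(default_factory=Domain)
    n: int = 140
    t_end: float = 40.0
    record_stride: int = 100          # steps between recorded frames
    triangulation_stride: int = 1     # steps between connectivity updates
    equilibration_tol: float = 1e-3   # max |mu F| at exit, in v0 units
    equilibration_max_steps: int = 1_000_000
    division: DivisionPolicy = field(default_factory=DivisionPolicy)
    division_start: Optional[float] = None   # enable cycles at this time
    confinement_removal_time: Optional[float] = None
    lock_window: Optional[tuple[float, float]] = None  # freeze edge list
    motile_fraction: float = 1.0
    v0_passive_mobility_ratio: float = 1.0   # >1: passive cells feel more friction
    passive_layout: Optional[str] = None     # None | 'annular' | 'center' | 'periphery'
    n_active: Optional[int] = None           # used with passive_layout

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "domain": self.domain.to_dict(),
            "division": self.division.to_dict(),
        }
        for f in dataclasses.fields(self):
            if f.name in d:
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        kwargs["params"] = ModelParams.from_dict(d.pop("params", {}))
        kwargs["domain"] = Domain.from_dict(d.pop("domain", {}))
        kwargs["division"] = DivisionPolicy.from_dict(d.pop("division", {}))
        keys = {f.name for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k in keys:
                if k == "lock_window" and v is not None:
                    v = tuple(v)
                kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))
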