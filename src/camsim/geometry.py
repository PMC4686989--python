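"""Confinement domains and the soft-wall restoring force.

Micropatterned substrates confine the monolayer to a disc or an annulus.
The wall is soft: a cell centre that crosses the pattern edge feels a
linear restoring force of stiffness ``3 k_c`` pointing back into the
allowed region.  Removing the confinement (invasion experiments) swaps
the domain for an unbounded one, for which the wall force is identically
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Domain", "penetration", "boundary_force", "remove_confinement"]

# Wall stiffness multiplier relative to the compressive cell stiffness k_c.
WALL_STIFFNESS_FACTOR = 3.0


@dataclass(frozen=True)
class Domain:
    """A confinement geometry: ``disc``, ``annulus`` or ``unbounded``.

    Lengths are in rest-length (a0) units.  ``R`` is the outer radius,
    ``R_in`` the inner radius (annulus only), ``center`` the pattern
    centre.
    """

    kind: str = "disc"
    R: float = 5.0
    R_in: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "annulus", "unbounded"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.kind == "disc" and not self.R > 0:
            raise ValueError("disc requires R > 0")
        if self.kind == "annulus" and not (0 < self.R_in < self.R):
            raise ValueError("annulus requires 0 < R_in < R")

    @property
    def thickness(self) -> float:
        """Annulus thickness t = R - R_in (R for a disc)."""
        return self.R - self.R_in

    def area(self) -> float:
        if self.kind == "disc":
            return float(np.pi * self.R**2)
        if self.kind == "annulus":
            return float(np.pi * (self.R**2 - self.R_in**2))
        return float("inf")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the allowed region."""
        positions = np.atleast_2d(positions)
        if self.kind == "unbounded":
            return np.ones(len(positions), dtype=bool)
        r = np.linalg.norm(positions - np.asarray(self.center), axis=1)
        inside = r <= self.R
        if self.kind == "annulus":
            inside &= r >= self.R_in
        return inside

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "R": self.R,
            "R_in": self.R_in,
            "center": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Domain":
        return cls(
            kind=d.get("kind", "disc"),
            R=float(d.get("R", 5.0)),
            R_in=float(d.get("R_in", 0.0)),
            center=tuple(d.get("center", (0.0, 0.0))),
        )


def penetration(positions: np.ndarray, domain: Domain):
    """Depth past the wall and inward unit normal, per position.

    Returns ``(depth, normal)`` with ``depth`` shape (n,) and ``normal``
    shape (n, 2).  Interior points have depth 0 (normal rows are then
    meaningless and set to 0).  For an annulus, a point exactly at the
    centre has an undefined normal; the tie is broken deterministically
    toward +x.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    depth = np.zeros(n)
    normal = np.zeros((n, 2))
    if domain.kind == "unbounded":
        return depth, normal

    rel = positions - np.asarray(domain.center, dtype=float)
    r = np.linalg.norm(rel, axis=1)

    out = r > domain.R
    if np.any(out):
        depth[out] = r[out] - domain.R
        normal[out] = -rel[out] / r[out, None]

    if domain.kind == "annulus":
        inner = r < domain.R_in
        if np.any(inner):
            depth[inner] = domain.R_in - r[inner]
            safe = r > 0
            idx = inner & safe
            normal[idx] = rel[idx] / r[idx, None]
            # centre point: radially outward normal, tie-broken along +x
            centre = inner & ~safe
            normal[centre] = (1.0, 0.0)
    return depth, normal


def boundary_force(positions: np.ndarray, domain: Domain, k_c: float) -> np.ndarray:
    """Soft-wall force 3·k_c·depth·n̂ on each cell centre (shape (n, 2))."""
    depth, normal = penetration(positions, domain)
    return WALL_STIFFNESS_FACTOR * k_c * depth[:, None] * normal


def remove_confinement(domain: Domain) -> Domain:
    """Replace a bounded domain by the unbounded one (both annulus walls go)."""
    return Domain(kind="unbounded", R=domain.R, R_in=0.0, center=domain.center)
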