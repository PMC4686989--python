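"""Cell-cell connectivity: Delaunay triangulation, force-bearing edges,
Voronoi cell geometry with boundary dummy points, and T1 counting.

Connectivity is rebuilt from the cell centres by Delaunay triangulation
(Qhull via scipy); neighbour exchanges between consecutive rebuilds are
the model's T1 transitions.  The dual Voronoi polygons stand in for cell
shapes; a dense ring of dummy points just outside the confinement keeps
boundary polygons finite, and the polygons are clipped to the domain.
Dummy points never enter the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, Voronoi
from shapely.geometry import Point, Polygon

from .geometry import Domain
from .params import ModelParams

__all__ = [
    "Triangulation",
    "VoronoiGeometry",
    "build_triangulation",
    "force_neighbors",
    "voronoi_geometry",
    "count_t1_events",
    "triangle_quality",
]


@dataclass
class Triangulation:
    """Delaunay triangulation of the cell centres at one frame."""

    triangles: np.ndarray    # (m, 3) int, vertex indices into positions
    edges: np.ndarray        # (e, 2) int, sorted unordered pairs
    time: float = 0.0

    def neighbor_lists(self) -> dict[int, set[int]]:
        nbrs: dict[int, set[int]] = {}
        for i, j in self.edges:
            nbrs.setdefault(int(i), set()).add(int(j))
            nbrs.setdefault(int(j), set()).add(int(i))
        return nbrs


@dataclass
class VoronoiGeometry:
    """Clipped Voronoi polygons of all cells, with derived shape measures."""

    polygons: list[np.ndarray]        # per-cell (k, 2) vertex rings
    areas: np.ndarray                 # (n,)
    second_moments: np.ndarray        # (n, 2, 2) area moments about centroid
    edge_lengths: list[np.ndarray]    # per-cell polygon edge lengths

    def major_axis(self, i: int) -> np.ndarray:
        """Unit eigenvector of the larger area second moment (elongation axis)."""
        w, v = np.linalg.eigh(self.second_moments[i])
        return v[:, int(np.argmax(w))]


def build_triangulation(positions: np.ndarray, time: float = 0.0) -> Triangulation:
    """Delaunay-triangulate the point set (raises on < 3 or collinear points)."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 3:
        raise ValueError("triangulation needs at least 3 points")
    try:
        tri = Delaunay(positions)
    except Exception as exc:  # Qhull degenerate input
        raise ValueError(f"degenerate point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate (collinear) point set")
    simplices = np.sort(tri.simplices, axis=1)
    # dedupe undirected edges via integer keys (cheaper than unique(axis=0))
    n = len(positions)
    pairs = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [0, 2]], simplices[:, [1, 2]]]
    )
    keys = np.unique(pairs[:, 0].astype(np.int64) * n + pairs[:, 1])
    edges = np.column_stack([keys // n, keys % n])
    return Triangulation(triangles=simplices, edges=edges, time=time)


def force_neighbors(
    triangulation: Triangulation,
    positions: np.ndarray,
    params: ModelParams,
):
    """Delaunay edges that transfer force, with their spring deformations.

    Deformation is delta = |r_j - r_i| - a0.  Edges beyond the cutoff are
    dropped: delta > d_max under the default deformation cutoff, or
    separation > d_max under the 'separation' convention.  Returns
    ``(edges, deformation)`` where edges is (e, 2) and deformation (e,).
    """
    positions = np.asarray(positions, dtype=float)
    edges = triangulation.edges
    d = positions[edges[:, 1]] - positions[edges[:, 0]]
    sep = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
    deform = sep - params.a0
    if params.cutoff_on == "deformation":
        keep = deform <= params.d_max
    else:
        keep = sep <= params.d_max
    return edges[keep], deform[keep]


def _dummy_ring(R: float, a0: float, center) -> np.ndarray:
    m = max(8, int(np.ceil(2 * np.pi * R / (a0 / 2))))
    th = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    return np.column_stack([R * np.cos(th), R * np.sin(th)]) + np.asarray(center)


def _polygon_moments(verts: np.ndarray):
    """Area, centroid and second area moments about the centroid.

    Standard Green's-theorem formulas for a simple polygon; vertex ring
    may be CW or CCW (signs cancel).
    """
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if a == 0:
        return 0.0, np.zeros(2), np.zeros((2, 2))
    cx = ((x + x1) * cross).sum() / (6 * a)
    cy = ((y + y1) * cross).sum() / (6 * a)
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    sgn = np.sign(a)
    area = abs(a)
    # translate raw moments (about origin) to the centroid; restore sign
    mxx = sgn * ixx - area * cx * cx
    myy = sgn * iyy - area * cy * cy
    mxy = sgn * ixy - area * cx * cy
    return area, np.array([cx, cy]), np.array([[mxx, mxy], [mxy, myy]])


def voronoi_geometry(
    positions: np.ndarray,
    domain: Domain,
    params: ModelParams | None = None,
) -> VoronoiGeometry:
    """Voronoi polygon per cell, clipped to the confinement.

    A ring of dummy points at R + a0/2 (and R_in - a0/2 for an annulus)
    with angular spacing a0/2 closes the boundary polygons; for an
    unbounded state the ring is placed just outside the current cloud.
    The dummy points only shape the tessellation — they carry no
    dynamics.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 3:
        raise ValueError("voronoi geometry needs at least 3 cells")
    a0 = params.a0 if params is not None else 1.0

    if domain.kind == "unbounded":
        c = positions.mean(axis=0)
        R_eff = float(np.max(np.linalg.norm(positions - c, axis=1))) + 2 * a0
        clip = Point(*c).buffer(R_eff, quad_segs=90)
        dummies = _dummy_ring(R_eff + a0 / 2, a0, c)
    else:
        clip = Point(*domain.center).buffer(domain.R, quad_segs=90)
        dummies = _dummy_ring(domain.R + a0 / 2, a0, domain.center)
        if domain.kind == "annulus":
            clip = clip.difference(Point(*domain.center).buffer(domain.R_in, quad_segs=90))
            inner_r = max(domain.R_in - a0 / 2, a0 / 4)
            dummies = np.vstack([dummies, _dummy_ring(inner_r, a0, domain.center)])

    vor = Voronoi(np.vstack([positions, dummies]))
    polygons: list[np.ndarray] = []
    areas = np.zeros(n)
    moments = np.zeros((n, 2, 2))
    edge_lengths: list[np.ndarray] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            # boundary polygon unexpectedly open despite the dummy ring
            polygons.append(np.empty((0, 2)))
            edge_lengths.append(np.empty(0))
            continue
        raw = vor.vertices[region]
        # fast path: polygons wholly inside the domain need no clipping
        rr = np.linalg.norm(raw - np.asarray(domain.center if domain.kind != "unbounded"
                                             else positions.mean(axis=0)), axis=1)
        # outer circle is convex: all vertices inside => polygon inside.
        # the inner hole is not: an edge chord can dip below R_in by up to
        # L^2/(8 R_in), so keep a safety margin there.
        needs_clip = domain.kind != "unbounded" and (
            np.any(rr > domain.R) or
            (domain.kind == "annulus" and np.any(rr < domain.R_in + 0.1 * a0)))
        if needs_clip:
            clipped = Polygon(raw).intersection(clip)
            if clipped.is_empty or clipped.geom_type != "Polygon":
                polygons.append(np.empty((0, 2)))
                edge_lengths.append(np.empty(0))
                continue
            verts = np.asarray(clipped.exterior.coords)[:-1]
        else:
            verts = raw
        polygons.append(verts)
        area, _, mom = _polygon_moments(verts)
        areas[i] = area
        moments[i] = mom
        edge_lengths.append(np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1))
    return VoronoiGeometry(
        polygons=polygons, areas=areas, second_moments=moments,
        edge_lengths=edge_lengths,
    )


def count_t1_events(prev: Triangulation, next: Triangulation,
                    prev_ids: np.ndarray | None = None,
                    next_ids: np.ndarray | None = None) -> int:
    """Number of Delaunay edges lost between two frames (edge flips).

    Edges are compared on stable cell IDs when ID arrays are given;
    otherwise positional indices must refer to the same cells.  Frames
    with different cell populations are rejected.
    """
    if prev_ids is not None or next_ids is not None:
        if prev_ids is None or next_ids is None:
            raise ValueError("provide both ID arrays or neither")
        if set(prev_ids.tolist()) != set(next_ids.tolist()):
            raise ValueError("triangulations cover different cell populations")
        e_prev = np.sort(np.asarray(prev_ids)[prev.edges], axis=1)
        e_next = np.sort(np.asarray(next_ids)[next.edges], axis=1)
    else:
        e_prev, e_next = prev.edges, next.edges
    prev_set = set(map(tuple, e_prev.tolist()))
    next_set = set(map(tuple, e_next.tolist()))
    return len(prev_set - next_set)


def triangle_quality(positions: np.ndarray, triangulation: Triangulation) -> np.ndarray:
    """Shape regularity Q = 4*sqrt(3)*A / (l1^2 + l2^2 + l3^2) per triangle.

    Q = 1 exactly for an equilateral triangle and < 1 otherwise.
    """
    p = np.asarray(positions, dtype=float)
    t = triangulation.triangles
    a = p[t[:, 1]] - p[t[:, 0]]
    b = p[t[:, 2]] - p[t[:, 0]]
    c = p[t[:, 2]] - p[t[:, 1]]
    area = 0.5 * np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    ssq = (a**2).sum(1) + (b**2).sum(1) + (c**2).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ssq > 0, 4 * np.sqrt(3.0) * area / ssq, 0.0)
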