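"""Observables of the rotating monolayer.

The velocity-gradient field is estimated per Delaunay triangle by linear
interpolation of the three nodal velocities (linear shape functions), so
any affine velocity field is recovered exactly.  Scalars derived from it
follow the area-weighted integral convention: mean vorticity is
∫ω dA / ∫dA with ω = ½(∂v_y/∂x − ∂v_x/∂y), counter-clockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import Triangulation, VoronoiGeometry, triangle_quality

__all__ = [
    "VelocityGradientField",
    "velocity_gradient",
    "mean_vorticity",
    "radial_speed_profile",
    "alignment_score",
    "velocity_correlation",
    "fluidisation_diagnostics",
    "rotation_sign",
    "steady_plateau",
]

_DEGENERATE_AREA = 1e-12


@dataclass
class VelocityGradientField:
    """Per-triangle constant velocity gradients and derived invariants."""

    gradients: np.ndarray    # (m, 2, 2), G[a, b] = ∂v_a/∂x_b
    areas: np.ndarray        # (m,)
    n_degenerate: int = 0

    @property
    def vorticity(self) -> np.ndarray:
        """ω = ½(∂v_y/∂x − ∂v_x/∂y), CCW positive, per triangle."""
        return 0.5 * (self.gradients[:, 1, 0] - self.gradients[:, 0, 1])

    @property
    def shear_rate_xy(self) -> np.ndarray:
        """ε̇_xy = ½(∂v_x/∂y + ∂v_y/∂x) per triangle."""
        return 0.5 * (self.gradients[:, 0, 1] + self.gradients[:, 1, 0])

    @property
    def principal_shear(self) -> np.ndarray:
        """Max shear of the rate-of-deformation tensor: ½(λ1 − λ2).

        Equals sqrt(((D_xx − D_yy)/2)² + D_xy²); invariant under rigid
        rotation of the frame.
        """
        dxx = self.gradients[:, 0, 0]
        dyy = self.gradients[:, 1, 1]
        dxy = self.shear_rate_xy
        return np.sqrt(((dxx - dyy) / 2.0) ** 2 + dxy**2)


def velocity_gradient(
    positions: np.ndarray,
    velocities: np.ndarray,
    triangulation: Triangulation,
    domain=None,
) -> VelocityGradientField:
    """Per-triangle velocity gradient from linear shape functions.

    Solves  [r2-r1, r3-r1]ᵀ Gᵀ = [v2-v1, v3-v1]ᵀ  on each triangle;
    near-zero-area triangles are excluded (their count is reported).
    When a bounded ``domain`` is given, triangles whose centroid falls
    outside it are dropped — the Delaunay hull of an annular tissue spans
    the lumen with triangles that carry no tissue.
    """
    p = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    t = triangulation.triangles
    if domain is not None and domain.kind != "unbounded":
        centroids = (p[t[:, 0]] + p[t[:, 1]] + p[t[:, 2]]) / 3.0
        t = t[domain.contains(centroids)]
        if len(t) == 0:
            raise ValueError("no triangles inside the domain")
    dr = np.stack([p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]]], axis=1)  # (m,2,2)
    dv = np.stack([v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]], axis=1)
    det = dr[:, 0, 0] * dr[:, 1, 1] - dr[:, 0, 1] * dr[:, 1, 0]
    areas = 0.5 * np.abs(det)
    ok = areas > _DEGENERATE_AREA
    n_bad = int((~ok).sum())
    if not np.any(ok):
        raise ValueError("all triangles are degenerate; cannot estimate gradients")
    # G = (dv)ᵀ (dr)⁻¹ per triangle, written out with the 2x2 inverse
    inv = np.empty_like(dr[ok])
    d = det[ok]
    inv[:, 0, 0] = dr[ok][:, 1, 1] / d
    inv[:, 0, 1] = -dr[ok][:, 0, 1] / d
    inv[:, 1, 0] = -dr[ok][:, 1, 0] / d
    inv[:, 1, 1] = dr[ok][:, 0, 0] / d
    # dv_k = G dr_k  =>  Gᵀ = DR⁻¹ DV (rows of DR/DV are the edge vectors)
    g_t = np.einsum("mij,mjk->mik", inv, dv[ok])
    grads = np.transpose(g_t, (0, 2, 1))             # grads[m, a, b] = ∂v_a/∂x_b

    return VelocityGradientField(gradients=grads, areas=areas[ok], n_degenerate=n_bad)


def mean_vorticity(field: VelocityGradientField) -> float:
    """Area-weighted mean vorticity ∫ω dA / ∫dA (CCW positive)."""
    total = field.areas.sum()
    if not total > 0:
        raise ValueError("zero total triangulated area")
    return float(np.sum(field.vorticity * field.areas) / total)


def radial_speed_profile(
    positions: np.ndarray,
    velocities: np.ndarray,
    bins: np.ndarray,
    center=(0.0, 0.0),
    shear: np.ndarray | None = None,
    shear_positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bin-averaged |v| versus radial distance (and optional shear profile).

    Frames may be concatenated before calling; empty bins yield NaN
    rather than zero.  ``shear`` values (e.g. per-triangle principal
    shear) are binned by their own positions (e.g. triangle centroids).
    """
    p = np.atleast_2d(positions)
    v = np.atleast_2d(velocities)
    r = np.linalg.norm(p - np.asarray(center), axis=1)
    speed = np.linalg.norm(v, axis=1)
    idx = np.digitize(r, bins) - 1
    nb = len(bins) - 1
    rows = []
    for b in range(nb):
        sel = idx == b
        rows.append({
            "r_mid": 0.5 * (bins[b] + bins[b + 1]),
            "speed": float(np.mean(speed[sel])) if np.any(sel) else np.nan,
            "n": int(sel.sum()),
        })
    out = pd.DataFrame(rows)
    if shear is not None:
        rs = np.linalg.norm(np.atleast_2d(shear_positions) - np.asarray(center), axis=1)
        sidx = np.digitize(rs, bins) - 1
        out["principal_shear"] = [
            float(np.mean(shear[sidx == b])) if np.any(sidx == b) else np.nan
            for b in range(nb)
        ]
    return out


def alignment_score(polarizations: np.ndarray, velocities: np.ndarray) -> float:
    """Mean p̂·v̂ over cells with nonzero speed (NaN if none are eligible)."""
    p = np.atleast_2d(polarizations)
    v = np.atleast_2d(velocities)
    speed = np.linalg.norm(v, axis=1)
    ok = speed > 1e-12
    if not np.any(ok):
        return float("nan")
    vhat = v[ok] / speed[ok, None]
    return float(np.mean(np.sum(p[ok] * vhat, axis=1)))


def velocity_correlation(
    positions: np.ndarray,
    velocities: np.ndarray,
    r_bins: np.ndarray,
    subtract_mean: bool = True,
):
    """Spatial autocorrelation of velocity fluctuations and its length.

    C(r) = <δv_i · δv_j>_{|r_i-r_j| in bin} / <|δv|²>, with C(0) = 1 by
    normalization.  The correlation length is the first zero crossing of
    C(r) (linearly interpolated), or the maximum pair distance when C
    never crosses zero.  Returns ``(DataFrame, length, degenerate)``.
    """
    from scipy.spatial.distance import pdist

    p = np.atleast_2d(positions)
    v = np.atleast_2d(velocities).astype(float)
    if len(p) < 2:
        raise ValueError("need at least two cells")
    dv = v - v.mean(axis=0) if subtract_mean else v
    var = float(np.mean(np.sum(dv * dv, axis=1)))
    d = pdist(p)
    max_pair = float(d.max())
    if var < 1e-24:
        empty = pd.DataFrame({"r_mid": [], "C": [], "n": []})
        return empty, max_pair, True
    iu, ju = np.triu_indices(len(p), k=1)
    dots = np.sum(dv[iu] * dv[ju], axis=1)
    idx = np.digitize(d, r_bins) - 1
    rows = []
    for b in range(len(r_bins) - 1):
        sel = idx == b
        rows.append({
            "r_mid": 0.5 * (r_bins[b] + r_bins[b + 1]),
            "C": float(np.mean(dots[sel]) / var) if np.any(sel) else np.nan,
            "n": int(sel.sum()),
        })
    df = pd.DataFrame(rows)
    length = max_pair
    valid = df.dropna(subset=["C"]).reset_index(drop=True)
    for k in range(1, len(valid)):
        c0, c1 = valid.loc[k - 1, "C"], valid.loc[k, "C"]
        if c0 > 0 >= c1:
            r0, r1 = valid.loc[k - 1, "r_mid"], valid.loc[k, "r_mid"]
            length = float(r0 + (r1 - r0) * c0 / (c0 - c1))
            break
    return df, length, False


def fluidisation_diagnostics(
    positions: np.ndarray,
    triangulation: Triangulation,
    voronoi: VoronoiGeometry | None = None,
    center=(0.0, 0.0),
) -> dict:
    """Solid/fluid diagnostics of one frame.

    Returns triangle quality factors, the spring-length (centre-distance)
    distribution with its Pearson second skewness coefficient
    Sk2 = 3(mean − median)/std, Voronoi edge lengths when geometry is
    supplied, the mean radial distance of cells and the tissue centroid.
    """
    p = np.asarray(positions, dtype=float)
    q = triangle_quality(p, triangulation)
    e = triangulation.edges
    lengths = np.linalg.norm(p[e[:, 1]] - p[e[:, 0]], axis=1)
    std = float(np.std(lengths))
    mean = float(np.mean(lengths))
    # a relative floor: an (almost) degenerate spread has no meaningful skew
    sk2 = 3.0 * (mean - float(np.median(lengths))) / std \
        if std > 1e-9 * max(mean, 1e-300) else 0.0
    out = {
        "triangle_quality": q,
        "spring_lengths": lengths,
        "spring_length_skewness": sk2,
        "mean_radial_distance": float(np.mean(np.linalg.norm(p - np.asarray(center), axis=1))),
        "centroid": p.mean(axis=0),
    }
    if voronoi is not None:
        out["voronoi_edge_lengths"] = (
            np.concatenate([l for l in voronoi.edge_lengths if len(l)])
            if any(len(l) for l in voronoi.edge_lengths) else np.empty(0)
        )
    return out


def rotation_sign(times: np.ndarray, vorticity: np.ndarray,
                  window: tuple[float, float] | None = None,
                  min_magnitude: float = 0.0) -> int:
    """Sign of the time-median of mean vorticity over a window (±1, or 0).

    With ``min_magnitude`` > 0, a median smaller than that in magnitude
    returns 0: the rotation direction is not established (e.g. the run
    is still in, or just leaving, its transient).
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(vorticity, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        w = w[sel]
    if len(w) == 0:
        return 0
    med = float(np.median(w))
    if abs(med) < min_magnitude:
        return 0
    return int(np.sign(med))


def steady_plateau(times: np.ndarray, vorticity: np.ndarray,
                   window: float = 5.0, rel_tol: float = 0.05):
    """First time the mean vorticity plateaus, or None.

    Plateau: the moving-window standard deviation drops below
    ``rel_tol`` times the absolute moving mean.
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(vorticity, dtype=float)
    for k in range(len(t)):
        sel = (t >= t[k]) & (t <= t[k] + window)
        if t[-1] < t[k] + window:
            break
        seg = w[sel]
        m = np.abs(np.mean(seg))
        if m > 0 and np.std(seg) < rel_tol * m:
            return float(t[k])
    return None
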