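"""Closed-form continuum results for the coherently rotating tissue.

Treating the confined monolayer as a linear, isotropic elastic sheet
driven by tangential self-propulsion, torque balance with zero boundary
traction fixes the rigid-rotation rate at omega = 4 v0 / (3 R).  The
superimposed elastic displacement and internal shear have closed forms;
the internal shear peaks at r = R/2 with tau_max = v0 rho R / (12 mu).
In the fully fluidised limit the rim moves at v0 and the mean vorticity
drops to v0 / R.  These expressions serve as independent oracles for the
particle simulations, together with the unit conversions anchoring the
non-dimensional parameters to physiological values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContinuumParams",
    "omega_solid_disc",
    "omega_fluid_disc",
    "elastic_steady_profiles",
    "tau_max",
    "epsilon_max",
    "annulus_mean_vorticity",
    "dimensionalize",
]


@dataclass(frozen=True)
class ContinuumParams:
    """Elastic-sheet parameters for the continuum steady state.

    E (Pa), nu, h (length): Young's modulus, Poisson ratio and thickness
    of the sheet; rho (1/length^2): cell number density; mu: single-cell
    mobility; R: tissue radius; v0: motile speed.  The effective motility
    per unit area is mu_s = mu / rho (so mu_s * rho = mu by construction).
    """

    E: float
    nu: float
    h: float
    rho: float
    mu: float
    R: float
    v0: float

    def __post_init__(self) -> None:
        if not (self.E > 0 and self.h > 0 and self.rho > 0 and self.mu > 0
                and self.R > 0):
            raise ValueError("E, h, rho, mu, R must be positive")
        if not (0 <= self.nu < 1):
            raise ValueError("nu must be in [0, 1)")

    @property
    def mu_s(self) -> float:
        return self.mu / self.rho


def omega_solid_disc(v0: float, R: float) -> float:
    """Torque-balance rotation rate of the elastic disc: 4 v0 / (3 R)."""
    if not R > 0:
        raise ValueError("R must be positive")
    return 4.0 * v0 / (3.0 * R)


def omega_fluid_disc(v0: float, R: float) -> float:
    """Fluid-limit mean vorticity of the disc: v0 / R (rim moves at v0)."""
    if not R > 0:
        raise ValueError("R must be positive")
    return v0 / R


def elastic_steady_profiles(r, params: ContinuumParams):
    """Steady elastic displacement and internal shear profiles.

    Returns ``(u_r, u_theta, tau_rtheta)`` at radii ``r``:

        u_r      = 0
        u_theta  = [v0 rho (1+nu) R^2 / (3 E h mu)] * s^2 (s - 2),  s = r/R
        tau_rtheta = (v0 R / (3 mu_s)) * s (s - 1)   (per unit height h)

    satisfying u_r(R) = 0 and zero shear traction at the rim; |tau| is
    maximal at r = R/2 where it equals v0 rho R / (12 mu).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > params.R * (1 + 1e-12)):
        raise ValueError("r must lie in [0, R]")
    s = r / params.R
    amp = params.v0 * params.rho * (1 + params.nu) * params.R**2 / (
        3.0 * params.E * params.h * params.mu
    )
    u_theta = amp * s**2 * (s - 2.0)
    tau = params.v0 * params.R / (3.0 * params.mu_s) * s * (s - 1.0)
    return np.zeros_like(r), u_theta, tau


def tau_max(params: ContinuumParams) -> float:
    """Peak internal shear v0 rho R / (12 mu), attained at r = R/2."""
    return params.v0 * params.rho * params.R / (12.0 * params.mu)


def epsilon_max(params: ContinuumParams) -> float:
    """Peak shear strain v0 rho R (1+nu) / (12 mu E h)."""
    return params.v0 * params.rho * params.R * (1 + params.nu) / (
        12.0 * params.mu * params.E * params.h
    )


def annulus_mean_vorticity(R_out: float, R_in: float, v_out: float, v_in: float) -> float:
    """Mean vorticity of an annular flow from its rim speeds (Stokes).

    omega_mean = (R_out v_out - R_in v_in) / (R_out^2 - R_in^2).
    Reduces to v_out / R_out for a disc (R_in = 0) and to Omega exactly
    for rigid inputs v = Omega R.
    """
    if not R_out > R_in >= 0:
        raise ValueError("need R_out > R_in >= 0")
    return (R_out * v_out - R_in * v_in) / (R_out**2 - R_in**2)


# 1 pN/um = 1e-6 N/m
_PN_PER_UM_TO_N_PER_M = 1e-6


def dimensionalize(
    zeta: float = 100.0,        # substrate drag, pN hr / um^3
    a0_um: float = 20.0,        # cell length, um
    v0_um_hr: float = 20.0,     # cell speed, um / hr
    E_Pa: float = 10e3,         # Young's modulus, Pa
    h_um: float = 5.0,          # sheet thickness, um
    nu: float = 0.5,
    k_bar=(1.0, 10.0),          # non-dimensional stiffness range
    n_cells: int | None = None,
    domain_area_um2: float | None = None,
) -> dict:
    """Physical-unit report anchoring the simulation units.

    Computes the mobility mu = 1/(zeta a0^2), the force scale f0 = v0/mu,
    the time scale tau0 = a0/v0, the physical spring stiffness
    k = k_bar v0/(mu a0) for each requested k_bar, the thin-plate spring
    stiffness k = E h / (2 sqrt(3) (1 - nu)) of a triangular network,
    and optionally the cell density.  Internal units are pN, um, hr;
    stiffnesses are also reported in N/m.
    """
    mu = 1.0 / (zeta * a0_um**2)                  # um / (pN hr)
    f0 = v0_um_hr / mu                            # pN
    tau0 = a0_um / v0_um_hr                       # hr
    E_pN_um2 = E_Pa                               # 1 Pa = 1 pN/um^2
    k_plate_pN_um = E_pN_um2 * h_um / (2.0 * np.sqrt(3.0) * (1.0 - nu))
    k_bar = np.atleast_1d(np.asarray(k_bar, dtype=float))
    k_phys_pN_um = k_bar * v0_um_hr / (mu * a0_um)
    report = {
        "mu_um_per_pN_hr": mu,
        "f0_pN": f0,
        "tau0_hr": tau0,
        "k_plate_N_per_m": k_plate_pN_um * _PN_PER_UM_TO_N_PER_M,
        "k_physical_N_per_m": dict(
            zip(k_bar.tolist(),
                (k_phys_pN_um * _PN_PER_UM_TO_N_PER_M).tolist())
        ),
    }
    if n_cells is not None and domain_area_um2:
        report["density_cells_per_mm2"] = n_cells / domain_area_um2 * 1e6
    return report
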