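"""Steady interstitial Darcy flow through the gel channel with a spheroid inclusion.

The pressure field satisfies the heterogeneous Darcy equation
``div( (K/mu) grad p ) = 0`` with Dirichlet pressures on the pillar-gap
segments of the top (inlet, P1) and bottom (outlet, P2) boundaries and
no-flux side walls. The interstitial velocity is ``u = -(K/mu) grad p``.
Discretization is a conservative finite-volume scheme on the geometry grid
with harmonic permeability averaging at material interfaces and a sparse
direct solve.

Units: permeability in m^2, viscosity in Pa s, pressures in Pa, lengths in
um on the API, velocities reported in um/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import spsolve

from .geometry import ChipGeometry, GeometryError, build_geometry

__all__ = [
    "PorousMedium",
    "FlowBC",
    "FlowField",
    "InterfacialStress",
    "FlowError",
    "solve_flow",
    "mean_interstitial_velocity",
    "interfacial_stress",
    "calibrate_permeability",
    "boundary_fluxes",
    "convergence_check",
]

UM = 1e-6  # um -> m
MBAR = 100.0  # mbar -> Pa


class FlowError(RuntimeError):
    """Raised for ill-posed boundary conditions or solver failure."""


@dataclass(frozen=True)
class PorousMedium:
    """Hydraulic properties of the gel and the spheroid inclusion.

    permeability : gel hydraulic permeability K, m^2.
    permeability_spheroid : inclusion permeability K_s, m^2. Defaults to
        K/100 (near-impermeable multicellular aggregate).
    viscosity : interstitial fluid dynamic viscosity mu, Pa s.
    effective_viscosity : mu_e used for the Brinkman-style shear
        post-processing; defaults to mu.
    """

    permeability: float
    permeability_spheroid: float | None = None
    viscosity: float = 1e-3
    effective_viscosity: float | None = None

    def __post_init__(self):
        if self.permeability <= 0 or self.viscosity <= 0:
            raise ValueError("permeability and viscosity must be positive")
        if self.permeability_spheroid is None:
            object.__setattr__(
                self, "permeability_spheroid", self.permeability / 100.0
            )
        if self.permeability_spheroid <= 0:
            raise ValueError("spheroid permeability must be positive")
        if self.permeability_spheroid > self.permeability:
            raise ValueError("spheroid permeability must not exceed gel permeability")
        if self.effective_viscosity is None:
            object.__setattr__(self, "effective_viscosity", self.viscosity)

    def permeability_field(self, geom: ChipGeometry) -> np.ndarray:
        k = np.full(geom.shape, self.permeability)
        k[geom.spheroid_mask] = self.permeability_spheroid
        return k


@dataclass(frozen=True)
class FlowBC:
    """Dirichlet pressures (Pa) on the inlet/outlet boundary segments."""

    p_inlet: float
    p_outlet: float

    def __post_init__(self):
        # equality is the degenerate hydrostatic case (zero flow); a reversed
        # bias is rejected so "inlet" and "outlet" keep their meaning
        if self.p_inlet < self.p_outlet:
            raise ValueError("p_inlet must not be below p_outlet")

    @classmethod
    def from_mbar(cls, p1_mbar: float, p2_mbar: float = 0.0) -> "FlowBC":
        return cls(p1_mbar * MBAR, p2_mbar * MBAR)

    @property
    def delta_p(self) -> float:
        return self.p_inlet - self.p_outlet


@dataclass
class FlowField:
    """Pressure (Pa) and interstitial velocity (um/s) on the geometry grid.

    ``flux_x``/``flux_y`` hold face Darcy velocities in m/s on the staggered
    lattice (shapes (ny, nx+1) and (ny+1, nx)); positive y is downstream.
    """

    pressure: np.ndarray
    velocity_x: np.ndarray
    velocity_y: np.ndarray
    flux_x: np.ndarray
    flux_y: np.ndarray
    converged: bool
    residual: float


@dataclass
class InterfacialStress:
    """Normal and viscous shear stress (Pa) sampled on the spheroid interface.

    theta is in degrees, counterclockwise, 90 = inlet-facing (top) pole.
    Normal stress is the hydrodynamic pressure relative to the outlet.
    """

    theta: np.ndarray
    normal_stress: np.ndarray
    shear_stress: np.ndarray


def _assemble(geom: ChipGeometry, medium: PorousMedium, bc: FlowBC):
    ny, nx = geom.shape
    h = geom.grid_spacing * UM
    mob = medium.permeability_field(geom) / medium.viscosity  # K/mu

    def harm(a, b):
        return 2.0 * a * b / (a + b)

    # face mobilities (per unit depth transmissibility = mob_face, since
    # face length h cancels the h in the gradient)
    tx = harm(mob[:, :-1], mob[:, 1:])  # (ny, nx-1) interior x-faces
    ty = harm(mob[:-1, :], mob[1:, :])  # (ny-1, nx) interior y-faces

    idx = np.arange(ny * nx).reshape(ny, nx)
    rows, cols, vals = [], [], []
    b = np.zeros(ny * nx)
    diag = np.zeros(ny * nx)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    # interior x-faces
    a, bb = idx[:, :-1].ravel(), idx[:, 1:].ravel()
    t = tx.ravel()
    for p, q, tv in ((a, bb, t), (bb, a, t)):
        rows.extend(p)
        cols.extend(q)
        vals.extend(-tv)
    np.add.at(diag, a, t)
    np.add.at(diag, bb, t)
    # interior y-faces
    a, bb = idx[:-1, :].ravel(), idx[1:, :].ravel()
    t = ty.ravel()
    for p, q, tv in ((a, bb, t), (bb, a, t)):
        rows.extend(p)
        cols.extend(q)
        vals.extend(-tv)
    np.add.at(diag, a, t)
    np.add.at(diag, bb, t)

    # Dirichlet boundary faces (half-cell distance => transmissibility 2*mob)
    for cols_sel, row, pval in (
        (geom.inlet_columns, 0, bc.p_inlet),
        (geom.outlet_columns, ny - 1, bc.p_outlet),
    ):
        cells = idx[row, cols_sel]
        t = 2.0 * mob[row, cols_sel]
        np.add.at(diag, cells, t)
        np.add.at(b, cells, t * pval)

    rows.extend(np.arange(ny * nx))
    cols.extend(np.arange(ny * nx))
    vals.extend(diag)
    a_mat = sparse.csr_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
        shape=(ny * nx, ny * nx),
    )
    return a_mat, b, mob, h


def solve_flow(
    geom: ChipGeometry, medium: PorousMedium, bc: FlowBC, tol: float = 1e-8
) -> FlowField:
    """Solve the heterogeneous Darcy pressure equation and derive velocities."""
    if geom.inlet_columns.size == 0 or geom.outlet_columns.size == 0:
        raise FlowError("boundary conditions require at least one inlet and outlet segment")
    ny, nx = geom.shape
    a_mat, b, mob, h = _assemble(geom, medium, bc)
    p = spsolve(a_mat.tocsc(), b)
    residual = float(np.linalg.norm(a_mat @ p - b) / max(np.linalg.norm(b), 1e-300))
    converged = residual < tol
    if not converged:
        warnings.warn(f"flow solve residual {residual:.2e} above tolerance {tol:.0e}")
    p = p.reshape(ny, nx)

    def harm(a, c):
        return 2.0 * a * c / (a + c)

    fx = np.zeros((ny, nx + 1))
    fy = np.zeros((ny + 1, nx))
    fx[:, 1:-1] = -harm(mob[:, :-1], mob[:, 1:]) * (p[:, 1:] - p[:, :-1]) / h
    fy[1:-1, :] = -harm(mob[:-1, :], mob[1:, :]) * (p[1:, :] - p[:-1, :]) / h
    # Dirichlet boundary faces: half-cell gradient
    fy[0, geom.inlet_columns] = (
        2.0 * mob[0, geom.inlet_columns] * (bc.p_inlet - p[0, geom.inlet_columns]) / h
    )
    fy[-1, geom.outlet_columns] = (
        2.0 * mob[-1, geom.outlet_columns] * (p[-1, geom.outlet_columns] - bc.p_outlet) / h
    )
    ux = 0.5 * (fx[:, :-1] + fx[:, 1:]) / UM  # m/s -> um/s
    uy = 0.5 * (fy[:-1, :] + fy[1:, :]) / UM
    return FlowField(
        pressure=p,
        velocity_x=ux,
        velocity_y=uy,
        flux_x=fx,
        flux_y=fy,
        converged=converged,
        residual=residual,
    )


def mean_interstitial_velocity(field: FlowField, geom: ChipGeometry) -> float:
    """Mean velocity magnitude (um/s) over the gel, excluding the spheroid."""
    region = geom.gel_region & ~geom.spheroid_mask
    if not region.any():
        raise FlowError("empty averaging region")
    speed = np.hypot(field.velocity_x, field.velocity_y)
    return float(speed[region].mean())


def boundary_fluxes(field: FlowField, geom: ChipGeometry) -> tuple[float, float]:
    """Total volumetric inflow and outflow (m^2/s per unit depth)."""
    h = geom.grid_spacing * UM
    inflow = float(field.flux_y[0, geom.inlet_columns].sum() * h)
    outflow = float(field.flux_y[-1, geom.outlet_columns].sum() * h)
    return inflow, outflow


def _sample(grid: np.ndarray, x_um: np.ndarray, y_um: np.ndarray, h: float):
    # cell centers sit at (index + 0.5) * h
    return map_coordinates(
        grid, [y_um / h - 0.5, x_um / h - 0.5], order=1, mode="nearest"
    )


def interfacial_stress(
    field: FlowField,
    geom: ChipGeometry,
    medium: PorousMedium,
    bc: FlowBC,
    n_theta: int = 360,
) -> InterfacialStress:
    """Hydrodynamic normal and viscous shear stress around the spheroid rim.

    Normal stress is the interpolated interface pressure minus the outlet
    pressure. Shear stress is ``mu_e * |t . (2 E) . n|`` with E the symmetric
    velocity-gradient tensor, evaluated one grid shell outside the interface
    (a Brinkman-style estimate; pure Darcy flow carries no intrinsic shear).
    """
    if n_theta < 72:
        raise ValueError("need at least 72 angular stations")
    cx, cy = geom.spheroid_center
    r = geom.spheroid_radius
    h = geom.grid_spacing
    w, s = geom.extent
    if (
        cx - r - 2 * h < 0
        or cx + r + 2 * h > w
        or cy - r - 2 * h < 0
        or cy + r + 2 * h > s
    ):
        raise FlowError("spheroid interface too close to the domain boundary")

    theta = np.arange(n_theta) * 360.0 / n_theta
    th = np.deg2rad(theta)
    # theta counterclockwise with 90 deg at the top; grid y points down
    ex, ey = np.cos(th), -np.sin(th)
    xs, ys = cx + r * ex, cy + r * ey
    p_if = _sample(field.pressure, xs, ys, h)
    normal = p_if - bc.p_outlet

    # velocity gradients (SI) on the grid, sampled one shell outside
    hm = h * UM
    ux, uy = field.velocity_x * UM, field.velocity_y * UM
    dux_dy, dux_dx = np.gradient(ux, hm)
    duy_dy, duy_dx = np.gradient(uy, hm)
    r_out = r + h
    xo, yo = cx + r_out * ex, cy + r_out * ey
    g11 = _sample(dux_dx, xo, yo, h)
    g12 = _sample(dux_dy, xo, yo, h)
    g21 = _sample(duy_dx, xo, yo, h)
    g22 = _sample(duy_dy, xo, yo, h)
    e12 = 0.5 * (g12 + g21)
    nxv, nyv = ex, ey
    tx, ty = -ey, ex
    # t . (2E) . n
    tEn = 2.0 * (
        tx * (g11 * nxv + e12 * nyv) + ty * (e12 * nxv + g22 * nyv)
    )
    shear = medium.effective_viscosity * np.abs(tEn)
    return InterfacialStress(theta=theta, normal_stress=normal, shear_stress=shear)


def calibrate_permeability(
    u_target: float,
    bc: FlowBC,
    geom: ChipGeometry,
    medium: PorousMedium | None = None,
) -> float:
    """Gel permeability K (m^2) reproducing a target mean IF velocity (um/s).

    Exploits Darcy linearity: one solve at a template K, then closed-form
    rescaling (the spheroid/gel permeability ratio is held fixed).
    """
    if u_target <= 0:
        raise ValueError("target velocity must be positive")
    if medium is None:
        medium = PorousMedium(permeability=1e-15)
    field = solve_flow(geom, medium, bc)
    u0 = mean_interstitial_velocity(field, geom)
    return medium.permeability * u_target / u0


def convergence_check(
    geom_kwargs: dict, medium: PorousMedium, bc: FlowBC
) -> tuple[float, float, float]:
    """Re-solve at halved grid spacing; return (u_m, u_m_fine, rel_change)."""
    geom = build_geometry(**geom_kwargs)
    fine_kwargs = dict(geom_kwargs)
    fine_kwargs["grid_spacing"] = geom.grid_spacing / 2.0
    geom_f = build_geometry(**fine_kwargs)
    u0 = mean_interstitial_velocity(solve_flow(geom, medium, bc), geom)
    u1 = mean_interstitial_velocity(solve_flow(geom_f, medium, bc), geom_f)
    return u0, u1, abs(u1 - u0) / u1
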