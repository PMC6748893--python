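"""Steady incompressible 2-D channel flow with a Brinkman clot-drag term.

The growing clot is porous: its drag on the blood enters the momentum
balance as a Brinkman sink ``-mu * k * u`` where ``k`` (1/m², the viscous
resistance, i.e. inverse permeability) is derived from the local bound
platelet and fibrin content.  At the device's scale and shear the Reynolds
number is far below one, so the default solve drops the inertial terms and
the problem is linear (Stokes-Brinkman); the inertial terms can be switched
on, in which case they are Picard-iterated, to verify the creeping-flow
reduction.

Discretization: staggered (MAC) finite volumes on the uniform mesh.
u lives on vertical faces (nx+1, ny), v on horizontal faces (nx, ny+1),
p at cell centers (nx, ny).  Boundary conditions: prescribed parabolic
inlet profile, zero-pressure / zero-gradient outlet, no-slip walls.
The discrete continuity equation is enforced in every cell by a direct
sparse solve, so mass is conserved to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import StructuredMesh


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties and the target wall shear.

    Blood is treated as Newtonian; red-cell effects enter only through the
    shear-enhanced diffusivities and platelet margination elsewhere.
    """

    density: float = 1060.0          # kg/m^3
    viscosity: float = 3.5e-3        # Pa*s
    wall_shear_rate: float = 1000.0  # 1/s, arterial target

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")
        if self.wall_shear_rate < 0:
            raise ValueError("wall_shear_rate must be non-negative")

    @property
    def mean_velocity(self) -> float:
        """Plane-Poiseuille mean velocity for a 60-µm channel is set where
        the geometry is known; use :func:`inlet_profile` instead."""
        raise AttributeError("mean velocity depends on channel height; "
                             "use inlet_profile()")


@dataclass
class FlowState:
    """Converged discrete flow field on a structured mesh."""

    mesh: StructuredMesh
    u: np.ndarray            # (nx+1, ny) m/s, x-faces
    v: np.ndarray            # (nx, ny+1) m/s, y-faces
    p: np.ndarray            # (nx, ny) Pa
    residuals: dict = field(default_factory=dict)

    @property
    def u_center(self) -> np.ndarray:
        """Axial velocity interpolated to cell centers, (nx, ny)."""
        return 0.5 * (self.u[:-1, :] + self.u[1:, :])

    @property
    def v_center(self) -> np.ndarray:
        return 0.5 * (self.v[:, :-1] + self.v[:, 1:])

    def flux(self, i_face: int) -> float:
        """Volumetric flux per unit width (m²/s) through x-face column i."""
        dy = self.mesh.dy * 1e-6
        return float(self.u[i_face, :].sum() * dy)

    @property
    def divergence(self) -> np.ndarray:
        """Discrete divergence per cell (1/s)."""
        dx = self.mesh.dx * 1e-6
        dy = self.mesh.dy * 1e-6
        return ((self.u[1:, :] - self.u[:-1, :]) / dx
                + (self.v[:, 1:] - self.v[:, :-1]) / dy)


def inlet_profile(fluid: FluidProperties, height_um: float,
                  y_um: np.ndarray | None = None) -> np.ndarray:
    """Plane-Poiseuille inlet velocity with the target wall shear rate.

    u(y) = gw * (y - y^2/h), whose wall gradient is gw and whose mean is
    gw*h/6 (10 mm/s for gw = 1000 1/s, h = 60 µm).

    Parameters
    ----------
    fluid : FluidProperties
    height_um : float
        Channel height, µm.
    y_um : ndarray, optional
        Evaluation heights, µm.  Defaults to the analytic profile on a
        201-point grid.
    """
    if height_um <= 0:
        raise ValueError("height must be positive")
    h = height_um * 1e-6
    if y_um is None:
        y = np.linspace(0.0, h, 201)
    else:
        y = np.asarray(y_um, dtype=float) * 1e-6
    return fluid.wall_shear_rate * (y - y ** 2 / h)


def solve_flow(mesh: StructuredMesh, fluid: FluidProperties,
               resistance: np.ndarray | None = None,
               include_inertia: bool = False,
               picard_tol: float = 1e-6, picard_max_iter: int = 50,
               ) -> FlowState:
    """Solve the steady Stokes(-Brinkman) problem on the mesh.

    Parameters
    ----------
    mesh : StructuredMesh
    fluid : FluidProperties
    resistance : ndarray (nx, ny), optional
        Brinkman coefficient k per cell, 1/m².  None or zeros = clear
        channel.
    include_inertia : bool
        Picard-iterate the convective terms; at the device Reynolds number
        this changes the solution by well under 1%.

    Returns
    -------
    FlowState

    Raises
    ------
    RuntimeError
        If the Picard iteration fails to converge within the cap.
    """
    nx, ny = mesh.shape
    if resistance is None:
        resistance = np.zeros((nx, ny))
    resistance = np.asarray(resistance, dtype=float)
    if resistance.shape != (nx, ny):
        raise ValueError("resistance must be shaped (nx, ny)")
    if np.any(resistance < 0):
        raise ValueError("resistance must be non-negative")

    A, b, idx = _assemble(mesh, fluid, resistance)
    lu = spla.splu(A.tocsc())
    sol = lu.solve(b)
    for _ in range(2):  # iterative refinement tightens mass conservation
        sol += lu.solve(b - A @ sol)
    state = _unpack(mesh, sol, idx)

    if include_inertia:
        prev = sol
        for it in range(picard_max_iter):
            b_in = b - _convective_rhs(mesh, fluid, state, idx, b.size)
            sol = lu.solve(b_in)
            state = _unpack(mesh, sol, idx)
            change = np.linalg.norm(sol - prev) / max(np.linalg.norm(sol), 1e-300)
            prev = sol
            if change < picard_tol:
                break
        else:
            raise RuntimeError(
                f"inertial Picard iteration did not converge: last change {change:.3e}")

    state.residuals = {
        "max_divergence": float(np.abs(state.divergence).max()),
        "flux_imbalance": abs(state.flux(nx) - state.flux(0))
        / max(abs(state.flux(0)), 1e-300),
    }
    return state


def shear_field(state: FlowState) -> np.ndarray:
    """Shear-rate magnitude |du/dy + dv/dx| per cell, 1/s.

    Central differences on the cell-centered fields; one-sided differences
    at walls using the no-slip condition.
    """
    mesh = state.mesh
    dx = mesh.dx * 1e-6
    dy = mesh.dy * 1e-6
    uc = state.u_center
    vc = state.v_center

    dudy = np.empty_like(uc)
    dudy[:, 1:-1] = (uc[:, 2:] - uc[:, :-2]) / (2 * dy)
    # walls: u = 0 at the wall, half a cell away from the first center
    dudy[:, 0] = uc[:, 0] / (0.5 * dy)
    dudy[:, -1] = -uc[:, -1] / (0.5 * dy)

    dvdx = np.empty_like(vc)
    dvdx[1:-1, :] = (vc[2:, :] - vc[:-2, :]) / (2 * dx)
    dvdx[0, :] = (vc[1, :] - vc[0, :]) / dx
    dvdx[-1, :] = (vc[-1, :] - vc[-2, :]) / dx

    return np.abs(dudy + dvdx)


# ----------------------------------------------------------------------
# assembly internals

class _Index:
    def __init__(self, nx: int, ny: int):
        self.nx, self.ny = nx, ny
        self.nu = (nx + 1) * ny
        self.nv = nx * (ny + 1)
        self.np_ = nx * ny
        self.n = self.nu + self.nv + self.np_

    def iu(self, i, j):
        return i * self.ny + j

    def iv(self, i, j):
        return self.nu + i * (self.ny + 1) + j

    def ip(self, i, j):
        return self.nu + self.nv + i * self.ny + j


def _assemble(mesh: StructuredMesh, fluid: FluidProperties,
              resistance: np.ndarray):
    nx, ny = mesh.shape
    dx = mesh.dx * 1e-6
    dy = mesh.dy * 1e-6
    mu = fluid.viscosity
    idx = _Index(nx, ny)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(idx.n)

    def add(r, c, v):
        r = np.atleast_1d(np.asarray(r, dtype=np.int64)).ravel()
        c = np.atleast_1d(np.asarray(c, dtype=np.int64)).ravel()
        v = np.broadcast_to(np.asarray(v, dtype=float), r.shape).ravel()
        rows.append(r)
        cols.append(c)
        vals.append(v.copy())

    ax = mu / dx ** 2
    ay = mu / dy ** 2

    # ---- u equations -------------------------------------------------
    jj = np.arange(ny)
    # inlet Dirichlet u[0, j] = profile
    r = idx.iu(0, jj)
    add(r, r, 1.0)
    b[r] = inlet_profile(fluid, mesh.geometry.height, mesh.yc)

    # interior faces i = 1..nx-1
    ii, jj2 = np.meshgrid(np.arange(1, nx), np.arange(ny), indexing="ij")
    ii, jj2 = ii.ravel(), jj2.ravel()
    r = idx.iu(ii, jj2)
    k_face = 0.5 * (resistance[ii - 1, jj2] + resistance[ii, jj2])
    diag = -2.0 * ax - 2.0 * ay - mu * k_face
    # wall ghost: u_ghost = -u -> y-neighbour coefficient folds into diagonal
    at_bottom = jj2 == 0
    at_top = jj2 == ny - 1
    diag = diag - ay * at_bottom - ay * at_top
    add(r, r, diag)
    add(r, idx.iu(ii - 1, jj2), ax)
    # outlet neighbour i+1 exists for all (u has nx+1 columns)
    add(r, idx.iu(ii + 1, jj2), ax)
    m = ~at_bottom
    add(r[m], idx.iu(ii[m], jj2[m] - 1), ay)
    m = ~at_top
    add(r[m], idx.iu(ii[m], jj2[m] + 1), ay)
    # pressure gradient: -(p[i] - p[i-1])/dx
    add(r, idx.ip(ii, jj2), -1.0 / dx)
    add(r, idx.ip(ii - 1, jj2), 1.0 / dx)

    # outlet faces i = nx: zero-gradient in x, outlet pressure = 0
    jj = np.arange(ny)
    r = idx.iu(nx, jj)
    k_face = resistance[nx - 1, jj]
    diag = -ax - 2.0 * ay - mu * k_face
    diag = diag.copy()
    diag[0] -= ay
    diag[-1] -= ay
    add(r, r, diag)
    add(r, idx.iu(nx - 1, jj), ax)
    add(r[1:], idx.iu(nx, jj[1:] - 1), ay)
    add(r[:-1], idx.iu(nx, jj[:-1] + 1), ay)
    # pressure gradient to the outlet boundary value p_b = 0 at distance
    # dx/2: -(p_b - p[nx-1])/(dx/2) = +2 p[nx-1]/dx
    add(r, idx.ip(nx - 1, jj), 2.0 / dx)

    # ---- v equations -------------------------------------------------
    ii = np.arange(nx)
    for j in (0, ny):            # wall Dirichlet v = 0
        r = idx.iv(ii, j)
        add(r, r, 1.0)

    ii, jj2 = np.meshgrid(np.arange(nx), np.arange(1, ny), indexing="ij")
    ii, jj2 = ii.ravel(), jj2.ravel()
    r = idx.iv(ii, jj2)
    k_face = 0.5 * (resistance[ii, jj2 - 1] + resistance[ii, jj2])
    diag = -2.0 * ax - 2.0 * ay - mu * k_face
    at_in = ii == 0       # inlet: v boundary value 0, ghost = -v
    at_out = ii == nx - 1  # outlet: zero-gradient, ghost = v
    diag = diag - ax * at_in + ax * at_out
    add(r, r, diag)
    m = ~at_in
    add(r[m], idx.iv(ii[m] - 1, jj2[m]), ax)
    m = ~at_out
    add(r[m], idx.iv(ii[m] + 1, jj2[m]), ax)
    add(r, idx.iv(ii, jj2 - 1), ay)
    add(r, idx.iv(ii, jj2 + 1), ay)
    add(r, idx.ip(ii, jj2), -1.0 / dy)
    add(r, idx.ip(ii, jj2 - 1), 1.0 / dy)

    # ---- continuity --------------------------------------------------
    ii, jj2 = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ii, jj2 = ii.ravel(), jj2.ravel()
    r = idx.ip(ii, jj2)
    add(r, idx.iu(ii + 1, jj2), 1.0 / dx)
    add(r, idx.iu(ii, jj2), -1.0 / dx)
    add(r, idx.iv(ii, jj2 + 1), 1.0 / dy)
    add(r, idx.iv(ii, jj2), -1.0 / dy)

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(idx.n, idx.n)).tocsr()
    return A, b, idx


def _unpack(mesh: StructuredMesh, sol: np.ndarray, idx: _Index) -> FlowState:
    nx, ny = mesh.shape
    u = sol[:idx.nu].reshape(nx + 1, ny)
    v = sol[idx.nu:idx.nu + idx.nv].reshape(nx, ny + 1)
    p = sol[idx.nu + idx.nv:].reshape(nx, ny)
    return FlowState(mesh=mesh, u=u.copy(), v=v.copy(), p=p.copy())


def _convective_rhs(mesh: StructuredMesh, fluid: FluidProperties,
                    state: FlowState, idx: _Index, n: int) -> np.ndarray:
    """rho*(U.grad)U evaluated at the previous Picard iterate, on the
    staggered unknowns; returned as a vector added to the RHS."""
    nx, ny = mesh.shape
    dx = mesh.dx * 1e-6
    dy = mesh.dy * 1e-6
    rho = fluid.density
    u, v = state.u, state.v
    out = np.zeros(n)

    # u faces, interior in x
    dudx = np.zeros_like(u)
    dudx[1:-1, :] = (u[2:, :] - u[:-2, :]) / (2 * dx)
    dudy = np.zeros_like(u)
    dudy[:, 1:-1] = (u[:, 2:] - u[:, :-2]) / (2 * dy)
    dudy[:, 0] = (u[:, 1] - (-u[:, 0])) / (2 * dy)
    dudy[:, -1] = ((-u[:, -1]) - u[:, -2]) / (2 * dy)
    v_at_u = np.zeros_like(u)
    v_at_u[1:-1, :] = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
    conv_u = rho * (u * dudx + v_at_u * dudy)
    ii, jj = np.meshgrid(np.arange(1, nx), np.arange(ny), indexing="ij")
    out[idx.iu(ii.ravel(), jj.ravel())] = conv_u[1:-1, :].ravel()

    # v faces, interior in y
    dvdy = np.zeros_like(v)
    dvdy[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2 * dy)
    dvdx = np.zeros_like(v)
    dvdx[1:-1, :] = (v[2:, :] - v[:-2, :]) / (2 * dx)
    u_at_v = np.zeros_like(v)
    u_at_v[:, 1:-1] = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
    conv_v = rho * (u_at_v * dvdx + v * dvdy)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(1, ny), indexing="ij")
    out[idx.iv(ii.ravel(), jj.ravel())] = conv_v[:, 1:-1].ravel()
    return out
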