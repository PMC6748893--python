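"""Convection-diffusion-reaction transport of coagulation species.

Species are advanced by operator splitting: an implicit-Euler
advection-diffusion step (flux-form first-order upwind advection, central
diffusion, assembled as one sparse matrix per diffusivity class and solved
directly) followed by a vectorized RK4 reaction sub-step restricted to the
cells where any active species is present.  The implicit step is
unconditionally stable, strictly positivity-preserving (the system matrix
is an M-matrix) and exactly conservative in a closed domain; at large
Courant number in the fast lumen it relaxes the fields toward the
quasi-steady plume balance, which is the physically relevant limit there.

Red blood cells are not modeled explicitly; their stirring enters through
the shear-dependent augmentation of every Brownian diffusivity
(Zydney-Colton form): D_eff = D_b + k_sh a² γ̇ H (1-H)^0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow import FlowState
from .geometry import StructuredMesh
from .network import IMMOBILE, S, SPECIES, SURFACE_SPECIES, ReactionNetwork


def effective_diffusivity(d_brownian: float, shear_rate: np.ndarray | float,
                          hematocrit: float = 0.4, k_sh: float = 0.15,
                          rbc_radius: float = 2.75e-6) -> np.ndarray | float:
    """Shear-augmented diffusivity, m²/s.

    D_eff = D_b + k_sh · a² · γ̇ · H · (1-H)^0.8 with RBC radius a and
    hematocrit H.  With γ̇ = 0 or H = 0 this reduces to the Brownian value.
    """
    if d_brownian < 0 or k_sh < 0 or not (0.0 <= hematocrit < 1.0):
        raise ValueError("invalid diffusivity parameters")
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    return d_brownian + k_sh * rbc_radius ** 2 * g * hematocrit * (1 - hematocrit) ** 0.8


@dataclass
class SpeciesFields:
    """Per-cell bulk concentrations (nM) and per-face surface densities."""

    mesh: StructuredMesh
    conc: np.ndarray          # (nx, ny, n_species), nM
    surface: np.ndarray       # (n_faces, 4) mol/m^2: TF, TF:VII, TF:VIIa, dead

    @classmethod
    def initial(cls, mesh: StructuredMesh, network: ReactionNetwork,
                tf_site_density: float) -> "SpeciesFields":
        """Plasma baselines everywhere; free TF on the thrombogenic faces."""
        nx, ny = mesh.shape
        conc = np.broadcast_to(network.baselines, (nx, ny, len(SPECIES))).copy()
        nfaces = mesh.n_thrombogenic
        surface = np.zeros((nfaces, len(SURFACE_SPECIES)))
        surface[:, 0] = tf_site_density
        return cls(mesh=mesh, conc=conc, surface=surface)

    def total(self, species: str) -> float:
        """Domain-integrated amount per unit width, nM·µm²."""
        return float(self.conc[:, :, S[species]].sum()
                     * self.mesh.dx * self.mesh.dy)


class TransportOperator:
    """Implicit advection-diffusion stepper for one flow field.

    Builds, per diffusivity class, the matrix ``M = I + dt (A_adv + A_diff)``
    and its LU factorization; factorizations are reused until the flow (and
    hence the shear-dependent diffusivity) is refreshed.

    Boundary conditions: Dirichlet plasma baseline at the inlet, advective
    outflow at the outlet, zero flux through the walls (thrombogenic-surface
    chemistry enters through the reaction step, not here).
    """

    def __init__(self, mesh: StructuredMesh, flow: FlowState,
                 diffusivity_classes: dict[str, float],
                 shear_diffusion: np.ndarray, dt: float,
                 closed: bool = False):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.mesh = mesh
        self.dt = dt
        self.closed = closed
        nx, ny = mesh.shape
        self.n = nx * ny
        dx = mesh.dx * 1e-6
        dy = mesh.dy * 1e-6
        self._dirichlet_rhs: dict[str, np.ndarray] = {}
        self._lu: dict[str, spla.SuperLU] = {}

        adv_rows, adv_cols, adv_vals, s_adv = self._advection(flow, dx, dy)
        for cls_name, d_b in diffusivity_classes.items():
            d_cell = d_b + shear_diffusion
            r, c, v, s_dif = self._diffusion(d_cell, dx, dy)
            A = sp.coo_matrix((np.concatenate([adv_vals, v]),
                               (np.concatenate([adv_rows, r]),
                                np.concatenate([adv_cols, c]))),
                              shape=(self.n, self.n)).tocsc()
            M = sp.identity(self.n, format="csc") + dt * A
            self._lu[cls_name] = spla.splu(M)
            # rhs source per unit inlet concentration (1/s)
            self._dirichlet_rhs[cls_name] = s_adv + s_dif

    # -- assembly ------------------------------------------------------
    def _idx(self, i, j):
        return i * self.mesh.ny + j

    def _advection(self, flow: FlowState, dx: float, dy: float):
        nx, ny = self.mesh.shape
        rows, cols, vals = [], [], []
        s = np.zeros(self.n)  # source per unit inlet concentration, 1/s

        def add(r, c, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(c).ravel())
            vals.append(np.broadcast_to(v, np.asarray(r).shape).ravel().astype(float))

        u, v_ = flow.u, flow.v
        # interior x-faces between cells (i-1,j) and (i,j), i=1..nx-1
        ii, jj = np.meshgrid(np.arange(1, nx), np.arange(ny), indexing="ij")
        uf = u[1:nx, :]
        up = uf > 0
        L = self._idx(ii - 1, jj)
        R = self._idx(ii, jj)
        donor = np.where(up, L, R)
        coef = np.abs(uf) / dx
        # outflow from donor, inflow to the other cell
        add(donor, donor, coef)
        add(np.where(up, R, L), donor, -coef)
        if not self.closed:
            # inlet faces i=0 (u >= 0 into cell 0)
            jj0 = np.arange(ny)
            s[self._idx(0, jj0)] += np.maximum(u[0, :], 0.0) / dx
            # outlet faces i=nx: upwind outflow from the last cells
            Lo = self._idx(nx - 1, jj0)
            add(Lo, Lo, np.maximum(u[nx, :], 0.0) / dx)
        # interior y-faces between (i,j-1) and (i,j), j=1..ny-1
        ii, jj = np.meshgrid(np.arange(nx), np.arange(1, ny), indexing="ij")
        vf = v_[:, 1:ny]
        up = vf > 0
        L = self._idx(ii, jj - 1)
        R = self._idx(ii, jj)
        donor = np.where(up, L, R)
        coef = np.abs(vf) / dy
        add(donor, donor, coef)
        add(np.where(up, R, L), donor, -coef)
        return (np.concatenate(rows), np.concatenate(cols),
                np.concatenate(vals), s)

    def _diffusion(self, d_cell: np.ndarray, dx: float, dy: float):
        nx, ny = self.mesh.shape
        rows, cols, vals = [], [], []
        s = np.zeros(self.n)

        def add(r, c, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(c).ravel())
            vals.append(np.asarray(v, dtype=float).ravel())

        # x-direction interior faces
        df = 0.5 * (d_cell[:-1, :] + d_cell[1:, :])
        ii, jj = np.meshgrid(np.arange(1, nx), np.arange(ny), indexing="ij")
        L = self._idx(ii - 1, jj)
        R = self._idx(ii, jj)
        c = (df / dx ** 2).ravel()
        add(L, L, c); add(R, R, c); add(L, R, -c); add(R, L, -c)
        if not self.closed:
            # inlet Dirichlet at half-cell distance
            jj0 = np.arange(ny)
            cin = 2.0 * d_cell[0, :] / dx ** 2
            add(self._idx(0, jj0), self._idx(0, jj0), cin)
            s[self._idx(0, jj0)] += cin
        # outlet: no diffusive flux (advective outflow dominates)
        # y-direction interior faces
        df = 0.5 * (d_cell[:, :-1] + d_cell[:, 1:])
        ii, jj = np.meshgrid(np.arange(nx), np.arange(1, ny), indexing="ij")
        L = self._idx(ii, jj - 1)
        R = self._idx(ii, jj)
        c = (df / dy ** 2).ravel()
        add(L, L, c); add(R, R, c); add(L, R, -c); add(R, L, -c)
        return (np.concatenate(rows), np.concatenate(cols),
                np.concatenate(vals), s)

    # -- stepping ------------------------------------------------------
    def step_class(self, cls_name: str, c: np.ndarray,
                   inlet_value: float) -> np.ndarray:
        """One implicit step of one field (nx, ny) in a diffusivity class."""
        rhs = c.ravel() + self.dt * inlet_value * self._dirichlet_rhs[cls_name]
        out = self._lu[cls_name].solve(rhs)
        return out.reshape(self.mesh.shape)


#: diffusivity class per species
SPECIES_CLASS = {sp_: ("fibrinogen" if sp_ == "fibrinogen" else "protein")
                 for sp_ in SPECIES}


def advance_transport(fields: SpeciesFields, flow: FlowState, dt: float,
                      network: ReactionNetwork | None = None,
                      operator: TransportOperator | None = None,
                      shear: np.ndarray | None = None,
                      n_substeps: int = 1) -> SpeciesFields:
    """Advance all mobile species by advection-diffusion over ``dt``.

    A convenience wrapper over :class:`TransportOperator` (which coupled
    runs build once per flow refresh).  Reactions are not applied here; see
    :func:`react_step`.
    """
    from .flow import shear_field
    network = network or ReactionNetwork()
    if operator is None:
        g = shear if shear is not None else shear_field(flow)
        cfg = network.config
        sh = cfg["shear_enhancement"]
        d_shear = effective_diffusivity(0.0, g, sh["hematocrit"], sh["k_sh"],
                                        sh["rbc_radius_um"] * 1e-6)
        classes = {k: v for k, v in cfg["diffusivity"].items() if k != "platelet"}
        operator = TransportOperator(fields.mesh, flow, classes, d_shear,
                                     dt / n_substeps)
    conc = fields.conc.copy()
    for _ in range(n_substeps):
        for i, sp_name in enumerate(SPECIES):
            if sp_name in IMMOBILE:
                continue
            conc[:, :, i] = operator.step_class(
                SPECIES_CLASS[sp_name], conc[:, :, i], network.baselines[i])
    out = SpeciesFields(mesh=fields.mesh, conc=conc,
                        surface=fields.surface.copy())
    _check_finite(out)
    return out


def react_step(fields: SpeciesFields, platelet_phi: np.ndarray, dt: float,
               network: ReactionNetwork, dt_sub: float = 0.025,
               ) -> SpeciesFields:
    """Advance bulk + surface chemistry over ``dt`` with RK4 sub-steps.

    Only cells that can have nonzero rates are integrated: cells with any
    active enzyme/complex above 1e-9 nM, cells containing bound platelets,
    and the wall cells over the thrombogenic patch.
    """
    from .network import rk4_step

    mesh = fields.mesh
    conc = fields.conc.copy()
    sigma = fields.surface.copy()
    dy_m = mesh.dy * 1e-6

    active_idx = [S[n] for n in
                  ("VIIa", "IXa", "Xa", "IIa", "tenase", "prothrombinase",
                   "Xa_TFPI")]
    mask = (conc[:, :, active_idx] > 1e-9).any(axis=2)
    mask |= np.asarray(platelet_phi) > 1e-9
    face_i = np.flatnonzero(mesh.thrombogenic_faces)
    mask[face_i, 0] = True
    cells = np.argwhere(mask)
    if cells.size == 0:
        return fields
    ci, cj = cells[:, 0], cells[:, 1]
    c = conc[ci, cj, :]                        # (m, n_species)
    phi = np.asarray(platelet_phi)[ci, cj]
    # map thrombogenic faces into the masked cell list
    pos = np.full(mesh.shape, -1, dtype=np.int64)
    pos[ci, cj] = np.arange(len(ci))
    face_rows = pos[face_i, 0]

    n = max(1, int(round(dt / dt_sub)))
    h = dt / n
    for _ in range(n):
        def rhs_bulk(x):
            return network.reaction_rates(x, phi)
        c = rk4_step(rhs_bulk, c, h)
        # surface chemistry, explicit Euler at the same sub-step (surface
        # rates are slow relative to 1/h)
        dsig, dc = network.surface_reaction_flux(sigma, c[face_rows, :], dy_m)
        sigma = np.clip(sigma + h * dsig, 0.0, None)
        c[face_rows, :] += h * dc
        np.clip(c, 0.0, None, out=c)
    conc[ci, cj, :] = c
    out = SpeciesFields(mesh=mesh, conc=conc, surface=sigma)
    _check_finite(out)
    return out


def _check_finite(fields: SpeciesFields) -> None:
    if not np.isfinite(fields.conc).all():
        raise FloatingPointError(
            "non-finite concentration after transport step; "
            "reduce the time step")
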