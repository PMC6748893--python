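"""Platelet phenotypes, margination, adhesion/aggregation, and clot drag.

Four functional phenotypes are tracked: {mobile, bound} x {resting,
activated}.  Mobile platelets are number concentrations (platelets/m³)
advected and diffused with the blood; bound platelets are immobile volume
fractions φ capped at a packing limit φ_max.  Conversions between count
and volume use a single-platelet volume of 11 fL.

Margination: red cells crowd platelets toward the walls.  Rather than a
drift-flux term, the near-wall excess is imposed as an equilibrium
enhancement profile E(y) (wall/bulk ratio 3 within a 5-µm boundary layer,
normalized so the channel average of E is 1); each coupling step mobile
fields are multiplicatively reweighted toward E column by column, which
conserves every column total exactly and is the identity when E ≡ 1.

Capture: collagen faces capture near-wall mobile platelets (first-order,
expressed as a capture velocity; the arterial calibration multiplies the
base adhesion rate by 4 to stand in for vWF-mediated capture at high
shear), and cells adjacent to activated bound platelets capture mobile
platelets (aggregation).  Both saturate as (1 - φ/φ_max).  Activated
platelets are captured faster than resting ones, which is how
thrombin-driven activation feeds back on clot growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import StructuredMesh

#: single-platelet volume, m³ (11 fL)
PLATELET_VOLUME = 1.1e-17


@dataclass(frozen=True)
class PlateletParams:
    """Platelet model constants (units in comments)."""

    baseline_count: float = 2.5e14      # platelets/m^3 (250,000/µL)
    phi_max: float = 0.6                # packing cap, volume fraction
    v_adhesion: float = 2.0e-6          # m/s, collagen capture velocity (pre-calibration)
    adhesion_multiplier: float = 4.0    # arterial (vWF) calibration factor
    v_aggregation: float = 3.0e-6       # m/s, capture onto activated clot
    resting_capture_fraction: float = 0.45  # resting vs activated capture
    phi_neighbor_min: float = 0.02      # activated φ enabling neighbor capture
    k_activation: float = 0.5           # 1/s at saturating thrombin
    ec50_thrombin: float = 1.0          # nM
    hill_n: float = 1.0
    k_contact_activation: float = 0.05  # 1/s, collagen-bound resting -> activated
    k_bound_activation: float = 0.025   # 1/s, autocrine activation inside aggregate
    margination_peak: float = 3.0       # wall/bulk enhancement ratio
    margination_layer_um: float = 5.0


@dataclass
class PlateletState:
    """Mobile number concentrations and bound volume fractions per cell."""

    mesh: StructuredMesh
    mobile_resting: np.ndarray     # platelets/m^3
    mobile_activated: np.ndarray
    bound_resting: np.ndarray      # volume fraction
    bound_activated: np.ndarray
    params: PlateletParams = field(default_factory=PlateletParams)

    @classmethod
    def initial(cls, mesh: StructuredMesh,
                params: PlateletParams | None = None) -> "PlateletState":
        params = params or PlateletParams()
        nx, ny = mesh.shape
        z = np.zeros((nx, ny))
        return cls(mesh=mesh,
                   mobile_resting=np.full((nx, ny), params.baseline_count),
                   mobile_activated=z.copy(),
                   bound_resting=z.copy(),
                   bound_activated=z.copy(),
                   params=params)

    @property
    def phi_bound(self) -> np.ndarray:
        return self.bound_resting + self.bound_activated

    def total_count(self) -> float:
        """Total platelets per unit width (mobile + bound), 1/m."""
        cell_area = (self.mesh.dx * 1e-6) * (self.mesh.dy * 1e-6)
        mobile = (self.mobile_resting + self.mobile_activated).sum() * cell_area
        bound = self.phi_bound.sum() * cell_area / PLATELET_VOLUME
        return float(mobile + bound)

    def bound_total(self) -> float:
        """Domain-integrated bound platelet volume fraction, µm²."""
        return float(self.phi_bound.sum() * self.mesh.dx * self.mesh.dy)


# ----------------------------------------------------------------------
def margination_profile(mesh: StructuredMesh,
                        params: PlateletParams) -> np.ndarray:
    """Equilibrium near-wall enhancement E(y) with channel mean 1."""
    y = mesh.yc
    h = mesh.geometry.height
    delta = params.margination_layer_um
    e = np.where((y < delta) | (y > h - delta), params.margination_peak, 1.0)
    return e / e.mean()


def margination_redistribution(state: PlateletState,
                               profile: np.ndarray | None = None,
                               ) -> PlateletState:
    """Reweight mobile fields toward the margination profile.

    Multiplicative per-column reweighting: c -> c·E·(total/Σ c·E), so each
    column total is conserved exactly and E ≡ 1 is the identity.  Cells
    already packed with bound platelets are excluded from receiving excess.
    """
    profile = margination_profile(state.mesh, state.params) \
        if profile is None else np.asarray(profile, dtype=float)
    out = replace(state)
    for name in ("mobile_resting", "mobile_activated"):
        c = getattr(state, name)
        w = c * profile[None, :]
        tot = c.sum(axis=1, keepdims=True)
        wsum = w.sum(axis=1, keepdims=True)
        scale = np.divide(tot, wsum, out=np.ones_like(tot), where=wsum > 0)
        setattr(out, name, w * scale)
    return out


# ----------------------------------------------------------------------
def activation_step(state: PlateletState, thrombin: np.ndarray,
                    dt: float) -> PlateletState:
    """Resting -> activated conversion (count-conserving).

    Mobile and bound resting platelets activate at a thrombin-dependent
    Hill rate; bound platelets additionally activate at a fixed autocrine
    rate (faster on the collagen faces themselves).
    """
    if np.any(np.asarray(thrombin) < 0):
        raise ValueError("thrombin field must be non-negative")
    p = state.params
    th = np.asarray(thrombin, dtype=float)
    hill = th ** p.hill_n / (p.ec50_thrombin ** p.hill_n + th ** p.hill_n)
    rate_m = p.k_activation * hill
    frac_m = -np.expm1(-rate_m * dt)

    rate_b = p.k_activation * hill + p.k_bound_activation
    contact = np.zeros(state.mesh.shape)
    contact[state.mesh.thrombogenic_faces, 0] = p.k_contact_activation
    rate_b = rate_b + contact
    frac_b = -np.expm1(-rate_b * dt)

    moved_m = state.mobile_resting * frac_m
    moved_b = state.bound_resting * frac_b
    return replace(
        state,
        mobile_resting=state.mobile_resting - moved_m,
        mobile_activated=state.mobile_activated + moved_m,
        bound_resting=state.bound_resting - moved_b,
        bound_activated=state.bound_activated + moved_b,
    )


def adhesion_aggregation_step(state: PlateletState, dt: float,
                              max_dphi: float = 0.05) -> PlateletState:
    """Capture mobile platelets onto collagen and onto the clot.

    First-order capture with velocity v (m/s) converts mobile count to
    bound volume fraction via the single-platelet volume; the factor
    (1 - φ/φ_max) saturates capture as a cell packs.  Sub-steps internally
    so φ never overshoots.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    mesh = state.mesh
    dy_m = mesh.dy * 1e-6

    mr = state.mobile_resting.copy()
    ma = state.mobile_activated.copy()
    br = state.bound_resting.copy()
    ba = state.bound_activated.copy()

    remaining = dt
    while remaining > 1e-12:
        phi = br + ba
        sat = np.clip(1.0 - phi / p.phi_max, 0.0, None)
        # eligibility: collagen faces, or a 4-neighbor with activated clot
        elig = np.zeros(mesh.shape, dtype=bool)
        elig[mesh.thrombogenic_faces, 0] = True
        act = ba > p.phi_neighbor_min
        elig[1:, :] |= act[:-1, :]
        elig[:-1, :] |= act[1:, :]
        elig[:, 1:] |= act[:, :-1]
        elig[:, :-1] |= act[:, 1:]

        v_surf = p.v_adhesion * p.adhesion_multiplier
        v_cell = np.where(elig, p.v_aggregation, 0.0)
        v_cell[mesh.thrombogenic_faces, 0] = np.maximum(
            v_surf, v_cell[mesh.thrombogenic_faces, 0])

        # per-phenotype capture rate (1/s) acting on the mobile pools
        k_act = v_cell / dy_m * sat
        k_rest = k_act * p.resting_capture_fraction
        dphi_rate = (k_act * ma + k_rest * mr) * PLATELET_VOLUME
        peak = dphi_rate.max()
        h = remaining if peak <= 0 else min(remaining, max_dphi / peak)
        fa = -np.expm1(-k_act * h)
        fr = -np.expm1(-k_rest * h)
        ca, cr = ma * fa, mr * fr
        ma -= ca
        mr -= cr
        ba += ca * PLATELET_VOLUME
        br += cr * PLATELET_VOLUME
        remaining -= h

    np.clip(br, 0.0, p.phi_max, out=br)
    np.clip(ba, 0.0, p.phi_max, out=ba)
    return replace(state, mobile_resting=mr, mobile_activated=ma,
                   bound_resting=br, bound_activated=ba)


# ----------------------------------------------------------------------
def resistance_from_composition(phi_bound: np.ndarray,
                                fibrin_nM: np.ndarray,
                                d_platelet: float = 2e-6,
                                d_fiber: float = 1e-7,
                                nu_fibrin_per_nM: float = 1.5e-7,
                                ) -> np.ndarray:
    """Brinkman coefficient k (1/m²) from bound platelets and fibrin.

    Kozeny-Carman packed-bed form per constituent,
    k(φ; d) = 180 φ² / ((1-φ)³ d²), with the fibrin volume fraction
    obtained from concentration via ν_f (default 1.5e-4 per 1000 nM).
    """
    phi_b = np.asarray(phi_bound, dtype=float)
    phi_f = np.asarray(fibrin_nM, dtype=float) * nu_fibrin_per_nM
    if np.any(phi_b < 0) or np.any(phi_f < 0):
        raise ValueError("volume fractions must be non-negative")
    if np.any(phi_b >= 1.0) or np.any(phi_f >= 1.0):
        raise ValueError("volume fraction >= 1: upstream invariant breached")

    def kc(phi, d):
        return 180.0 * phi ** 2 / ((1.0 - phi) ** 3 * d ** 2)

    return kc(phi_b, d_platelet) + kc(phi_f, d_fiber)
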