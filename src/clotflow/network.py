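"""Coagulation reaction network: species, rate laws, and stiff integration.

The network covers the tissue-factor pathway restricted to the nine
proteins it is built from (TF, factors II, V, VII, VIII, IX, X, fibrinogen,
tissue factor pathway inhibitor) together with their activated forms and
the two membrane-bound enzyme complexes (intrinsic tenase IXa:VIIIa and
prothrombinase Xa:Va).  Bulk concentrations are in nM; thrombogenic-surface
species (free TF, TF:VII, TF:VIIa and the TFPI-quenched complex) are
surface densities in mol/m².

Tenase and prothrombinase assembly requires procoagulant membrane, which
deposited platelets supply: assembly rates are scaled by
``min(1, phi_bound/phi_ref)``.  That single multiplier localizes the
explosive phase of thrombin generation to the clot, which is what produces
the strong synergy between thrombogenic-surface length and TF density.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Bulk species, fixed order; state arrays are indexed accordingly.
SPECIES = (
    "VII", "VIIa", "IX", "IXa", "X", "Xa", "II", "IIa",
    "V", "Va", "VIII", "VIIIa", "tenase", "prothrombinase",
    "fibrinogen", "fibrin", "TFPI", "Xa_TFPI",
)
S = {name: i for i, name in enumerate(SPECIES)}

#: Species that are not transported (fibrin polymerizes in place).
IMMOBILE = ("fibrin",)

#: Thrombogenic-surface species, mol/m² per surface face.
SURFACE_SPECIES = ("TF", "TF_VII", "TF_VIIa", "TF_dead")

_NM_TO_M = 1e-9  # nM -> mol/L = M


def load_network_config(path: str | None = None) -> dict:
    """Load the reaction table (rate constants, baselines, diffusivities).

    Defaults to the versioned table shipped with the package.
    """
    if path is None:
        ref = importlib.resources.files("clotflow").joinpath("data/network.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _coerce_numbers(yaml.safe_load(text))


def _coerce_numbers(obj):
    """YAML 1.1 does not resolve exponents without a sign (e.g. 3.2e6);
    coerce any numeric-looking strings to float."""
    if isinstance(obj, dict):
        return {k: _coerce_numbers(v) for k, v in obj.items()}
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


@dataclass
class ReactionNetwork:
    """Rate-law evaluator for the TF-pathway table.

    Parameters
    ----------
    config : dict, optional
        Parsed network configuration; defaults to the packaged table.
    """

    config: dict = field(default_factory=load_network_config)

    def __post_init__(self) -> None:
        k = self.config["rate_constants"]
        for name, value in k.items():
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        self.k = k
        self.surf = self.config["surface_reactions"]
        self.phi_ref = float(self.config["platelet_surface"]["phi_ref"])
        ps = self.config["platelet_surface"]
        self.phi_fibrin_on = float(ps.get("phi_fibrin_on", 0.03))
        self.phi_fibrin_full = float(ps.get("phi_fibrin_full", 0.12))
        base = self.config["plasma_baselines_nM"]
        unknown = set(base) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species in baseline table: {unknown}")
        self.baselines = np.array([base.get(sp, 0.0) for sp in SPECIES])

    # ------------------------------------------------------------------
    def reaction_rates(self, c: np.ndarray,
                       platelet_phi: np.ndarray | float = 0.0) -> np.ndarray:
        """Bulk net production rates, nM/s.

        Parameters
        ----------
        c : ndarray (..., n_species)
            Local concentrations, nM (non-negative).
        platelet_phi : ndarray or float
            Bound-platelet volume fraction, gates complex assembly.

        Returns
        -------
        ndarray, same shape as ``c``.
        """
        c = np.asarray(c, dtype=float)
        k = self.k
        P = np.minimum(1.0, np.asarray(platelet_phi) / self.phi_ref)

        r_ten_on = P * k["kon_tenase"] * c[..., S["IXa"]] * c[..., S["VIIIa"]]
        r_ten_off = k["koff_tenase"] * c[..., S["tenase"]]
        r_pro_on = P * k["kon_prothrombinase"] * c[..., S["Xa"]] * c[..., S["Va"]]
        r_pro_off = k["koff_prothrombinase"] * c[..., S["prothrombinase"]]
        r_x = (k["kcat_tenase_x"] * c[..., S["tenase"]] * c[..., S["X"]]
               / (k["km_tenase_x"] + c[..., S["X"]]))
        r_ii = (k["kcat_prothrombinase"] * c[..., S["prothrombinase"]]
                * c[..., S["II"]] / (k["km_prothrombinase"] + c[..., S["II"]]))
        r_ii_xa = k["k_ii_by_xa"] * c[..., S["Xa"]] * c[..., S["II"]]
        r_v = k["k_v_by_iia"] * c[..., S["IIa"]] * c[..., S["V"]]
        r_viii = k["k_viii_by_iia"] * c[..., S["IIa"]] * c[..., S["VIII"]]
        r_vii_xa = k["k_vii_by_xa"] * c[..., S["Xa"]] * c[..., S["VII"]]
        r_vii_iia = k["k_vii_by_iia"] * c[..., S["IIa"]] * c[..., S["VII"]]
        # fibrin anchors to the platelet aggregate: deposition is gated by
        # clot presence, soluble fibrin elsewhere is washed out (not tracked)
        P_fib = np.clip((np.asarray(platelet_phi) - self.phi_fibrin_on)
                        / (self.phi_fibrin_full - self.phi_fibrin_on),
                        0.0, 1.0)
        r_fib = (P_fib * k["kcat_fibrin"] * c[..., S["IIa"]]
                 * c[..., S["fibrinogen"]]
                 / (k["km_fibrin"] + c[..., S["fibrinogen"]]))
        r_tfpi_on = k["kon_tfpi_xa"] * c[..., S["TFPI"]] * c[..., S["Xa"]]
        r_tfpi_off = k["koff_tfpi_xa"] * c[..., S["Xa_TFPI"]]

        d = np.zeros_like(c)
        d[..., S["VII"]] = -r_vii_xa - r_vii_iia
        d[..., S["VIIa"]] = r_vii_xa + r_vii_iia
        d[..., S["IXa"]] = -r_ten_on + r_ten_off
        d[..., S["X"]] = -r_x
        d[..., S["Xa"]] = r_x - r_pro_on + r_pro_off - r_tfpi_on + r_tfpi_off
        d[..., S["II"]] = -r_ii - r_ii_xa
        d[..., S["IIa"]] = r_ii + r_ii_xa
        d[..., S["V"]] = -r_v
        d[..., S["Va"]] = r_v - r_pro_on + r_pro_off
        d[..., S["VIII"]] = -r_viii
        d[..., S["VIIIa"]] = r_viii - r_ten_on + r_ten_off
        d[..., S["tenase"]] = r_ten_on - r_ten_off
        d[..., S["prothrombinase"]] = r_pro_on - r_pro_off
        d[..., S["fibrinogen"]] = -r_fib
        d[..., S["fibrin"]] = r_fib
        d[..., S["TFPI"]] = -r_tfpi_on + r_tfpi_off
        d[..., S["Xa_TFPI"]] = r_tfpi_on - r_tfpi_off
        return d

    # ------------------------------------------------------------------
    def surface_reaction_flux(self, sigma: np.ndarray, c_near: np.ndarray,
                              dy_m: float) -> tuple[np.ndarray, np.ndarray]:
        """Thrombogenic-surface rates and the bulk source they inject.

        Parameters
        ----------
        sigma : ndarray (n_faces, 4)
            Surface densities [TF, TF:VII, TF:VIIa, dead], mol/m².
        c_near : ndarray (n_faces, n_species)
            Concentrations in the wall-adjacent cells, nM.
        dy_m : float
            Wall-cell height in metres (converts area flux to volume source).

        Returns
        -------
        (dsigma_dt, dc_dt) : surface rates (mol/m²/s) and bulk source for
        the adjacent cells (nM/s).
        """
        p = self.surf
        tf, tf7, tf7a = sigma[:, 0], sigma[:, 1], sigma[:, 2]
        # kon are 1/(M s); near-wall concentrations converted nM -> M
        c7 = c_near[:, S["VII"]] * _NM_TO_M
        c7a = c_near[:, S["VIIa"]] * _NM_TO_M
        cxa = c_near[:, S["Xa"]] * _NM_TO_M
        cq = c_near[:, S["Xa_TFPI"]] * _NM_TO_M

        r_bind7 = p["kon_tf_vii"] * c7 * tf - p["koff_tf_vii"] * tf7
        r_bind7a = p["kon_tf_viia"] * c7a * tf - p["koff_tf_viia"] * tf7a
        r_act = p["k_tfvii_act_by_xa"] * cxa * tf7
        r_inh = p["k_tfviia_inhib"] * cq * tf7a
        cx = c_near[:, S["X"]]
        cix = c_near[:, S["IX"]]
        j_xa = p["kcat_x"] * tf7a * cx / (p["km_x"] + cx)       # mol/m^2/s
        j_ixa = p["kcat_ix"] * tf7a * cix / (p["km_ix"] + cix)

        dsig = np.zeros_like(sigma)
        dsig[:, 0] = -r_bind7 - r_bind7a
        dsig[:, 1] = r_bind7 - r_act
        dsig[:, 2] = r_bind7a + r_act - r_inh
        dsig[:, 3] = r_inh

        # mol/m^2/s -> mol/m^3/s -> nM/s  (1 nM = 1e-6 mol/m^3)
        to_nm = 1.0 / dy_m / 1e-6
        dc = np.zeros_like(c_near)
        dc[:, S["VII"]] = -r_bind7 * to_nm
        dc[:, S["VIIa"]] = -r_bind7a * to_nm
        dc[:, S["X"]] = -j_xa * to_nm
        dc[:, S["Xa"]] = (j_xa - r_act) * to_nm
        dc[:, S["IX"]] = -j_ixa * to_nm
        dc[:, S["IXa"]] = j_ixa * to_nm
        dc[:, S["Xa_TFPI"]] = -r_inh * to_nm
        return dsig, dc

    # ------------------------------------------------------------------
    def integrate_well_mixed(self, c0: np.ndarray, t_end: float,
                             dt: float = 0.02,
                             platelet_phi: float = 1.0) -> np.ndarray:
        """Integrate a closed well-mixed volume with classical RK4.

        Used both by the transport reaction sub-step (vectorized over
        cells) and directly in tests against an independent stiff-ODE
        integration of the same table.
        """
        c = np.asarray(c0, dtype=float).copy()
        n = max(1, int(round(t_end / dt)))
        h = t_end / n
        for _ in range(n):
            c = rk4_step(lambda x: self.reaction_rates(x, platelet_phi), c, h)
            np.clip(c, 0.0, None, out=c)
        return c


def rk4_step(f, y: np.ndarray, h: float) -> np.ndarray:
    k1 = f(y)
    k2 = f(np.clip(y + 0.5 * h * k1, 0.0, None))
    k3 = f(np.clip(y + 0.5 * h * k2, 0.0, None))
    k4 = f(np.clip(y + h * k3, 0.0, None))
    return y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
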