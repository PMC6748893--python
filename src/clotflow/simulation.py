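"""Coupled clot-growth simulation and condition-level analyses.

One macro time step (default 0.5 s) advances, in order: transport of all
mobile species and mobile platelets (implicit advection-diffusion),
platelet margination, coagulation chemistry (bulk + thrombogenic surface),
thrombin-driven platelet activation, and platelet capture.  The flow and
the shear-dependent diffusivities are refreshed at a coarser cadence
(default every 10 macro steps): the Brinkman resistance that feeds back on
the flow evolves over tens of seconds, so a quasi-steady flow is an
accurate and much cheaper reduction.

The four canonical experimental conditions cross a short (20 µm) or long
(100 µm) thrombogenic surface with a low (0.1/µm²) or high (2/µm²) TF
surface density at a 1000 1/s arterial wall shear rate.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .flow import FlowState, FluidProperties, shear_field, solve_flow
from .geometry import ChannelGeometry, StructuredMesh, build_mesh, surface_site_density
from .network import S, ReactionNetwork, load_network_config
from .platelets import (PlateletParams, PlateletState, activation_step,
                        adhesion_aggregation_step, margination_profile,
                        margination_redistribution,
                        resistance_from_composition)
from .transport import (SpeciesFields, TransportOperator, advance_transport,
                        effective_diffusivity, react_step)

#: canonical condition name -> (surface_length µm, tf_density molecules/µm²)
CONDITIONS = {
    "short_low": (20.0, 0.1),
    "short_high": (20.0, 2.0),
    "long_low": (100.0, 0.1),
    "long_high": (100.0, 2.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for one clot-growth simulation."""

    condition: str = "long_high"
    geometry: ChannelGeometry | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)
    platelet: PlateletParams = field(default_factory=PlateletParams)
    dx: float = 2.0               # µm
    dy: float = 2.0
    dt: float = 0.5               # s, macro (coupling) step
    flow_every: int = 10          # macro steps between flow re-solves
    t_end: float = 450.0          # s
    sample_every: float = 50.0    # s, kinetics cadence
    snapshot_times: tuple = (400.0,)
    seed: int = 0
    network_config: str | None = None

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.condition not in CONDITIONS and self.geometry is None:
            raise ValueError(
                f"condition must be one of {sorted(CONDITIONS)} or a custom "
                "geometry must be supplied")

    def resolve_geometry(self) -> ChannelGeometry:
        if self.geometry is not None:
            return self.geometry
        length, tf = CONDITIONS[self.condition]
        return ChannelGeometry(surface_length=length, tf_density=tf)


@dataclass
class SimulationOutput:
    """Kinetics, snapshots and final state of one coupled run."""

    config: SimulationConfig
    mesh: StructuredMesh
    kinetics: pd.DataFrame          # time_s, platelet, thrombin, fibrin
    snapshots: dict                 # time -> {"phi_bound","fibrin","resistance","u","v","shear"}
    final_species: SpeciesFields
    final_platelets: PlateletState
    wall_time_s: float = 0.0


def simulate_clot_growth(config: SimulationConfig,
                         progress: bool = False) -> SimulationOutput:
    """Run one coupled clot-growth simulation.

    Deterministic: identical configs produce bit-identical kinetics.
    """
    t_start = time.time()
    geom = config.resolve_geometry()
    mesh = build_mesh(geom, config.dx, config.dy)
    network = ReactionNetwork(
        config=load_network_config(config.network_config))
    fields = SpeciesFields.initial(mesh, network,
                                   surface_site_density(geom.tf_density))
    platelets = PlateletState.initial(mesh, config.platelet)
    marg = margination_profile(mesh, config.platelet)
    sh_cfg = network.config["shear_enhancement"]
    d_classes = dict(network.config["diffusivity"])

    n_steps = int(round(config.t_end / config.dt))
    records = []
    snapshots: dict[float, dict] = {}
    snap_times = sorted(config.snapshot_times)
    flow: FlowState | None = None
    operator: TransportOperator | None = None
    resistance = np.zeros(mesh.shape)

    def sample(t):
        records.append({
            "time_s": t,
            "platelet": platelets.bound_total(),
            "thrombin": fields.total("IIa"),
            "fibrin": fields.total("fibrin"),
        })

    sample(0.0)
    next_sample = config.sample_every
    for step in range(n_steps):
        t = (step + 1) * config.dt
        try:
            if step % config.flow_every == 0:
                resistance = resistance_from_composition(
                    platelets.phi_bound, fields.conc[:, :, S["fibrin"]])
                flow = solve_flow(mesh, config.fluid, resistance)
                gamma = shear_field(flow)
                d_shear = effective_diffusivity(
                    0.0, gamma, sh_cfg["hematocrit"], sh_cfg["k_sh"],
                    sh_cfg["rbc_radius_um"] * 1e-6)
                operator = TransportOperator(mesh, flow, d_classes, d_shear,
                                             config.dt)
            fields = advance_transport(fields, flow, config.dt,
                                       network=network, operator=operator)
            platelets.mobile_resting = operator.step_class(
                "platelet", platelets.mobile_resting,
                config.platelet.baseline_count)
            platelets.mobile_activated = operator.step_class(
                "platelet", platelets.mobile_activated, 0.0)
            platelets = margination_redistribution(platelets, marg)
            fields = react_step(fields, platelets.phi_bound, config.dt,
                                network)
            platelets = activation_step(platelets,
                                        fields.conc[:, :, S["IIa"]],
                                        config.dt)
            platelets = adhesion_aggregation_step(platelets, config.dt)
        except Exception as exc:
            raise RuntimeError(
                f"simulation stage failed at t={t:.1f} s "
                f"(condition {config.condition}): {exc}") from exc

        if t >= next_sample - 1e-9:
            sample(t)
            next_sample += config.sample_every
        while snap_times and t >= snap_times[0] - 1e-9:
            snapshots[snap_times.pop(0)] = {
                "phi_bound": platelets.phi_bound.copy(),
                "fibrin": fields.conc[:, :, S["fibrin"]].copy(),
                "resistance": resistance_from_composition(
                    platelets.phi_bound, fields.conc[:, :, S["fibrin"]]),
                "u": flow.u.copy(), "v": flow.v.copy(),
                "shear": shear_field(flow),
            }
        if progress and (step + 1) % 100 == 0:
            print(f"  t={t:6.1f} s  phi_max={platelets.phi_bound.max():.3f} "
                  f"IIa_tot={fields.total('IIa'):.3g} "
                  f"Fn_tot={fields.total('fibrin'):.3g}", flush=True)

    return SimulationOutput(
        config=config, mesh=mesh,
        kinetics=pd.DataFrame.from_records(records),
        snapshots=snapshots, final_species=fields,
        final_platelets=platelets, wall_time_s=time.time() - t_start)


# ----------------------------------------------------------------------
def normalize_kinetics(series: dict[str, pd.DataFrame],
                       analytes: tuple = ("platelet", "thrombin", "fibrin"),
                       ) -> dict[str, pd.DataFrame]:
    """Normalize each analyte by its maximum across all conditions/times.

    Mirrors the arbitrary-unit comparison of fluorescence and simulation:
    after division the family maximum of every analyte is exactly 1, and
    ratios between conditions at any fixed time are unchanged.
    """
    if not series:
        raise ValueError("no kinetics series supplied")
    out = {k: df.copy() for k, df in series.items()}
    for analyte in analytes:
        peak = max(df[analyte].max() for df in series.values())
        if peak <= 0:
            raise ValueError(f"all-zero series for {analyte}: nothing to normalize")
        for df in out.values():
            df[analyte] = df[analyte] / peak
    return out


def synergy_ratio(outputs: dict[str, SimulationOutput | pd.DataFrame],
                  analyte: str = "thrombin", t: float = 450.0) -> dict:
    """Fold changes at time t between the four canonical conditions.

    Returns the combined-condition ratio total(long_high)/total(short_low)
    plus the two single-factor ratios.  A zero denominator is reported as
    inf with a flag.
    """
    def value(key):
        obj = outputs[key]
        df = obj.kinetics if isinstance(obj, SimulationOutput) else obj
        row = df.loc[(df["time_s"] - t).abs().idxmin()]
        return float(row[analyte])

    lo = value("short_low")
    hi = value("long_high")
    res = {
        "combined": hi / lo if lo > 0 else float("inf"),
        "length_only": value("long_low") / lo if lo > 0 else float("inf"),
        "density_only": value("short_high") / lo if lo > 0 else float("inf"),
        "zero_denominator": lo <= 0,
    }
    return res


def run_all_conditions(base: SimulationConfig | None = None,
                       progress: bool = False,
                       ) -> dict[str, SimulationOutput]:
    """Run the four canonical conditions with shared numerics."""
    base = base or SimulationConfig()
    out = {}
    for name in CONDITIONS:
        cfg = dc_replace(base, condition=name, geometry=None)
        out[name] = simulate_clot_growth(cfg, progress=progress)
    return out
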