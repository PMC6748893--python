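"""Synthetic microfluidic datasets with the structure the pipeline assumes.

No measured fluorescence data accompany this package, so every processing
stage is exercised on generated data with known ground truth: per-condition
deposition profiles for 5 donors x 4 repetitions (smooth squared-cosine
bumps with center jitter, donor scatter, additive noise, monotone growth
in time and occasional spurious secondary bumps), and per-analyte
fluorescence-like kinetics sampled every 50 s to 450 s whose plateaus
encode the observed condition ordering — in particular a 20-fold
thrombin/fibrin plateau ratio between the combined long-surface/high-TF
condition and the short/low condition.

Profiles are generated in height-equivalent units (µm) so they compare
directly to simulated deposition domains; an arbitrary-unit scale can be
applied afterwards to exercise normalization.  Regeneration with the same
seed is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import DepositionProfile

#: experimental mean peak heights at 400 s, µm, by condition
DEFAULT_PEAK_HEIGHTS = {
    "short_low": 7.5,
    "short_high": 13.0,
    "long_low": 14.5,
    "long_high": 16.0,
}

#: kinetics plateaus (arbitrary units) encoding the condition ordering and
#: the ~20-fold thrombin/fibrin synergy; platelet synergy is milder
DEFAULT_PLATEAUS = {
    "short_low": {"platelet": 0.25, "thrombin": 0.05, "fibrin": 0.05},
    "short_high": {"platelet": 0.45, "thrombin": 0.30, "fibrin": 0.30},
    "long_low": {"platelet": 0.55, "thrombin": 0.35, "fibrin": 0.35},
    "long_high": {"platelet": 1.0, "thrombin": 1.0, "fibrin": 1.0},
}


@dataclass(frozen=True)
class ConditionSpec:
    """Statistical description of one experimental condition."""

    name: str = "long_high"
    surface_length: float = 100.0        # µm
    tf_density: float = 2.0              # molecules/µm²
    peak_height_mean: float = 16.0       # µm at 400 s
    peak_height_sd: float = 4.0          # µm, event-to-event
    profile_length: float = 160.0        # µm full width of the bump
    center_jitter_sd: float = 25.0       # µm, instrument frame offset
    noise_sd: float = 0.4                # µm additive per point
    spurious_probability: float = 0.1
    donor_cv: float = 0.25               # lognormal donor multiplier CV
    growth_exponent: float = 1.0         # height ~ (t/400)^g
    kinetics_plateaus: dict = field(
        default_factory=lambda: dict(DEFAULT_PLATEAUS["long_high"]))
    kinetics_rise_s: float = 150.0       # saturating-rise time constant
    channel_height: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spurious_probability <= 1.0):
            raise ValueError("spurious_probability must be in [0,1]")
        if min(self.peak_height_sd, self.noise_sd, self.center_jitter_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.peak_height_mean > self.channel_height:
            raise ValueError("peak height cannot exceed the channel height")


def default_condition_specs() -> dict[str, ConditionSpec]:
    """The four canonical conditions with defaults from the study design."""
    out = {}
    for name, peak in DEFAULT_PEAK_HEIGHTS.items():
        length = 20.0 if name.startswith("short") else 100.0
        tf = 0.1 if name.endswith("low") else 2.0
        out[name] = ConditionSpec(
            name=name, surface_length=length, tf_density=tf,
            peak_height_mean=peak,
            peak_height_sd=0.3 * peak,
            profile_length=length + 120.0,
            kinetics_plateaus=dict(DEFAULT_PLATEAUS[name]))
    return out


@dataclass
class SyntheticDataset:
    """Profiles, kinetics and the ground truth that generated them."""

    profiles: list[DepositionProfile]
    ground_truth: pd.DataFrame     # one row per profile
    kinetics: pd.DataFrame | None = None
    seed: int = 0


def _bump(x: np.ndarray, center: float, half_length: float,
          height: float) -> np.ndarray:
    """Smooth concave squared-cosine bump of given height and support."""
    arg = (x - center) / half_length
    out = np.where(np.abs(arg) < 1.0,
                   height * np.cos(0.5 * np.pi * arg) ** 2, 0.0)
    return out


def generate_profiles(spec: ConditionSpec, n_donors: int = 5,
                      n_reps: int = 4,
                      times: tuple = (400.0,),
                      seed: int = 0,
                      grid: np.ndarray | None = None) -> SyntheticDataset:
    """Generate per-donor/repetition deposition profiles with ground truth.

    Each profile is a squared-cosine bump of the configured support,
    centered at 300 µm plus a per-event frame jitter, with height =
    condition mean x lognormal donor multiplier x event scatter, growing
    monotonically in time, plus additive truncated noise; with the
    configured probability a spurious secondary bump is added well away
    from the main one.
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.arange(0.0, 600.0 + 0.5, 1.0)
    half = 0.5 * spec.profile_length
    sigma_ln = np.sqrt(np.log(1.0 + spec.donor_cv ** 2))
    donor_mult = rng.lognormal(mean=-0.5 * sigma_ln ** 2, sigma=sigma_ln,
                               size=n_donors)
    profiles, truth = [], []
    for d in range(n_donors):
        for r in range(n_reps):
            jitter = rng.normal(0.0, spec.center_jitter_sd)
            event_scale = max(0.1, rng.normal(1.0, spec.peak_height_sd
                                              / max(spec.peak_height_mean, 1e-9)))
            peak400 = spec.peak_height_mean * donor_mult[d] * event_scale
            peak400 = min(peak400, spec.channel_height)
            spurious = rng.random() < spec.spurious_probability
            sp_offset = rng.uniform(130.0, 220.0) * rng.choice([-1.0, 1.0])
            sp_height_frac = rng.uniform(0.6, 1.0)
            for t in times:
                height = peak400 * (t / 400.0) ** spec.growth_exponent
                center = 300.0 + jitter
                v = _bump(grid, center, half, height)
                if spurious:
                    v = v + _bump(grid, center + sp_offset, 0.4 * half,
                                  sp_height_frac * height)
                v = np.clip(v + rng.normal(0.0, spec.noise_sd, grid.shape),
                            0.0, None)
                profiles.append(DepositionProfile(
                    x=grid.copy(), value=v, donor=d, repetition=r,
                    condition=spec.name, time_s=t))
                truth.append({
                    "condition": spec.name, "donor": d, "repetition": r,
                    "time_s": t, "true_center": center,
                    "true_peak_height": height, "spurious": spurious})
    return SyntheticDataset(profiles=profiles,
                            ground_truth=pd.DataFrame(truth), seed=seed)


def generate_kinetics(specs: dict[str, ConditionSpec] | None = None,
                      n_donors: int = 5, n_reps: int = 4,
                      cadence_s: float = 50.0, horizon_s: float = 450.0,
                      noise_cv: float = 0.15, event_cv: float = 0.1,
                      seed: int = 0) -> pd.DataFrame:
    """Saturating-growth fluorescence kinetics for all conditions.

    Per event: value(t) = plateau x donor multiplier x event scatter x
    (1 - exp(-t/tau)) x (1 + noise).  Tidy frame with one row per
    condition/donor/repetition/analyte/time.
    """
    specs = specs or default_condition_specs()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon_s + 1e-9, cadence_s)
    rows = []
    for name, spec in specs.items():
        sigma_ln = np.sqrt(np.log(1.0 + spec.donor_cv ** 2))
        donor_mult = rng.lognormal(-0.5 * sigma_ln ** 2, sigma_ln, n_donors)
        for d in range(n_donors):
            for r in range(n_reps):
                event = rng.lognormal(-0.5 * event_cv ** 2, event_cv) \
                    if event_cv > 0 else 1.0
                for analyte, plateau in spec.kinetics_plateaus.items():
                    rise = -np.expm1(-times / spec.kinetics_rise_s)
                    noise = rng.normal(0.0, noise_cv, times.shape)
                    vals = np.clip(plateau * donor_mult[d] * event
                                   * rise * (1.0 + noise), 0.0, None)
                    for t, v in zip(times, vals):
                        rows.append({"condition": name, "donor": d,
                                     "repetition": r, "analyte": analyte,
                                     "time_s": t, "value": v})
    return pd.DataFrame(rows)
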