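"""Measurement-style processing of platelet deposition profiles.

A deposition profile is the platelet signal (height or fluorescence,
already width-averaged) versus the channel-length coordinate.  Because the
instrument frame differs between clotting events, profiles must be aligned
before averaging: the upstream/downstream edges of the accumulation region
are detected as the outermost crossings of a fraction of the profile
maximum, each profile is shifted so its edge midpoint sits at 300 µm, and
profiles with spurious accumulation (too much signal outside the main
region, or a comparable second peak far from the first) are filtered out.
Ensembles then report pointwise mean ± SD bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: alignment target for profile centers, µm
ALIGN_CENTER = 300.0


@dataclass
class DepositionProfile:
    """Signal vs length coordinate for one clotting event at one time."""

    x: np.ndarray           # µm, strictly increasing, uniform
    value: np.ndarray       # height (µm) or intensity (a.u.), >= 0
    donor: int = 0
    repetition: int = 0
    condition: str = ""
    time_s: float = np.nan

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.value.shape:
            raise ValueError("x and value must be matching 1-D arrays")
        dx = np.diff(self.x)
        if len(dx) and (np.any(dx <= 0)
                        or not np.allclose(dx, dx[0], rtol=1e-6)):
            raise ValueError("x must be strictly increasing and uniform")
        if np.any(self.value < -1e-12):
            raise ValueError("profile values must be non-negative")


@dataclass
class ProfileEnsemble:
    """Aligned profiles on a common grid with mean and SD."""

    x: np.ndarray
    profiles: list[DepositionProfile]
    rejected: list[tuple[DepositionProfile, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.profiles)

    def values(self) -> np.ndarray:
        return np.vstack([p.value for p in self.profiles])


def detect_edges(profile: DepositionProfile,
                 level: float = 0.1,
                 min_run: int = 5) -> tuple[float, float]:
    """Outermost sustained crossings of ``level·max(value)``.

    Only runs of at least ``min_run`` consecutive supra-threshold samples
    count as accumulation, so isolated noise spikes cannot masquerade as a
    profile edge.  Returns (x_up, x_down); the profile center is their
    midpoint.  Raises on an all-zero profile ("no accumulation").
    """
    v = profile.value
    peak = v.max()
    if peak <= 0:
        raise ValueError("no accumulation: profile is identically zero")
    thr = level * peak
    above = v >= thr
    # run-length filter: drop above-threshold runs shorter than min_run
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:].astype(int)
                            - padded[:-1].astype(int) == 1)
    ends = np.flatnonzero(padded[1:].astype(int)
                          - padded[:-1].astype(int) == -1)
    long_runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min(
        min_run, len(v))]
    if not long_runs:
        raise ValueError("no accumulation: no sustained supra-level region")
    i0 = long_runs[0][0]
    i1 = long_runs[-1][1] - 1
    x = profile.x

    def cross(i_out, i_in):
        # linear interpolation between the last sub- and first supra-level
        if i_out < 0 or i_out >= len(v) or v[i_in] == v[i_out]:
            return x[i_in]
        f = (thr - v[i_out]) / (v[i_in] - v[i_out])
        return x[i_out] + f * (x[i_in] - x[i_out])

    return cross(i0 - 1, i0), cross(i1 + 1, i1)


def profile_center(profile: DepositionProfile, level: float = 0.1) -> float:
    x_up, x_down = detect_edges(profile, level)
    return 0.5 * (x_up + x_down)


def align_profiles(profiles: list[DepositionProfile],
                   level: float = 0.1,
                   grid: np.ndarray | None = None,
                   center: float = ALIGN_CENTER) -> ProfileEnsemble:
    """Shift every profile so its center sits at 300 µm.

    Values are resampled to the common grid (default 1-µm spacing over
    [0, 600] µm) by linear interpolation, zero-filled outside the measured
    range.  Profiles whose edges cannot be detected are excluded with a
    logged reason.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if grid is None:
        grid = np.arange(0.0, 600.0 + 0.5, 1.0)
    kept, rejected = [], []
    for p in profiles:
        try:
            c = profile_center(p, level)
        except ValueError as exc:
            rejected.append((p, str(exc)))
            continue
        shifted = replace(p, x=grid, value=np.interp(
            grid + (c - center), p.x, p.value, left=0.0, right=0.0))
        kept.append(shifted)
    return ProfileEnsemble(x=grid, profiles=kept, rejected=rejected)


def filter_spurious(profiles: list[DepositionProfile],
                    max_outside_fraction: float = 0.2,
                    level: float = 0.1,
                    twin_peak_ratio: float = 0.5,
                    twin_peak_separation: float = 100.0,
                    ) -> tuple[list[DepositionProfile],
                               list[tuple[DepositionProfile, str]]]:
    """Reject profiles with spurious accumulation.

    Two translation-invariant rules, each logged per rejection:
    (a) integrated signal outside the detected main region exceeds
    ``max_outside_fraction`` of the total; (b) a secondary peak taller
    than ``twin_peak_ratio`` of the main peak lies farther than
    ``twin_peak_separation`` from it.
    """
    kept, rejected = [], []
    for p in profiles:
        reason = _spurious_reason(p, max_outside_fraction, level,
                                  twin_peak_ratio, twin_peak_separation)
        if reason is None:
            kept.append(p)
        else:
            rejected.append((p, reason))
    return kept, rejected


def _spurious_reason(p, max_outside_fraction, level, ratio, separation):
    v, x = p.value, p.x
    if v.max() <= 0:
        return "no accumulation"
    # main region around the global peak: contiguous run above level*max.
    # Only supra-threshold signal counts toward the outside fraction, so
    # the near-zero noise floor over the long empty stretch of channel
    # cannot masquerade as spurious accumulation.
    thr = level * v.max()
    above = v >= thr
    ipk = int(np.argmax(v))
    lo = ipk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(v) - 1 and above[hi + 1]:
        hi += 1
    supra = np.clip(v - thr, 0.0, None)
    total = np.trapezoid(supra, x)
    inside = np.trapezoid(supra[lo:hi + 1], x[lo:hi + 1])
    outside_frac = 1.0 - inside / total if total > 0 else 0.0
    if outside_frac > max_outside_fraction:
        return (f"outside-fraction {outside_frac:.2f} > "
                f"{max_outside_fraction}")
    # secondary peak rule: tallest signal far from the main peak
    far = np.abs(x - x[ipk]) > separation
    if far.any() and v[far].max() > ratio * v[ipk]:
        return ("secondary peak "
                f"{v[far].max() / v[ipk]:.2f} of main at >"
                f"{separation:.0f} µm")
    return None


def ensemble_stats(ensemble: ProfileEnsemble,
                   ) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Pointwise mean profile, sample SD (None and flagged if n = 1), n."""
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    vals = ensemble.values()
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if ensemble.n >= 2 else None
    return mean, sd, ensemble.n


# ----------------------------------------------------------------------
def profiles_from_dataframe(df: pd.DataFrame) -> list[DepositionProfile]:
    """Read tidy CSV columns (condition, donor, repetition, time_s, x_um,
    value) into profile objects."""
    out = []
    keys = ["condition", "donor", "repetition", "time_s"]
    for (cond, donor, rep, t), g in df.groupby(keys, sort=True):
        g = g.sort_values("x_um")
        out.append(DepositionProfile(
            x=g["x_um"].to_numpy(), value=g["value"].to_numpy(),
            donor=int(donor), repetition=int(rep), condition=str(cond),
            time_s=float(t)))
    return out


def profiles_to_dataframe(profiles: list[DepositionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(pd.DataFrame({
            "condition": p.condition, "donor": p.donor,
            "repetition": p.repetition, "time_s": p.time_s,
            "x_um": p.x, "value": p.value}))
    return pd.concat(rows, ignore_index=True)
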