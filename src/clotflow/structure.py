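"""Core/shell clot architecture: contours, embedding, and flow metrics.

The clot has a two-zone architecture: a fibrin-rich *core* (the 1-nM
superlevel set of the fibrin field) surrounded by a platelet-rich *shell*
(the superlevel set of the bound-platelet fraction at 5% of the packing
cap).  Shells extracted from measured deposition profiles can receive an
embedded, rescaled simulated core — preserving the simulated core-to-shell
height and length ratios and the core's relative downstream offset — and
piecewise-constant resistances, after which the flow solver yields the
intraclot velocity structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage import measure

from .flow import FlowState, FluidProperties, solve_flow
from .geometry import StructuredMesh


@dataclass(frozen=True)
class RegionContour:
    """Closed polyline (µm) anchored on the bottom wall.

    ``vertices`` is an (n, 2) array of (x, y); an empty region is an
    empty array.
    """

    vertices: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.vertices.size == 0

    @property
    def peak_height(self) -> float:
        return 0.0 if self.is_empty else float(self.vertices[:, 1].max())

    @property
    def length(self) -> float:
        if self.is_empty:
            return 0.0
        x = self.vertices[:, 0]
        return float(x.max() - x.min())

    @property
    def x_range(self) -> tuple[float, float]:
        x = self.vertices[:, 0]
        return float(x.min()), float(x.max())

    @property
    def center_x(self) -> float:
        lo, hi = self.x_range
        return 0.5 * (lo + hi)

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula, µm²."""
        if self.is_empty:
            return 0.0
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1))
                               - np.dot(y, np.roll(x, -1))))

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, other: "RegionContour", tol: float = 1e-6) -> bool:
        """True if ``other`` lies inside this contour (with tolerance)."""
        if other.is_empty:
            return True
        if self.is_empty:
            return False
        return self.polygon().buffer(tol).contains(other.polygon())


def _empty() -> RegionContour:
    return RegionContour(vertices=np.empty((0, 2)))


def extract_region(field: np.ndarray, mesh: StructuredMesh,
                   threshold: float) -> RegionContour:
    """Contour of the largest connected superlevel component of a field.

    The field is padded with zeros below the wall so contours close on
    y = 0; satellite components (e.g. spurious deposits) are discarded by
    the largest-component rule.  Returns an empty contour if the field
    stays below the threshold.
    """
    if field.shape != mesh.shape:
        raise ValueError("field shape does not match mesh")
    if not (field > threshold).any():
        return _empty()
    # pad with a sub-threshold frame so that marching squares closes every
    # contour; grid in index space, converted to µm afterwards
    pad = np.full((field.shape[0] + 2, field.shape[1] + 2), -np.inf)
    pad[1:-1, 1:-1] = field
    pad[1:-1, 0] = field[:, 0]       # mirror below the wall: contour sits on y=0
    contours = measure.find_contours(pad, threshold)
    if not contours:
        return _empty()
    best, best_area = None, -1.0
    for cnt in contours:
        x = (cnt[:, 0] - 1 + 0.5) * mesh.dx
        y = (cnt[:, 1] - 1 + 0.5) * mesh.dy
        y = np.clip(y, 0.0, mesh.geometry.height)
        verts = np.column_stack([x, y])
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area > best_area:
            best, best_area = verts, poly.area
    return RegionContour(vertices=best)


def extract_core(fibrin: np.ndarray, mesh: StructuredMesh,
                 threshold_nM: float = 1.0) -> RegionContour:
    """Fibrin core: largest connected region above the 1-nM threshold."""
    return extract_region(fibrin, mesh, threshold_nM)


def extract_shell(phi_bound: np.ndarray, mesh: StructuredMesh,
                  threshold_fraction: float = 0.05,
                  phi_max: float = 0.6) -> RegionContour:
    """Platelet shell: bound fraction above ``threshold_fraction·φ_max``."""
    return extract_region(phi_bound, mesh, threshold_fraction * phi_max)


@dataclass(frozen=True)
class CoreShellPair:
    """A core nested in a shell, with their assigned Brinkman resistances."""

    core: RegionContour
    shell: RegionContour
    k_core: float = 0.0
    k_shell: float = 0.0

    def __post_init__(self) -> None:
        if self.k_shell < 0 or self.k_core < self.k_shell:
            raise ValueError("resistances must satisfy k_core >= k_shell >= 0")


def embed_core_in_shell(sim: CoreShellPair,
                        measured_shell: RegionContour) -> CoreShellPair:
    """Rescale the simulated core into a measured shell.

    The output core keeps the simulated core-to-shell height and length
    ratios (height = measured_height·H_core/H_shell, similarly for length)
    and the simulated core's relative downstream offset within its shell.
    """
    if measured_shell.is_empty:
        raise ValueError("measured shell must be non-empty")
    if sim.core.is_empty:
        return CoreShellPair(core=_empty(), shell=measured_shell,
                             k_core=sim.k_core, k_shell=sim.k_shell)
    # simulated contours are cell-accurate; marching-squares interpolation
    # can push a steep core level set up to one cell past the shell, so
    # the ratios are capped at 1 to keep the embedded core inside
    h_ratio = min(1.0, sim.core.peak_height / sim.shell.peak_height)
    l_ratio = min(1.0, sim.core.length / sim.shell.length)
    rel_offset = ((sim.core.center_x - sim.shell.center_x)
                  / sim.shell.length)

    target_h = measured_shell.peak_height * h_ratio
    target_l = measured_shell.length * l_ratio
    target_cx = (measured_shell.center_x
                 + rel_offset * measured_shell.length)

    v = sim.core.vertices.copy()
    v[:, 0] = (v[:, 0] - sim.core.center_x) * (target_l / sim.core.length) \
        + target_cx
    v[:, 1] *= target_h / sim.core.peak_height
    return CoreShellPair(core=RegionContour(vertices=v),
                         shell=measured_shell,
                         k_core=sim.k_core, k_shell=sim.k_shell)


def region_mask(region: RegionContour, mesh: StructuredMesh) -> np.ndarray:
    """Boolean mask of cells whose centers lie inside the contour."""
    if region.is_empty:
        return np.zeros(mesh.shape, dtype=bool)
    from matplotlib.path import Path
    xx, yy = np.meshgrid(mesh.xc, mesh.yc, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    path = Path(region.vertices)
    inside = path.contains_points(pts, radius=1e-9)
    return inside.reshape(mesh.shape)


def region_mean_resistance(resistance: np.ndarray, region: RegionContour,
                           mesh: StructuredMesh) -> float:
    """Area-weighted mean Brinkman coefficient over a region, 1/m²."""
    mask = region_mask(region, mesh)
    if not mask.any():
        raise ValueError("region is empty on this mesh")
    return float(resistance[mask].mean())


def occlusivity(contour: RegionContour, channel_height: float) -> float:
    """Peak clot height divided by channel height (0 for an empty clot)."""
    if contour.peak_height > channel_height + 1e-9:
        raise ValueError("contour taller than the channel")
    return contour.peak_height / channel_height


# ----------------------------------------------------------------------
@dataclass
class IntraclotMetrics:
    """Velocity structure of flow through a clot shape."""

    mean_axial: float            # m/s inside the shell
    max_axial: float
    lumen_mean_axial: float
    vertical_variation: float    # SD of u along y at the clot center
    horizontal_variation: float  # SD of u along x at fixed relative height
    low_velocity_x_range: tuple  # extent of the low-velocity region
    low_velocity_thickness_center: float = 0.0   # µm, at the clot center
    low_velocity_thickness_upstream: float = 0.0  # µm, far upstream


def flow_through_measured_shape(pair: CoreShellPair, mesh: StructuredMesh,
                                fluid: FluidProperties,
                                ) -> tuple[FlowState, IntraclotMetrics]:
    """Solve flow through a piecewise-constant core/shell resistance.

    k = k_core inside the core, k_shell in shell∖core, 0 outside, then a
    clean steady solve; returns the flow plus intraclot velocity metrics.
    """
    shell_mask = region_mask(pair.shell, mesh)
    core_mask = region_mask(pair.core, mesh) & shell_mask
    k = np.zeros(mesh.shape)
    k[shell_mask] = pair.k_shell
    k[core_mask] = pair.k_core
    state = solve_flow(mesh, fluid, k)
    uc = state.u_center

    lumen_mean = uc[~shell_mask].mean() if (~shell_mask).any() else 0.0
    if shell_mask.any():
        intra = uc[shell_mask]
        mean_ax, max_ax = float(intra.mean()), float(intra.max())
        # vertical profile at the clot's center column
        cols = np.flatnonzero(shell_mask.any(axis=1))
        icen = cols[np.argmin(np.abs(mesh.xc[cols] - pair.shell.center_x))]
        vert = uc[icen, shell_mask[icen, :]]
        v_var = float(np.std(vert))
        # horizontal profile at mid relative height within the clot
        heights = shell_mask.sum(axis=1)
        hsel = []
        for i in cols:
            j = max(0, int(0.5 * heights[i]) - 1)
            hsel.append(uc[i, j])
        h_var = float(np.std(hsel))
    else:
        mean_ax = max_ax = v_var = h_var = 0.0

    # low-velocity region: axial speed below 10% of the lumen mean.  The
    # thin near-wall no-slip layer qualifies everywhere (as it does in the
    # real device); over and around the clot the layer thickens sharply,
    # which the thickness metrics quantify.
    low = np.abs(uc) < 0.1 * abs(lumen_mean)
    lowcols = np.flatnonzero(low.any(axis=1))
    if lowcols.size:
        low_range = (float(mesh.xc[lowcols[0]]), float(mesh.xc[lowcols[-1]]))
    else:
        low_range = (np.nan, np.nan)

    def thickness(i):
        below = np.flatnonzero(~low[i, :])
        n_low = below[0] if below.size else mesh.ny
        return float(n_low * mesh.dy)

    icen = int(np.argmin(np.abs(mesh.xc - pair.shell.center_x)))
    return state, IntraclotMetrics(
        mean_axial=mean_ax, max_axial=max_ax,
        lumen_mean_axial=float(lumen_mean),
        vertical_variation=v_var, horizontal_variation=h_var,
        low_velocity_x_range=low_range,
        low_velocity_thickness_center=thickness(icen),
        low_velocity_thickness_upstream=thickness(2))
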