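"""Channel geometry and structured meshing.

The microfluidic channel is represented in 2-D: x runs along the flow from
the inlet (x = 0) to the outlet, y from the bottom wall (y = 0) to the top
wall (y = height).  A thrombogenic patch (collagen + tissue factor) occupies
an interval of the bottom wall; clot growth initiates there.  All lengths
are in micrometres unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Boundary patch names of the channel mesh.
PATCHES = ("inlet", "outlet", "top_wall", "bottom_wall", "thrombogenic_surface")


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular 2-D channel with a thrombogenic patch on the bottom wall.

    Parameters
    ----------
    length : float
        Domain extent along the flow direction, µm.
    height : float
        Channel height, µm (device: 60 µm).
    width : float
        Out-of-plane channel width, µm (device: 250 µm); used only to
        convert 2-D fluxes to volumetric quantities.
    surface_center : float
        x-coordinate of the center of the thrombogenic patch, µm.
    surface_length : float
        Length of the thrombogenic patch along the flow, µm (20 or 100).
    tf_density : float
        Tissue-factor surface density on the patch, molecules/µm²
        (0.1 "low" or 2.0 "high").
    """

    length: float = 600.0
    height: float = 60.0
    width: float = 250.0
    surface_center: float = 300.0
    surface_length: float = 20.0
    tf_density: float = 0.1

    def __post_init__(self) -> None:
        if self.height <= 0 or self.length <= 0 or self.width <= 0:
            raise ValueError("channel dimensions must be positive")
        if self.surface_length <= 0:
            raise ValueError("surface_length must be positive")
        if self.tf_density < 0:
            raise ValueError("tf_density must be non-negative")
        lo, hi = self.surface_interval
        if not (0.0 < lo and hi < self.length):
            raise ValueError(
                "thrombogenic surface must lie strictly inside the bottom wall"
            )

    @property
    def surface_interval(self) -> tuple[float, float]:
        """(x_lo, x_hi) of the thrombogenic patch, µm."""
        half = 0.5 * self.surface_length
        return (self.surface_center - half, self.surface_center + half)


@dataclass(frozen=True)
class StructuredMesh:
    """Uniform cell-centered Cartesian mesh of a :class:`ChannelGeometry`.

    Cells own the half-open box ``[x, x+dx) × [y, y+dy)``.  Bottom-wall cell
    faces belong to exactly one of ``bottom_wall`` or
    ``thrombogenic_surface``; a face is thrombogenic when its center falls
    inside the surface interval.
    """

    geometry: ChannelGeometry
    nx: int
    ny: int
    dx: float
    dy: float
    #: boolean mask over bottom-wall faces (length nx), True = thrombogenic
    thrombogenic_faces: np.ndarray = field(repr=False)

    @property
    def xc(self) -> np.ndarray:
        """Cell-center x coordinates, µm (length nx)."""
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def yc(self) -> np.ndarray:
        """Cell-center y coordinates, µm (length ny)."""
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        """(nx, ny) — field arrays are indexed [i, j] = [x, y]."""
        return (self.nx, self.ny)

    @property
    def n_thrombogenic(self) -> int:
        return int(self.thrombogenic_faces.sum())

    def patch_of_bottom_face(self, x: float) -> str:
        """Boundary patch owning the bottom-wall face whose center is nearest x."""
        i = min(self.nx - 1, max(0, int(x / self.dx)))
        return "thrombogenic_surface" if self.thrombogenic_faces[i] else "bottom_wall"


def build_mesh(geometry: ChannelGeometry, dx: float, dy: float) -> StructuredMesh:
    """Build a uniform structured mesh covering the channel exactly.

    Parameters
    ----------
    geometry : ChannelGeometry
    dx, dy : float
        Target cell sizes, µm.  The cell counts are rounded to cover the
        domain exactly; ``nx·dx == length`` and ``ny·dy == height`` must
        hold to 1e-9 relative, otherwise the sizes are rejected.

    Raises
    ------
    ValueError
        If dx or dy is non-positive, does not tile the domain, or if the
        thrombogenic surface is shorter than one cell.
    """
    if dx <= 0 or dy <= 0:
        raise ValueError("cell sizes dx, dy must be positive")
    nx = int(round(geometry.length / dx))
    ny = int(round(geometry.height / dy))
    if nx < 1 or ny < 1:
        raise ValueError("cell sizes exceed the domain")
    if abs(nx * dx - geometry.length) > 1e-9 * geometry.length:
        raise ValueError(f"dx={dx} does not tile length={geometry.length}")
    if abs(ny * dy - geometry.height) > 1e-9 * geometry.height:
        raise ValueError(f"dy={dy} does not tile height={geometry.height}")
    if geometry.surface_length < dx:
        raise ValueError(
            "thrombogenic surface shorter than one cell: "
            f"need dx <= {geometry.surface_length} µm"
        )
    xf = (np.arange(nx) + 0.5) * dx
    lo, hi = geometry.surface_interval
    faces = (xf >= lo) & (xf < hi)
    return StructuredMesh(geometry=geometry, nx=nx, ny=ny, dx=dx, dy=dy,
                          thrombogenic_faces=faces)


def surface_site_density(tf_density: float) -> float:
    """Convert a TF surface density to molar units.

    Parameters
    ----------
    tf_density : float
        molecules/µm².

    Returns
    -------
    float
        mol/m² (molecules/µm² × 1e12 µm²/m² ÷ N_A).
    """
    if tf_density < 0:
        raise ValueError("tf_density must be non-negative")
    return tf_density * 1e12 / N_AVOGADRO
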