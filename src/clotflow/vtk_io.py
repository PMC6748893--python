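"""Lightweight legacy-VTK (ASCII) structured-grid output.

Writes cell-centered scalars/vectors of a simulation snapshot as a
STRUCTURED_POINTS dataset readable by ParaView/VisIt.  Only the legacy
ASCII flavor is produced; it is a plain-text format and keeps the package
dependency-free for visualization.
"""

from __future__ import annotations

import numpy as np

from .geometry import StructuredMesh


def write_vtk(path: str, mesh: StructuredMesh,
              scalars: dict[str, np.ndarray] | None = None,
              vectors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
              title: str = "clotflow fields") -> None:
    """Write cell data on the structured mesh to a legacy-VTK file.

    Parameters
    ----------
    scalars : mapping name -> (nx, ny) array
    vectors : mapping name -> (u_center, v_center) pair of (nx, ny) arrays
    """
    nx, ny = mesh.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        "ORIGIN 0 0 0",
        f"SPACING {mesh.dx * 1e-6:.9e} {mesh.dy * 1e-6:.9e} 1",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in (scalars or {}).items():
        if arr.shape != (nx, ny):
            raise ValueError(f"scalar {name} has shape {arr.shape}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest
        lines.extend(f"{v:.9e}" for v in arr.T.ravel())
    for name, (u, v) in (vectors or {}).items():
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{a:.9e} {b:.9e} 0.0"
                     for a, b in zip(u.T.ravel(), v.T.ravel()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
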