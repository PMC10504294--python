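"""Minimal legacy-ASCII VTK writers for structured-grid exports.

Only the STRUCTURED_POINTS flavour is needed (uniform grids with scalar or
vector cell data); files are plain text and readable by ParaView/VisIt.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_structured_points(
    path: str | Path,
    spacing: tuple[float, float, float],
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Path:
    """Write point-data arrays on a uniform grid as a legacy VTK file.

    All arrays must share one (nx, ny, nz) shape (vectors: (nx, ny, nz, 3));
    data are emitted in VTK's x-fastest ordering.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    arrays = list(scalars.values()) + [v[..., 0] for v in vectors.values()]
    if not arrays:
        raise ValueError("nothing to write")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all arrays must share one grid shape")
    nx, ny, nz = shape
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nnanotear field export\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.7g")
        for name, arr in vectors.items():
            fh.write(f"VECTORS {name} float\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.7g")
    return path
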