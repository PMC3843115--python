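"""Legacy-VTK ASCII export of solved voxel models.

Writes an unstructured-grid file (hexahedra) with point displacement
vectors and cell data (modulus, label, von Mises stress), readable by
ParaView and VTK-based viewers.  The legacy ASCII format is simple enough
to emit directly, which keeps visualization support dependency-free.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fe_core import Model, SolveResult, element_stresses, von_mises

__all__ = ["write_vtk"]

# VTK_HEXAHEDRON ordering: bottom face CCW then top face CCW, matching the
# package's corner ordering exactly
_VTK_HEX = 12


def write_vtk(
    path: "str | Path",
    model: Model,
    result: "SolveResult | None" = None,
) -> None:
    path = Path(path)
    nn, ne = model.n_nodes, model.n_elements
    lines: list[str] = [
        "# vtk DataFile Version 3.0",
        "vertefem voxel model",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {nn} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in model.node_coords]
    lines.append(f"CELLS {ne} {ne * 9}")
    lines += ["8 " + " ".join(map(str, c)) for c in model.conn]
    lines.append(f"CELL_TYPES {ne}")
    lines += [str(_VTK_HEX)] * ne

    if result is not None:
        lines.append(f"POINT_DATA {nn}")
        lines.append("VECTORS displacement float")
        lines += [" ".join(f"{v:.6g}" for v in u) for u in result.displacements]

    lines.append(f"CELL_DATA {ne}")
    lines.append("SCALARS modulus_MPa float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{e:.6g}" for e in model.elem_E]
    lines.append("SCALARS label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in model.elem_label]
    if result is not None:
        vm = von_mises(element_stresses(model, result))
        lines.append("SCALARS von_mises_MPa float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in vm]

    path.write_text("\n".join(lines) + "\n")
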