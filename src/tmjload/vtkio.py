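"""Minimal legacy-ASCII VTK polydata writer for contact-surface stress maps."""

from __future__ import annotations

import numpy as np


def write_vtk_surface(path, vertices, faces, cell_data: dict | None = None) -> None:
    """Write a triangulated surface with optional per-cell scalar fields."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncontact surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for v in vertices:
            fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(faces)}\n")
            for name, values in cell_data.items():
                values = np.asarray(values, dtype=float)
                if len(values) != len(faces):
                    raise ValueError(
                        f"cell data {name!r} has {len(values)} values for {len(faces)} cells")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in values:
                    fh.write(f"{x:.6g}\n")


def read_vtk_cell_scalars(path) -> dict[str, np.ndarray]:
    """Read back the per-cell scalar fields (round-trip checks)."""
    fields: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_cells = 0
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["CELL_DATA"]:
            n_cells = int(tok[1])
        elif tok[:1] == ["SCALARS"]:
            name = tok[1]
            vals = [float(lines[j]) for j in range(i + 2, i + 2 + n_cells)]
            fields[name] = np.array(vals)
            i += 1 + n_cells
        i += 1
    return fields
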