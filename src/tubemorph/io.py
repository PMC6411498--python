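"""Readers and writers for the pipeline's on-disk formats.

Triangle meshes: PLY (binary little-endian) / OFF / STL via trimesh, plus a
minimal VTK legacy polydata writer for visualisation tools. Grid surfaces
and statistical maps: VTK legacy structured grids with point data, plus
JSON sidecars. Masks: NIfTI-1 via nibabel (gzip accepted).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .correspondence import DeformationField, GridSurface


def write_mesh(path, mesh: trimesh.Trimesh) -> None:
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        write_vtk_polydata(path, mesh)
    else:
        mesh.export(str(path))


def read_mesh(path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh", process=False)
    return trimesh.Trimesh(vertices=np.asarray(m.vertices),
                           faces=np.asarray(m.faces), process=False)


def write_vtk_polydata(path, mesh: trimesh.Trimesh,
                       point_data: dict | None = None) -> None:
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntubemorph surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        np.savetxt(fh, v, fmt="%.8g")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(f), 3), f]), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float).ravel()
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, values, fmt="%.8g")


def write_vtk_structured_grid(path, grid: GridSurface,
                              point_data: dict | None = None) -> None:
    n_u, n_v = grid.shape
    pos = grid.positions.reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntubemorph grid surface\nASCII\n")
        fh.write("DATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {n_v} {n_u} 1\n")
        fh.write(f"POINTS {n_u * n_v} double\n")
        np.savetxt(fh, pos, fmt="%.8g")
        data = {"conformal_factor": grid.conformal_factor,
                "mean_curvature": grid.mean_curvature}
        if point_data:
            data.update(point_data)
        fh.write(f"POINT_DATA {n_u * n_v}\n")
        for name, values in data.items():
            values = np.asarray(values, dtype=float).ravel()
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, values, fmt="%.8g")


def save_grid_surface(path_stem, grid: GridSurface) -> None:
    """VTK structured grid plus a JSON sidecar with the grid metadata."""
    stem = Path(path_stem)
    write_vtk_structured_grid(stem.with_suffix(".vtk"), grid)
    sidecar = {"grid_shape": [int(s) for s in grid.shape],
               "subject_id": grid.subject_id,
               "fallback_nodes": int(grid.fallback_nodes)}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_deformation_field(path_stem, field: DeformationField) -> None:
    stem = Path(path_stem)
    np.savez(stem.with_suffix(".npz"), forward=field.forward,
             backward=field.backward)
    sidecar = {"ic_p95_cells": float(field.ic_p95),
               "params": {k: (v if isinstance(v, (int, float, bool)) else str(v))
                          for k, v in field.params.__dict__.items()},
               "convergence_iterations": {
                   k: (len(v) if isinstance(v, list) else v)
                   for k, v in field.convergence.items()}}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
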