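"""File formats: meshes (PLY/STL/legacy VTK), momenta, NIfTI volumes.

All coordinates are millimetres.  PLY and STL go through :mod:`trimesh`;
legacy ASCII VTK polydata is read/written directly because it is the one
format here that also carries per-vertex scalar fields (statistic maps
on the template).  Momenta and control grids are stored as plain CSV
with a JSON sidecar holding the kernel widths and grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .deformation import ControlPointGrid, MomentaField
from .mesh import SurfaceMesh

# -- meshes -------------------------------------------------------------


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return _read_vtk(path)
    import trimesh
    tm = trimesh.load(path, process=False, force="mesh")
    return SurfaceMesh.from_trimesh(tm, name=path.stem)


def write_mesh(mesh: SurfaceMesh, path,
               point_scalars: dict[str, np.ndarray] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".vtk":
        _write_vtk(mesh, path, point_scalars or {})
        return
    if point_scalars:
        raise ValueError("per-vertex scalars require the .vtk format")
    mesh.to_trimesh().export(path)


def _read_vtk(path: Path) -> SurfaceMesh:
    """Minimal legacy ASCII VTK polydata reader (POINTS + POLYGONS)."""
    tokens = path.read_text().split()
    i = 0

    def seek(word):
        nonlocal i
        while i < len(tokens) and tokens[i].upper() != word:
            i += 1
        if i == len(tokens):
            raise ValueError(f"{word} section not found in {path}")

    seek("POINTS")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i += 3 + 3 * n
    seek("POLYGONS")
    nf = int(tokens[i + 1])
    i += 3
    faces = []
    for _ in range(nf):
        k = int(tokens[i])
        if k != 3:
            raise ValueError("only triangle polygons are supported")
        faces.append([int(tokens[i + 1]), int(tokens[i + 2]),
                      int(tokens[i + 3])])
        i += 4
    return SurfaceMesh(coords, np.array(faces, dtype=int), name=path.stem)


def _write_vtk(mesh: SurfaceMesh, path: Path,
               point_scalars: dict[str, np.ndarray]) -> None:
    lines = ["# vtk DataFile Version 3.0", "tavimorph surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_vertices} float"]
    lines += [" ".join(f"{x:.6f}" for x in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += ["3 " + " ".join(str(j) for j in f) for f in mesh.faces]
    if point_scalars:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, values in point_scalars.items():
            values = np.asarray(values, dtype=float)
            if len(values) != mesh.n_vertices:
                raise ValueError(f"scalar field '{name}' length mismatch")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in values]
    path.write_text("\n".join(lines) + "\n")


# -- momenta and control grids -------------------------------------------


def write_momenta(momenta: MomentaField, grid: ControlPointGrid, path,
                  meta: dict | None = None) -> None:
    """CSV of control-point coordinates and momentum components.

    A JSON sidecar ``<path>.json`` records the grid spacing/margin and
    any extra metadata (kernel widths, subject id, ...).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.hstack([grid.points, momenta.vectors])
    header = "cx,cy,cz,ax,ay,az"
    np.savetxt(path, data, delimiter=",", header=header, comments="")
    sidecar = {"spacing": grid.spacing, "margin": grid.margin,
               "reference": momenta.reference}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_momenta(path) -> tuple[MomentaField, ControlPointGrid, dict]:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = ControlPointGrid(data[:, :3], spacing=meta["spacing"],
                            margin=meta.get("margin", 0.0))
    momenta = MomentaField(data[:, 3:6], reference=meta.get("reference", ""))
    return momenta, grid, meta


# -- volumes -------------------------------------------------------------


def write_volume(data: np.ndarray, origin, path, spacing: float = 1.0) -> None:
    """Write a scalar volume as NIfTI with a diagonal mm affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a NIfTI file."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
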