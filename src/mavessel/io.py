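"""Plain-text import/export: XYZ and VTK-legacy particle/mesh files, OFF
meshes, track tables and geometry archives."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dpd import TYPE_NAMES
from .geometry import MAChannelGeometry
from .meshes import TriangulatedMembrane, build_topology


def write_xyz(path, positions: np.ndarray, types=None, comment: str = ""):
    """Extended-XYZ frame (one species letter per particle type)."""
    letters = {0: "S", 1: "W", 2: "R", 3: "P"}
    n = len(positions)
    with open(path, "w") as fh:
        fh.write(f"{n}\n{comment}\n")
        for k in range(n):
            sp = letters.get(int(types[k]) if types is not None else 0, "X")
            fh.write(f"{sp} {positions[k, 0]:.6f} {positions[k, 1]:.6f} "
                     f"{positions[k, 2]:.6f}\n")


def write_vtk_particles(path, positions: np.ndarray, types=None):
    """Legacy-VTK polydata point cloud with a particle-type scalar."""
    n = len(positions)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nparticles\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in positions:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        if types is not None:
            fh.write(f"POINT_DATA {n}\nSCALARS type int 1\n"
                     "LOOKUP_TABLE default\n")
            for t in types:
                fh.write(f"{int(t)}\n")


def write_vtk_mesh(path, mesh: TriangulatedMembrane):
    """Legacy-VTK polydata triangle mesh."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmembrane\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for p in mesh.x:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        f = mesh.n_triangles
        fh.write(f"POLYGONS {f} {4 * f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def write_off(path, mesh: TriangulatedMembrane):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} {mesh.n_edges}\n")
        for p in mesh.x:
            fh.write(f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path) -> TriangulatedMembrane:
    lines = [ln.strip() for ln in open(path) if ln.strip()
             and not ln.startswith("#")]
    if lines[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf, _ = (int(v) for v in lines[1].split())
    x = np.array([[float(v) for v in ln.split()[:3]]
                  for ln in lines[2:2 + nv]])
    tris = np.array([[int(v) for v in ln.split()[1:4]]
                     for ln in lines[2 + nv:2 + nv + nf]], dtype=np.int64)
    edges, opp = build_topology(tris)
    mesh = TriangulatedMembrane(x=x, triangles=tris, edges=edges,
                                edge_opposite=opp)
    mesh.set_reference()
    return mesh


def write_tracks_tsv(path, tracks: pd.DataFrame):
    tracks.to_csv(path, sep="\t", index=False)


def read_tracks_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_geometry_json(path, geom: MAChannelGeometry):
    payload = {
        "bnr": geom.bnr, "r2": geom.r2, "depth": geom.depth,
        "length": geom.L, "neck_width": geom.neck_width,
        "R1": geom.R1, "body_center": list(geom.body_center),
        "lumen_volume_um3": geom.lumen_volume,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_geometry_json(path) -> MAChannelGeometry:
    d = json.loads(Path(path).read_text())
    return MAChannelGeometry(bnr=d["bnr"], r2=d["r2"], depth=d["depth"],
                             length=d["length"],
                             neck_width=d["neck_width"])
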