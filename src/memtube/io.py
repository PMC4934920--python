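"""Configuration, mesh/filament file I/O, and run manifests.

Meshes are exchanged as OFF or PLY via trimesh; per-frame visualization
export additionally supports legacy ASCII VTK (hand-written: no installed
package emits the legacy format).  Observables stream as CSV; filament
trajectories as CSV (frame, filament, node, x, y, z) or XYZ.  Every run can
write a manifest recording parameters, seeds and package version.
"""

from __future__ import annotations

import csv
import json
import time
from pathlib import Path

import numpy as np
import trimesh as _trimesh
import yaml

from .mesh import TriMesh


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_manifest(path, config, seed, extra=None):
    payload = {
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "package": "memtube",
        "version": _version(),
        "seed": int(seed),
        "config": config,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_np_safe))


def _np_safe(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _version():
    try:
        from importlib.metadata import version

        return version("memtube")
    except Exception:
        return "unknown"


# ------------------------------------------------------------------ meshes

def export_mesh(mesh: TriMesh, path):
    """Write the current triangulation as OFF, PLY, or legacy ASCII VTK."""
    path = Path(path)
    ids = mesh.vertex_ids
    remap = {int(v): i for i, v in enumerate(ids)}
    verts = mesh.m.pos[ids]
    faces = np.array([[remap[int(w)] for w in f] for f in mesh.faces()])
    suffix = path.suffix.lower()
    if suffix in (".off", ".ply"):
        tm = _trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        tm.export(path)
    elif suffix == ".vtk":
        _write_legacy_vtk(path, verts, faces)
    else:
        raise ValueError(f"unsupported mesh format {suffix}")
    return path


def import_mesh(path, Lx, Ly, frozen=()):
    """Load an OFF/PLY triangulation into a periodic TriMesh."""
    tm = _trimesh.load(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces, np.int32),
                   Lx, Ly, frozen=frozen)


def _write_legacy_vtk(path, verts, faces):
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\nmemtube frame\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} float\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# --------------------------------------------------------------- filaments

def write_filament_csv(path, filaments, frame=0, mode="w"):
    with open(path, mode, newline="") as fh:
        w = csv.writer(fh)
        if mode == "w":
            w.writerow(["frame", "filament", "node", "x", "y", "z"])
        for fi, f in enumerate(filaments):
            for ni, p in enumerate(f.nodes):
                w.writerow([frame, fi, ni,
                            f"{p[0]:.4f}", f"{p[1]:.4f}", f"{p[2]:.4f}"])


def write_filament_xyz(path, filaments, comment="", mode="w"):
    n = sum(len(f.nodes) for f in filaments)
    with open(path, mode) as fh:
        fh.write(f"{n}\n{comment}\n")
        for fi, f in enumerate(filaments):
            for p in f.nodes:
                fh.write(f"F{fi} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def write_observables_csv(path, rows, header):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def write_event_log(path, traj):
    """Growth event log as JSONL (time, filament, event, length, height)."""
    names = {0: "on", 1: "on-rejected", 2: "off", 3: "off-null"}
    with open(path, "w") as fh:
        for t, fi, ev, n, h in zip(traj.times, traj.filament, traj.event,
                                   traj.length, traj.height):
            fh.write(json.dumps({
                "t": float(t), "filament": int(fi), "event": names[int(ev)],
                "n": int(n), "height": float(h)}) + "\n")
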