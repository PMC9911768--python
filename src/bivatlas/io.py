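"""Mesh and subject-table I/O.

Surfaces are written as legacy ASCII VTK polydata carrying the vertex-level
integer arrays ``surface_label`` and ``wall_assignment`` as POINT_DATA and
the annulus rings, structured-grid indexing and wall-interface plane as
FIELD data, so a file round-trips the full :class:`BiventricularSurface`.
PLY output (via trimesh) stores the geometry, with the non-geometric
metadata in a JSON sidecar next to the file.

The subject table is a strict CSV with exactly the SubjectRecord fields;
missing values are rejected on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import (
    VALVES,
    BiventricularSurface,
    StructuredGrid,
    SubjectRecord,
)

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_ply",
    "read_ply",
    "write_subject_table",
    "read_subject_table",
]

_SUBJECT_COLUMNS = [
    "subject_id", "group", "sex", "repair_type", "age_at_repair",
    "age_at_cmr", "time_after_repair", "height", "weight", "bsa",
    "symptomatic", "prvi", "prf",
]


# ---------------------------------------------------------------------------
# legacy ASCII VTK polydata
# ---------------------------------------------------------------------------

def write_vtk(surface: BiventricularSurface, path: Union[str, Path]) -> None:
    path = Path(path)
    v = surface.vertices
    t = surface.triangles
    lines: List[str] = [
        "# vtk DataFile Version 3.0",
        f"bivatlas subject={surface.subject_id} phase={surface.phase}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines.extend(" ".join(f"{x:.9g}" for x in row) for row in v)
    lines.append(f"POLYGONS {len(t)} {4 * len(t)}")
    lines.extend("3 " + " ".join(str(i) for i in row) for row in t)

    lines.append(f"POINT_DATA {len(v)}")
    lines.append("SCALARS surface_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(x)) for x in surface.surface_label)
    if surface.wall_assignment is not None:
        lines.append("SCALARS wall_assignment int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(int(x)) for x in surface.wall_assignment)

    fields: Dict[str, np.ndarray] = {}
    for valve in VALVES:
        if valve in surface.annulus_rings:
            fields[f"ring_{valve}"] = surface.annulus_rings[valve].astype(float)
    if surface.wall_plane is not None:
        fields["wall_plane"] = surface.wall_plane
    for label, grid in surface.grids.items():
        fields[f"grid_{label}"] = np.concatenate(
            [[grid.pole, grid.n_rings, grid.n_meridians],
             grid.rings.ravel()]).astype(float)
    lines.append(f"FIELD metadata {len(fields)}")
    for name, arr in fields.items():
        lines.append(f"{name} 1 {arr.size} double")
        lines.append(" ".join(f"{x:.9g}" for x in arr))
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path: Union[str, Path]) -> BiventricularSurface:
    tokens_by_line = Path(path).read_text().splitlines()
    if not tokens_by_line[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path}: not a legacy VTK file")
    title = tokens_by_line[1]
    meta = dict(kv.split("=", 1) for kv in title.split() if "=" in kv)
    subject_id = meta.get("subject", "unknown")
    phase = meta.get("phase", "ED")

    # flatten into a token stream after the 4 header lines
    stream: List[str] = []
    for line in tokens_by_line[2:]:
        stream.extend(line.split())
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        if stream[pos].upper() != word:
            raise ValueError(f"{path}: expected {word}, found {stream[pos]}")
        pos += 1

    def take(n: int) -> List[str]:
        nonlocal pos
        out = stream[pos:pos + n]
        pos += n
        return out

    expect("ASCII")
    expect("DATASET")
    expect("POLYDATA")
    expect("POINTS")
    n_pts = int(take(1)[0])
    take(1)  # dtype
    verts = np.array(take(3 * n_pts), dtype=float).reshape(n_pts, 3)
    expect("POLYGONS")
    n_poly = int(take(1)[0])
    total = int(take(1)[0])
    raw = np.array(take(total), dtype=np.int64)
    tris = []
    i = 0
    while i < total:
        k = raw[i]
        if k != 3:
            raise ValueError(f"{path}: only triangles supported, found {k}-gon")
        tris.append(raw[i + 1:i + 4])
        i += k + 1
    tris = np.array(tris)
    if len(tris) != n_poly:
        raise ValueError(f"{path}: polygon count mismatch")

    labels = None
    wall = None
    rings: Dict[str, np.ndarray] = {}
    wall_plane = None
    grids: Dict[int, StructuredGrid] = {}
    while pos < len(stream):
        word = stream[pos].upper()
        pos += 1
        if word == "POINT_DATA":
            take(1)
        elif word == "SCALARS":
            name = take(1)[0]
            take(2)  # dtype, ncomp
            expect("LOOKUP_TABLE")
            take(1)
            arr = np.array(take(n_pts), dtype=np.int64)
            if name == "surface_label":
                labels = arr
            elif name == "wall_assignment":
                wall = arr
        elif word == "FIELD":
            take(1)  # field name
            n_arrays = int(take(1)[0])
            for _ in range(n_arrays):
                name = take(1)[0]
                take(1)  # components
                n = int(take(1)[0])
                take(1)  # dtype
                arr = np.array(take(n), dtype=float)
                if name.startswith("ring_"):
                    rings[name[5:]] = arr.astype(np.int64)
                elif name == "wall_plane":
                    wall_plane = arr
                elif name.startswith("grid_"):
                    label = int(name[5:])
                    pole, k, m = int(arr[0]), int(arr[1]), int(arr[2])
                    grids[label] = StructuredGrid(
                        pole=pole, rings=arr[3:].astype(np.int64).reshape(k, m))
        else:
            raise ValueError(f"{path}: unsupported section {word}")

    if labels is None:
        raise ValueError(f"{path}: missing surface_label point data")
    surf = BiventricularSurface(
        subject_id=subject_id, phase=phase, vertices=verts, triangles=tris,
        surface_label=labels, annulus_rings=rings, wall_assignment=wall,
        wall_plane=wall_plane, grids=grids)
    surf.validate()
    return surf


# ---------------------------------------------------------------------------
# PLY via trimesh, metadata in a JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_ply(surface: BiventricularSurface, path: Union[str, Path]) -> None:
    import trimesh

    path = Path(path)
    mesh = trimesh.Trimesh(vertices=surface.vertices,
                           faces=surface.triangles, process=False)
    path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    meta = {
        "subject_id": surface.subject_id,
        "phase": surface.phase,
        "surface_label": surface.surface_label.tolist(),
        "annulus_rings": {k: v.tolist() for k, v in surface.annulus_rings.items()},
        "wall_assignment": (surface.wall_assignment.tolist()
                            if surface.wall_assignment is not None else None),
        "wall_plane": (surface.wall_plane.tolist()
                       if surface.wall_plane is not None else None),
        "grids": {str(k): {"pole": g.pole, "rings": g.rings.tolist()}
                  for k, g in surface.grids.items()},
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_ply(path: Union[str, Path]) -> BiventricularSurface:
    import trimesh

    path = Path(path)
    mesh = trimesh.load(str(path), process=False)
    meta = json.loads(_sidecar(path).read_text())
    surf = BiventricularSurface(
        subject_id=meta["subject_id"], phase=meta["phase"],
        vertices=np.asarray(mesh.vertices, dtype=float),
        triangles=np.asarray(mesh.faces, dtype=np.int64),
        surface_label=np.asarray(meta["surface_label"], dtype=np.int64),
        annulus_rings={k: np.asarray(v, dtype=np.int64)
                       for k, v in meta["annulus_rings"].items()},
        wall_assignment=(np.asarray(meta["wall_assignment"], dtype=np.int64)
                         if meta["wall_assignment"] is not None else None),
        wall_plane=(np.asarray(meta["wall_plane"], dtype=float)
                    if meta["wall_plane"] is not None else None),
        grids={int(k): StructuredGrid(pole=g["pole"],
                                      rings=np.asarray(g["rings"], dtype=np.int64))
               for k, g in meta["grids"].items()},
    )
    surf.validate()
    return surf


# ---------------------------------------------------------------------------
# subject table
# ---------------------------------------------------------------------------

def write_subject_table(records: Sequence[SubjectRecord],
                        path: Union[str, Path]) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _SUBJECT_COLUMNS}
                       for r in records])
    df.to_csv(path, index=False)


def read_subject_table(path: Union[str, Path]) -> List[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    extra = set(df.columns) - set(_SUBJECT_COLUMNS)
    if extra:
        raise ValueError(f"subject table has unknown columns: {sorted(extra)}")
    if df[_SUBJECT_COLUMNS].isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"subject table has missing values in {bad}")
    return [SubjectRecord(**{c: row[c] for c in _SUBJECT_COLUMNS})
            for _, row in df.iterrows()]
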