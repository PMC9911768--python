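"""Mesh data model and standard imaging indices.

A :class:`BiventricularSurface` is a labeled, triangulated, corresponded point
set describing one subject's heart at one cardiac phase (end-diastole or
end-systole).  Three labeled sub-surfaces — LV endocardium, RV endocardium and
the epicardium — are open surfaces whose only boundary cycles are the four
valve annulus rings (mitral, tricuspid, aortic, pulmonary).  Capping those
rings makes each sub-surface a closed 2-manifold, so cavity and wall volumes
are well defined and can be measured by numerical integration (signed
tetrahedra / divergence theorem).

From a paired ED/ES surface and the subject record the module computes the ten
standard imaging indices used throughout the analysis: LV/RV EDVi, ESVi, EF
and mass index, plus the pulmonary-regurgitation measures PRVi and PRF which
are carried as given inputs.

Units are fixed package-wide: coordinates mm, volumes mL, masses g, indexed
quantities per m^2 of body surface area.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "SurfaceLabel",
    "WallSide",
    "Phase",
    "Sex",
    "Group",
    "RepairType",
    "StructuredGrid",
    "BiventricularSurface",
    "SubjectRecord",
    "ImagingIndexSet",
    "ClosedSurface",
    "TopologyError",
    "VALVES",
    "boundary_edges",
    "boundary_cycles",
    "close_surface",
    "enclosed_volume",
    "compute_cavity_volumes",
    "wall_volumes",
    "compute_masses",
    "ejection_fraction",
    "index_to_bsa",
    "compute_imaging_indices",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05  # standard CMR literature value

VALVES = ("mitral", "tricuspid", "aortic", "pulmonary")


class TopologyError(ValueError):
    """Raised when a surface is not the topology an operation requires."""


class SurfaceLabel(enum.IntEnum):
    LV_ENDO = 0
    RV_ENDO = 1
    EPI = 2


class WallSide(enum.IntEnum):
    LV = 0
    RV = 1


class Phase(str, enum.Enum):
    ED = "ED"
    ES = "ES"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Group(str, enum.Enum):
    PVR = "PVR"
    NO_PVR = "NO_PVR"


class RepairType(str, enum.Enum):
    TRANSANNULAR_PATCH = "TRANSANNULAR_PATCH"
    VALVE_SPARING = "VALVE_SPARING"
    CONDUIT = "CONDUIT"


@dataclass
class StructuredGrid:
    """Ring x meridian parameterization of one endo/epi sub-surface.

    ``rings[k, j]`` is the vertex index at longitudinal level k (0 = nearest
    the apex, last row = basal boundary ring) and circumferential position j.
    ``pole`` is the apical pole vertex.
    """

    pole: int
    rings: np.ndarray  # (K, M) int

    @property
    def n_rings(self) -> int:
        return int(self.rings.shape[0])

    @property
    def n_meridians(self) -> int:
        return int(self.rings.shape[1])


@dataclass
class BiventricularSurface:
    subject_id: str
    phase: str
    vertices: np.ndarray  # (N, 3) float, mm
    triangles: np.ndarray  # (T, 3) int
    surface_label: np.ndarray  # (N,) int, SurfaceLabel values
    annulus_rings: Dict[str, np.ndarray]  # valve name -> ordered vertex ring
    wall_assignment: Optional[np.ndarray] = None  # (N,) int, WallSide values
    # optional explicit LV/RV wall interface plane [nx, ny, nz, d] with
    # n . x = d and n pointing toward the RV side; estimated from the
    # assignment map when absent
    wall_plane: Optional[np.ndarray] = None
    grids: Dict[int, StructuredGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.surface_label = np.asarray(self.surface_label, dtype=np.int64)
        if isinstance(self.phase, Phase):
            self.phase = self.phase.value
        self.annulus_rings = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.annulus_rings.items()
        }
        if self.wall_assignment is not None:
            self.wall_assignment = np.asarray(self.wall_assignment, dtype=np.int64)
        if self.wall_plane is not None:
            self.wall_plane = np.asarray(self.wall_plane, dtype=float).reshape(4)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def label_mask(self, label: int) -> np.ndarray:
        return self.surface_label == int(label)

    def submesh(self, label: int) -> Tuple[np.ndarray, np.ndarray]:
        """Vertices and (reindexed) triangles of one labeled sub-surface."""
        mask = self.label_mask(label)
        if not mask.any():
            raise ValueError(f"surface has no vertices with label {label!r}")
        tri_mask = mask[self.triangles].all(axis=1)
        old_to_new = -np.ones(self.n_vertices, dtype=np.int64)
        idx = np.flatnonzero(mask)
        old_to_new[idx] = np.arange(idx.size)
        return self.vertices[idx], old_to_new[self.triangles[tri_mask]]

    def validate(self) -> None:
        """Check the cohort-correspondence invariants; raise on violation."""
        if not np.isfinite(self.vertices).all():
            raise ValueError("non-finite vertex coordinates")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be N x 3")
        if self.triangles.min(initial=0) < 0 or (
            self.triangles.size and self.triangles.max() >= self.n_vertices
        ):
            raise ValueError("triangle indexes out-of-range vertex")
        if self.surface_label.shape != (self.n_vertices,):
            raise ValueError("surface_label must have one entry per vertex")
        if not np.isin(self.surface_label, [int(l) for l in SurfaceLabel]).all():
            raise ValueError("unknown surface label value")
        bedges = boundary_edge_set(self.triangles)
        for valve, ring in self.annulus_rings.items():
            if ring.size < 3:
                raise ValueError(f"{valve} annulus ring too short")
            closed = np.concatenate([ring, ring[:1]])
            for a, b in zip(closed[:-1], closed[1:]):
                if (min(a, b), max(a, b)) not in bedges:
                    raise TopologyError(
                        f"{valve} annulus ring edge ({a}, {b}) is not a boundary edge"
                    )


@dataclass
class SubjectRecord:
    """Demographics, confounders, group label and PR measures for one subject."""

    subject_id: str
    group: str  # Group
    sex: str  # Sex
    repair_type: str  # RepairType
    age_at_repair: float  # years
    age_at_cmr: float  # years
    time_after_repair: float  # years
    height: float  # cm
    weight: float  # kg
    bsa: float  # m^2
    symptomatic: bool
    prvi: float  # mL/m^2
    prf: float  # %

    def __post_init__(self) -> None:
        for attr, enum_cls in (("group", Group), ("sex", Sex), ("repair_type", RepairType)):
            v = getattr(self, attr)
            if isinstance(v, enum.Enum):
                v = v.value
            setattr(self, attr, enum_cls(v).value)
        self.symptomatic = bool(self.symptomatic)
        if not self.bsa > 0:
            raise ValueError("bsa must be positive")
        if self.time_after_repair < 0:
            raise ValueError("time_after_repair must be >= 0")
        if not (0.0 <= self.prf <= 100.0):
            raise ValueError("prf must lie in [0, 100]")


@dataclass
class ImagingIndexSet:
    """The ten standard imaging indices (Table-2 feature set)."""

    lv_edvi: float  # mL/m^2
    lv_esvi: float
    rv_edvi: float
    rv_esvi: float
    lv_ef: float  # %
    rv_ef: float
    lv_mi: float  # g/m^2
    rv_mi: float
    prvi: float  # mL/m^2
    prf: float  # %

    FIELD_ORDER = (
        "lv_edvi", "lv_esvi", "lv_ef", "lv_mi",
        "rv_edvi", "rv_esvi", "rv_ef", "rv_mi",
        "prvi", "prf",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELD_ORDER], dtype=float)

    def as_dict(self) -> Dict[str, float]:
        return {f: float(getattr(self, f)) for f in self.FIELD_ORDER}


@dataclass
class ClosedSurface:
    """A closed, consistently oriented triangulated surface."""

    vertices: np.ndarray
    triangles: np.ndarray


# ---------------------------------------------------------------------------
# topology helpers
# ---------------------------------------------------------------------------

def _directed_edges(triangles: np.ndarray) -> np.ndarray:
    t = np.asarray(triangles, dtype=np.int64)
    return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])


def boundary_edges(triangles: np.ndarray) -> List[Tuple[int, int]]:
    """Edges incident to exactly one triangle."""
    e = _directed_edges(triangles)
    und = np.sort(e, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    return [tuple(map(int, row)) for row in uniq[counts == 1]]


def boundary_edge_set(triangles: np.ndarray) -> set:
    return set(boundary_edges(triangles))


def boundary_cycles(triangles: np.ndarray) -> List[List[int]]:
    """Group boundary edges into closed vertex cycles.

    Raises :class:`TopologyError` if the boundary is not a disjoint union of
    simple cycles (e.g. a dangling seam).
    """
    edges = boundary_edges(triangles)
    adj: Dict[int, List[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    bad = [v for v, nb in adj.items() if len(nb) != 2]
    if bad:
        offending = [e for e in edges if e[0] in bad or e[1] in bad]
        raise TopologyError(f"open seam: boundary edges {offending} do not form rings")
    cycles: List[List[int]] = []
    unused = {tuple(e) for e in edges}
    visited: set = set()
    for start in sorted(adj):
        if start in visited:
            continue
        cycle = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = [v for v in adj[cur] if v != prev]
            nxt_v = nxt[0] if nxt else adj[cur][0]
            if nxt_v == start:
                break
            cycle.append(nxt_v)
            visited.add(nxt_v)
            prev, cur = cur, nxt_v
        cycles.append(cycle)
    del unused
    return cycles


def check_closed_oriented(triangles: np.ndarray) -> None:
    """Raise unless every edge is shared by exactly 2 consistently wound triangles."""
    e = _directed_edges(triangles)
    n = int(e.max()) + 1 if e.size else 1
    keys = e[:, 0] * n + e[:, 1]
    uniq, counts = np.unique(keys, return_counts=True)
    if (counts != 1).any():
        a, b = divmod(int(uniq[counts != 1][0]), n)
        raise TopologyError(
            f"surface not a closed consistently oriented 2-manifold at edge ({a}, {b})")
    rev = np.sort(e[:, 1] * n + e[:, 0])
    if not np.array_equal(np.sort(keys), rev):
        missing = np.setdiff1d(keys, e[:, 1] * n + e[:, 0])
        a, b = divmod(int(missing[0]), n)
        raise TopologyError(
            f"surface not a closed consistently oriented 2-manifold at edge ({a}, {b})")


def close_surface(surface: BiventricularSurface, label: int) -> ClosedSurface:
    """Close one labeled sub-surface by capping its valve annulus rings.

    Each boundary cycle of the sub-surface must coincide with one of the
    surface's annulus rings; it is capped with a triangle fan to the ring
    centroid, wound consistently with the adjacent surface triangles.  An
    already-closed sub-surface is returned unchanged.
    """
    verts, tris = surface.submesh(label)
    try:
        cycles = boundary_cycles(tris)
    except TopologyError:
        raise
    if not cycles:
        return ClosedSurface(verts, tris)

    # map original ring indices into submesh indexing
    mask = surface.label_mask(label)
    old_to_new = -np.ones(surface.n_vertices, dtype=np.int64)
    idx = np.flatnonzero(mask)
    old_to_new[idx] = np.arange(idx.size)
    ring_sets = {}
    for valve, ring in surface.annulus_rings.items():
        if mask[ring].all():
            ring_sets[valve] = frozenset(int(old_to_new[v]) for v in ring)

    de = _directed_edges(tris)
    big = int(verts.shape[0]) + 1
    directed = set((de[:, 0] * big + de[:, 1]).tolist())

    new_verts = [verts]
    new_tris = [tris]
    next_idx = verts.shape[0]
    for cycle in cycles:
        cset = frozenset(cycle)
        if cset not in ring_sets.values():
            edges = list(zip(cycle, cycle[1:] + cycle[:1]))
            raise TopologyError(
                f"boundary cycle {edges} of label {label!r} is not a valve annulus ring"
            )
        centroid = verts[list(cycle)].mean(axis=0)
        new_verts.append(centroid[None, :])
        cap = []
        closed = cycle + [cycle[0]]
        for a, b in zip(closed[:-1], closed[1:]):
            # oppose the existing interior winding so the cap is consistent
            if int(a) * big + int(b) in directed:
                cap.append((b, a, next_idx))
            else:
                cap.append((a, b, next_idx))
        new_tris.append(np.array(cap, dtype=np.int64))
        next_idx += 1
    closed_surface = ClosedSurface(
        np.vstack(new_verts), np.vstack(new_tris)
    )
    check_closed_oriented(closed_surface.triangles)
    return closed_surface


# ---------------------------------------------------------------------------
# volumes and masses
# ---------------------------------------------------------------------------

def _signed_volume_mm3(vertices: np.ndarray, triangles: np.ndarray,
                       origin: Optional[np.ndarray] = None) -> float:
    v = np.asarray(vertices, dtype=float)
    if origin is not None:
        v = v - np.asarray(origin, dtype=float)[None, :]
    p0 = v[triangles[:, 0]]
    p1 = v[triangles[:, 1]]
    p2 = v[triangles[:, 2]]
    return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)


def enclosed_volume(surface: ClosedSurface) -> float:
    """Volume (mL) enclosed by a closed oriented surface with mm coordinates."""
    check_closed_oriented(surface.triangles)
    return abs(_signed_volume_mm3(surface.vertices, surface.triangles)) / 1000.0


def compute_cavity_volumes(surface: BiventricularSurface) -> Dict[str, float]:
    """LV cavity, RV cavity and total epicardial enclosed volume (mL)."""
    return {
        "lv": enclosed_volume(close_surface(surface, SurfaceLabel.LV_ENDO)),
        "rv": enclosed_volume(close_surface(surface, SurfaceLabel.RV_ENDO)),
        "epi": enclosed_volume(close_surface(surface, SurfaceLabel.EPI)),
    }


def wall_volumes(surface: BiventricularSurface,
                 cavity: Optional[Mapping[str, float]] = None) -> Dict[str, float]:
    """Total wall volume and its LV/RV split (mL).

    Total wall volume is the epicardial enclosed volume minus both cavities.
    The LV/RV split cuts the closed epicardial shell at the wall interface
    plane (septum belongs to the LV wall); the LV wall is the LV-side
    clipped volume minus the LV cavity.  The plane is taken from
    ``surface.wall_plane`` when present, otherwise estimated from the
    vertex-level assignment map (centroid axis refined by the least-variance
    direction of the interface band) with accuracy limited by mesh spacing.
    """
    if surface.wall_assignment is None:
        raise ValueError("surface carries no wall_assignment map")
    if cavity is None:
        cavity = compute_cavity_volumes(surface)
    total = cavity["epi"] - cavity["lv"] - cavity["rv"]
    if total < 0:
        raise ValueError("negative wall volume: malformed mesh")

    mask = surface.label_mask(SurfaceLabel.EPI)
    assign = surface.wall_assignment[mask]
    pts = surface.vertices[mask]
    lv_pts = pts[assign == int(WallSide.LV)]
    rv_pts = pts[assign == int(WallSide.RV)]
    if len(lv_pts) == 0 or len(rv_pts) == 0:
        side = "lv" if len(rv_pts) == 0 else "rv"
        out = {"total": total, "lv": 0.0, "rv": 0.0}
        out[side] = total
        return out

    import trimesh  # standard mesh toolkit; used for the exact plane clip

    if surface.wall_plane is not None:
        normal = surface.wall_plane[:3] / np.linalg.norm(surface.wall_plane[:3])
        d = float(surface.wall_plane[3]) / np.linalg.norm(surface.wall_plane[:3])
    else:
        # estimate: start from the LV->RV centroid axis, then refine the
        # normal as the least-variance direction of the vertices nearest
        # the current plane (the interface band), shrinking the band
        normal = rv_pts.mean(axis=0) - lv_pts.mean(axis=0)
        normal = normal / np.linalg.norm(normal)
        d = 0.5 * (lv_pts @ normal).max() + 0.5 * (rv_pts @ normal).min()
        scale = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        for h in (0.15 * scale, 0.08 * scale, 0.05 * scale):
            proj = pts @ normal
            band = pts[np.abs(proj - d) < h]
            if len(band) < 12:
                break
            _, _, vt = np.linalg.svd(band - band.mean(axis=0), full_matrices=False)
            cand = vt[-1]
            if cand @ normal < 0:
                cand = -cand
            normal = cand
            d = 0.5 * (lv_pts @ normal).max() + 0.5 * (rv_pts @ normal).min()
    origin = d * normal
    closed = close_surface(surface, SurfaceLabel.EPI)
    tm = trimesh.Trimesh(vertices=closed.vertices, faces=closed.triangles, process=False)
    lv_part = trimesh.intersections.slice_mesh_plane(
        tm, plane_normal=-normal, plane_origin=origin, cap=False
    )
    # the open cut lies exactly in the plane, so signed tetrahedra about a
    # reference point in that plane integrate the clipped region exactly
    lv_side = abs(_signed_volume_mm3(lv_part.vertices, lv_part.faces, origin)) / 1000.0
    lv_wall = min(max(lv_side - cavity["lv"], 0.0), total)
    return {"total": total, "lv": lv_wall, "rv": total - lv_wall}


def compute_masses(wall: Mapping[str, float],
                   density: float = MYOCARDIAL_DENSITY_G_PER_ML,
                   allow_zero: bool = False) -> Dict[str, float]:
    """Wall volumes (mL) -> masses (g) at myocardial density 1.05 g/mL."""
    lv, rv = float(wall["lv"]), float(wall["rv"])
    if lv < 0 or rv < 0:
        raise ValueError("negative wall volume: malformed mesh")
    if (lv + rv) == 0 and not allow_zero:
        raise ValueError("zero wall volume (epicardium coincides with endocardium)")
    return {"lv_mass": lv * density, "rv_mass": rv * density}


def ejection_fraction(edv: float, esv: float) -> float:
    """100 * (EDV - ESV) / EDV.  Negative EF is allowed but flags poor input."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def index_to_bsa(value: float, bsa: float) -> float:
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    return value / bsa


def compute_imaging_indices(ed: BiventricularSurface, es: BiventricularSurface,
                            rec: SubjectRecord) -> ImagingIndexSet:
    """All ten standard imaging indices from a paired ED/ES surface.

    Masses are measured at ED.  PRVi and PRF are copied from the subject
    record (flow-derived measures are inputs, not mesh quantities).
    """
    if ed.subject_id != es.subject_id or ed.subject_id != rec.subject_id:
        raise ValueError("subject_id mismatch between ED, ES and record")
    if ed.n_vertices != es.n_vertices:
        raise ValueError("ED and ES surfaces are not in correspondence")
    vol_ed = compute_cavity_volumes(ed)
    vol_es = compute_cavity_volumes(es)
    masses = compute_masses(wall_volumes(ed, vol_ed))
    bsa = rec.bsa
    return ImagingIndexSet(
        lv_edvi=index_to_bsa(vol_ed["lv"], bsa),
        lv_esvi=index_to_bsa(vol_es["lv"], bsa),
        rv_edvi=index_to_bsa(vol_ed["rv"], bsa),
        rv_esvi=index_to_bsa(vol_es["rv"], bsa),
        lv_ef=ejection_fraction(vol_ed["lv"], vol_es["lv"]),
        rv_ef=ejection_fraction(vol_ed["rv"], vol_es["rv"]),
        lv_mi=index_to_bsa(masses["lv_mass"], bsa),
        rv_mi=index_to_bsa(masses["rv_mass"], bsa),
        prvi=rec.prvi,
        prf=rec.prf,
    )
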