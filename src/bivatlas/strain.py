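"""Geometric systolic strain from paired ED/ES surfaces.

Longitudinal strain (LS) and circumferential strain (CS) are Cauchy strains
of arc length — per-line relative length change between end-diastole and
end-systole — measured on the endocardial surfaces along the structured
ring/meridian parameterization: longitudinal lines run from the apex pole
to the basal ring along fixed circumferential positions, circumferential
lines are the closed rings.  The interventricular septum is part of the LV
endocardial surface, so it is included in the LV strains.

Radial strain (RS, wall thickening) uses a modified centerline method on
short-axis slices: each slice plane (perpendicular to the LV long axis)
cuts the endocardial and epicardial surfaces into contours; the endo and
epi contour arcs over the ventricle's free-wall sector are resampled to
equal arc-length stations, the centerline is their midpoint curve, and
wall thickness is the chord cast along the centerline normal between the
endo and epi crossings.  RS per station is the Cauchy strain of thickness,
averaged over stations and slices.  Stations are restricted to the
free-wall sector because the epicardium wraps both ventricles — a septal
chord from the LV endocardium to the epicardial contour would cross the RV
cavity rather than the wall.

All constructions are defined relative to the mitral annulus plane and the
contour centroids, so strains are invariant to a common rigid transform of
the ED/ES pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import trimesh
from shapely.geometry import LineString

from .geometry import BiventricularSurface, SurfaceLabel

__all__ = [
    "StrainResult",
    "cauchy_strain",
    "sample_parameter_lines",
    "directional_strain",
    "radial_strain_centerline",
    "default_slice_planes",
    "compute_strains",
]

logger = logging.getLogger(__name__)

DEFAULT_SLICE_FRACTIONS = np.linspace(0.1, 0.9, 8)
DEFAULT_SECTOR_HALF_ANGLE_DEG = 100.0
DEFAULT_STATIONS = 100
MIN_VALID_SLICES = 3

_VENTRICLE_LABEL = {"LV": SurfaceLabel.LV_ENDO, "RV": SurfaceLabel.RV_ENDO}


@dataclass
class StrainResult:
    """Six geometric systolic strains (%), Cauchy convention: LS/CS negative
    for contraction, RS positive for wall thickening."""

    lv_ls: float
    rv_ls: float
    lv_cs: float
    rv_cs: float
    lv_rs: float
    rv_rs: float
    per_line: Dict[str, np.ndarray] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {k: float(getattr(self, k))
                for k in ("lv_ls", "rv_ls", "lv_cs", "rv_cs", "lv_rs", "rv_rs")}


def cauchy_strain(length_ed: float, length_es: float) -> float:
    """100 * (L_es - L_ed) / L_ed."""
    if length_ed <= 0:
        raise ValueError("ED length must be positive")
    return 100.0 * (length_es - length_ed) / length_ed


# ---------------------------------------------------------------------------
# arc-length strains on the structured grid
# ---------------------------------------------------------------------------

def sample_parameter_lines(surface: BiventricularSurface, direction: str,
                           ventricle: str) -> List[np.ndarray]:
    """Ordered vertex-index polylines along the structured parameterization.

    ``direction`` is "LONGITUDINAL" (apex pole to basal ring per meridian)
    or "CIRCUMFERENTIAL" (closed rings, first vertex repeated at the end).
    """
    label = _VENTRICLE_LABEL[ventricle]
    grid = surface.grids.get(int(label))
    if grid is None:
        raise ValueError(
            "surface carries no structured grid metadata for "
            f"{ventricle}; only slice-based radial strain is available")
    if direction == "LONGITUDINAL":
        lines = []
        for j in range(grid.n_meridians):
            lines.append(np.concatenate([[grid.pole], grid.rings[:, j]]))
        return lines
    if direction == "CIRCUMFERENTIAL":
        return [np.concatenate([grid.rings[k], grid.rings[k, :1]])
                for k in range(grid.n_rings)]
    raise ValueError(f"unknown direction {direction!r}")


def _polyline_length(vertices: np.ndarray, line: np.ndarray) -> float:
    pts = vertices[line]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def directional_strain(ed: BiventricularSurface, es: BiventricularSurface,
                       direction: str, ventricle: str,
                       return_per_line: bool = False):
    """Unweighted mean Cauchy strain over the parameter lines."""
    lines = sample_parameter_lines(ed, direction, ventricle)
    per_line = np.array([
        cauchy_strain(_polyline_length(ed.vertices, ln),
                      _polyline_length(es.vertices, ln))
        for ln in lines
    ])
    mean = float(per_line.mean())
    if return_per_line:
        return mean, per_line
    return mean


# ---------------------------------------------------------------------------
# short-axis slicing
# ---------------------------------------------------------------------------

def _lv_long_axis(surface: BiventricularSurface) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(axis unit vector base->apex is -axis ... returns (axis, apex, base)).

    The axis is the mitral-annulus best-fit plane normal oriented from apex
    toward base; apex is the LV endocardial vertex farthest from the plane.
    """
    ring = surface.vertices[surface.annulus_rings["mitral"]]
    base = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - base, full_matrices=False)
    normal = vt[-1]
    lv_pts = surface.vertices[surface.label_mask(SurfaceLabel.LV_ENDO)]
    depth = (lv_pts - base) @ normal
    if abs(depth.max()) > abs(depth.min()):
        normal = -normal  # orient so the apex sits at negative projection
    apex = lv_pts[np.argmin((lv_pts - base) @ normal)]
    return normal, apex, base


def default_slice_planes(surface: BiventricularSurface,
                         fractions: Optional[np.ndarray] = None
                         ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Short-axis stack: (origin, normal) pairs perpendicular to the LV long
    axis at fixed fractions of the apex-base extent (0 = apex, 1 = base)."""
    if fractions is None:
        fractions = DEFAULT_SLICE_FRACTIONS
    normal, apex, base = _lv_long_axis(surface)
    d_apex = float(apex @ normal)
    d_base = float(base @ normal)
    return [(apex + (d_base - d_apex) * f * normal, normal) for f in fractions]


def _plane_contours(surface: BiventricularSurface, label: SurfaceLabel,
                    origin: np.ndarray, normal: np.ndarray) -> List[np.ndarray]:
    """Closed intersection contours of one labeled sub-surface with a plane,
    as ordered 3D point loops."""
    verts, tris = surface.submesh(int(label))
    segs = trimesh.intersections.mesh_plane(
        trimesh.Trimesh(vertices=verts, faces=tris, process=False),
        plane_normal=normal, plane_origin=origin)
    if len(segs) == 0:
        return []
    # chain segments into loops by matching endpoints
    pts: List[np.ndarray] = []
    key_of: Dict[Tuple[int, int, int], int] = {}
    adj: Dict[int, List[int]] = {}

    def node(pt: np.ndarray) -> int:
        key = tuple(np.round(pt, 4))
        if key not in key_of:
            key_of[key] = len(pts)
            pts.append(pt)
            adj[key_of[key]] = []
        return key_of[key]

    for a, b in segs:
        ia, ib = node(a), node(b)
        if ib not in adj[ia]:
            adj[ia].append(ib)
            adj[ib].append(ia)
    loops = []
    visited = set()
    for start in range(len(pts)):
        if start in visited or len(adj[start]) != 2:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        closed = False
        while True:
            nxt = [v for v in adj[cur] if v != prev]
            if not nxt:
                break
            nxt_v = nxt[0]
            if nxt_v == start:
                closed = True
                break
            if nxt_v in visited:
                break
            loop.append(nxt_v)
            visited.add(nxt_v)
            prev, cur = cur, nxt_v
        if closed and len(loop) >= 8:
            loops.append(np.array([pts[i] for i in loop]))
    return loops


def _to_plane_2d(points: np.ndarray, origin: np.ndarray,
                 normal: np.ndarray) -> np.ndarray:
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = points - origin
    return np.column_stack([rel @ e1, rel @ e2])


def _resample_arc(arc: np.ndarray, n: int) -> np.ndarray:
    """Resample an open 2D polyline to n equal arc-length stations."""
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise ValueError("degenerate contour arc")
    targets = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, cum, arc[:, d])
    return out


def _sector_arc(contour2d: np.ndarray, center: np.ndarray, away: np.ndarray,
                half_angle: float) -> Optional[np.ndarray]:
    """Contiguous arc of a closed contour within +/- half_angle of the away
    direction, ordered by angle."""
    rel = contour2d - center
    ang = np.arctan2(rel[:, 1], rel[:, 0]) - math.atan2(away[1], away[0])
    ang = np.mod(ang + math.pi, 2 * math.pi) - math.pi
    mask = np.abs(ang) <= half_angle
    if mask.sum() < 5:
        return None
    order = np.argsort(ang[mask])
    return contour2d[mask][order]


def _station_thickness(endo_arc: np.ndarray, epi_arc: np.ndarray,
                       endo_ls: LineString, epi_ls: LineString,
                       n_stations: int) -> np.ndarray:
    """Chord thickness at equal arc-length stations along the centerline.

    NaN marks stations whose chord misses one of the contours.
    """
    e = _resample_arc(endo_arc, n_stations)
    p = _resample_arc(epi_arc, n_stations)
    mid = 0.5 * (e + p)
    tang = np.gradient(mid, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    reach = 3.0 * np.linalg.norm(e - p, axis=1) + 10.0
    out = np.full(n_stations, np.nan)
    for i in range(n_stations):
        chord = LineString([mid[i] - reach[i] * nrm[i], mid[i] + reach[i] * nrm[i]])
        qe = _nearest_intersection(chord, endo_ls, mid[i])
        qp = _nearest_intersection(chord, epi_ls, mid[i])
        if qe is None or qp is None:
            continue
        out[i] = float(np.linalg.norm(qe - qp))
    return out


def _nearest_intersection(chord: LineString, contour: LineString,
                          point: np.ndarray) -> Optional[np.ndarray]:
    inter = chord.intersection(contour)
    if inter.is_empty:
        return None
    cand = []
    for geom in getattr(inter, "geoms", [inter]):
        coords = np.asarray(geom.coords)
        cand.extend(coords)
    cand = np.asarray(cand)
    return cand[np.argmin(np.linalg.norm(cand - point[None, :], axis=1))]


def _slice_thickness_profile(surface: BiventricularSurface, ventricle: str,
                             origin: np.ndarray, normal: np.ndarray,
                             sector_half_angle: float, n_stations: int
                             ) -> Optional[np.ndarray]:
    """Free-wall thickness stations of one ventricle on one slice plane."""
    endo_loops = _plane_contours(surface, _VENTRICLE_LABEL[ventricle],
                                 origin, normal)
    epi_loops = _plane_contours(surface, SurfaceLabel.EPI, origin, normal)
    if not endo_loops or not epi_loops:
        return None
    endo3d = max(endo_loops, key=len)
    epi3d = max(epi_loops, key=len)
    endo = _to_plane_2d(endo3d, origin, normal)
    epi = _to_plane_2d(epi3d, origin, normal)
    center = endo.mean(axis=0)

    other = "RV" if ventricle == "LV" else "LV"
    other_pts = surface.vertices[surface.label_mask(_VENTRICLE_LABEL[other])]
    if other_pts.size:
        other_c = _to_plane_2d(other_pts.mean(axis=0)[None, :], origin, normal)[0]
        away = center - other_c
        nrm = np.linalg.norm(away)
        away = away / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
        half = math.radians(sector_half_angle)
    else:
        away = np.array([1.0, 0.0])
        half = math.pi  # no other ventricle: use the full contour
    endo_arc = _sector_arc(endo, center, away, half)
    epi_arc = _sector_arc(epi, center, away, half)
    if endo_arc is None or epi_arc is None:
        return None
    return _station_thickness(endo_arc, epi_arc,
                              LineString(np.vstack([endo, endo[:1]])),
                              LineString(np.vstack([epi, epi[:1]])),
                              n_stations)


def radial_strain_centerline(ed: BiventricularSurface, es: BiventricularSurface,
                             ventricle: str,
                             slice_planes: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None,
                             sector_half_angle_deg: float = DEFAULT_SECTOR_HALF_ANGLE_DEG,
                             n_stations: int = DEFAULT_STATIONS,
                             min_valid_slices: int = MIN_VALID_SLICES) -> float:
    """Mean centerline radial strain (%) over stations and slices.

    Slice planes default to the short-axis stack of the ED surface; the same
    apex-base fractions are re-derived on the ES surface so stations
    correspond between phases.  Slices missing the ventricle are skipped
    (logged); fewer than ``min_valid_slices`` valid slices is an error.
    """
    if slice_planes is None:
        planes_ed = default_slice_planes(ed)
        planes_es = default_slice_planes(es)
    else:
        planes_ed = planes_es = list(slice_planes)
    vals = []
    n_valid = 0
    for k, ((o_ed, n_ed), (o_es, n_es)) in enumerate(zip(planes_ed, planes_es)):
        th_ed = _slice_thickness_profile(ed, ventricle, o_ed, n_ed,
                                         sector_half_angle_deg, n_stations)
        th_es = _slice_thickness_profile(es, ventricle, o_es, n_es,
                                         sector_half_angle_deg, n_stations)
        if th_ed is None or th_es is None:
            logger.info("slice %d skipped for %s (plane misses the ventricle)",
                        k, ventricle)
            continue
        ok = (np.isfinite(th_ed) & np.isfinite(th_es)
              & (th_ed > 0.25) & (th_es > 0.25))
        if ok.sum() < n_stations // 4:
            logger.info("slice %d skipped for %s (too few valid chords)",
                        k, ventricle)
            continue
        n_valid += 1
        # Cauchy strain of the slice-mean thickness: per-station ratios are
        # unstable on thin walls (measurement noise in the denominator
        # biases the mean ratio upward), so stations are averaged first
        vals.append(cauchy_strain(float(th_ed[ok].mean()),
                                  float(th_es[ok].mean())))
    if n_valid < min_valid_slices:
        raise ValueError(
            f"only {n_valid} valid short-axis slices for {ventricle} "
            f"(need {min_valid_slices})")
    return float(np.mean(vals))


def compute_strains(ed: BiventricularSurface, es: BiventricularSurface) -> StrainResult:
    """All six systolic strains for a corresponded ED/ES pair."""
    if ed.n_vertices != es.n_vertices:
        raise ValueError("ED and ES surfaces are not in correspondence")
    per_line: Dict[str, np.ndarray] = {}
    vals = {}
    for vent in ("LV", "RV"):
        for direction, key in (("LONGITUDINAL", "ls"), ("CIRCUMFERENTIAL", "cs")):
            mean, lines = directional_strain(ed, es, direction, vent,
                                             return_per_line=True)
            vals[f"{vent.lower()}_{key}"] = mean
            per_line[f"{vent.lower()}_{key}"] = lines
        vals[f"{vent.lower()}_rs"] = radial_strain_centerline(ed, es, vent)
    return StrainResult(per_line=per_line, **vals)
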