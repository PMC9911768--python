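"""Parametric biventricular template with analytically known volumes.

The template stands in for a subdivision-surface heart model: it guarantees
the statistical and topological properties the analysis pipeline consumes
(vertex correspondence, surface labels, four annulus rings, structured
ring/meridian lines, known cavity and wall volumes) without attempting
anatomical fidelity.

Geometry
--------
All surfaces share a flat base plane at z = 0 with the apex pointing to
negative z.  The LV endocardium is a half prolate spheroid (circular cross
section, radius ``lv_a``, depth ``lv_c``).  The RV endocardium is a
septally-flattened half ellipsoid whose polar radius about the RV axis is
``rv_r * (1 + rv_beta * cos(theta))``, so the side facing the LV is
flattened and the free wall bulges outward.  The epicardium is a tapered
capsule hugging both ventricles: at every depth its cross section is the
convex hull of two disks — the LV disk (radius ``lv_a + t_lv`` at the
equator, depth ``lv_c + t_lv``) and an RV disk offset toward the free wall
that circumscribes the RV cross section with clearance ``t_rv``.  It is
closed at the base by a flat plate carrying two circular holes, the aortic
and pulmonary annuli; the basal boundary rings of the LV and RV endocardium
are the mitral and tricuspid annuli.

Because every basal structure is flat at z = 0, closing any sub-surface
with flat caps recovers the exact volume of the corresponding continuous
region.  Cavity volumes have closed forms:

* LV half spheroid:            V = (2/3) pi a^2 c
* flattened RV cross section:  A(z) = pi r(z)^2 (1 + beta^2 / 2)
  so                           V = pi r^2 (1 + beta^2/2) (2 c / 3)

The capsule cross section is piecewise circular-arc/tangent-line, so the
epicardial volume and the LV/RV wall split (a plane cut at
``wall_split_x``) are evaluated by quadrature of closed-form cross
sections, accurate to ~1e-4 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy import integrate, optimize

from ..geometry import (
    BiventricularSurface,
    StructuredGrid,
    SurfaceLabel,
    WallSide,
)

__all__ = [
    "ShapeParams",
    "Resolution",
    "generate_template",
    "build_surface",
    "analytic_volumes",
    "solve_epicardium",
    "contracted_params",
    "meridian_length",
    "mean_longitudinal_strain",
    "analytic_radial_strain",
]

_N_POLY = 128   # points per capsule cross-section polygon
_N_Z = 48       # depth quadrature levels


@dataclass
class Resolution:
    """Mesh resolution: rings x meridians per ventricle."""

    endo_rings: int = 16
    endo_meridians: int = 24
    epi_rings: int = 20
    epi_meridians: int = 32
    hole_points: int = 16
    seam_points: int = 6

    def validate(self) -> None:
        if self.endo_rings < 8 or self.endo_meridians < 16:
            raise ValueError("resolution too coarse: need >= 8 rings x 16 meridians")
        if self.epi_rings < 8 or self.epi_meridians < 16:
            raise ValueError("resolution too coarse for epicardium")


@dataclass
class ShapeParams:
    """Analytic shape parameters for one subject at one phase (mm)."""

    lv_a: float = 30.0      # LV endo equatorial radius
    lv_c: float = 58.0      # LV endo apex depth
    rv_r: float = 38.0      # RV endo reference radius
    rv_beta: float = 0.35   # septal flattening of the RV cross section
    rv_c: float = 56.0      # RV endo apex depth
    rv_cx: float = 0.0      # RV basal axis x offset; 0 -> derived from septal gap
    septal_gap: float = 5.0  # ED distance LV endo to RV endo across the septum
    t_lv: float = 9.0       # LV free-wall epicardial clearance
    t_rv: float = 4.0       # RV free-wall epicardial clearance
    aortic_r: float = 11.0
    pulmonary_r: float = 13.0
    # RV long-axis tilt toward the LV: the RV cross-section center slides as
    # x_c(z) = rv_cx + rv_tilt * z (z < 0 toward the apex).  None -> largest
    # collision-free slope up to 0.45 * rv_cx / rv_c.  Cross-section areas
    # are shear-invariant, so cavity closed forms are unaffected.
    rv_tilt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rv_cx == 0.0:
            self.rv_cx = self.lv_a + self.septal_gap + self.rv_r * (1.0 - self.rv_beta)
        if self.rv_tilt is None:
            margin = 2.0
            z = np.linspace(-0.98 * self.rv_c, -1e-6, 64)
            s_lv = np.sqrt(np.clip(1.0 - (z / self.lv_c) ** 2, 0.0, None))
            s_rv = np.sqrt(np.clip(1.0 - (z / self.rv_c) ** 2, 0.0, None))
            need = self.lv_a * s_lv + self.rv_r * (1.0 - self.rv_beta) * s_rv + margin
            safe = float(np.min((self.rv_cx - need) / (-z)))
            self.rv_tilt = float(min(max(safe, 0.0), 0.45 * self.rv_cx / self.rv_c))

    def rv_axis_x(self, z: np.ndarray) -> np.ndarray:
        """RV cross-section center at depth z."""
        return self.rv_cx + self.rv_tilt * np.asarray(z, dtype=float)

    # -- derived geometry ---------------------------------------------------
    @property
    def rv_min_x(self) -> float:
        return self.rv_cx - self.rv_r * (1.0 - self.rv_beta)

    @property
    def rv_max_x(self) -> float:
        return self.rv_cx + self.rv_r * (1.0 + self.rv_beta)

    @property
    def wall_split_x(self) -> float:
        """Basal intercept of the LV/RV wall split plane; the septal gap
        goes to the LV.  The plane tilts with the RV axis:
        x - rv_tilt * z = wall_split_x."""
        gap = self.rv_min_x - self.lv_a
        return self.rv_min_x - 0.25 * gap

    def wall_plane_vector(self) -> np.ndarray:
        """[nx, ny, nz, d] with n . x = d, n pointing toward the RV side."""
        norm = math.sqrt(1.0 + self.rv_tilt ** 2)
        return np.array([1.0 / norm, 0.0, -self.rv_tilt / norm,
                         self.wall_split_x / norm])

    @property
    def epi_c(self) -> float:
        return max(self.lv_c + self.t_lv, self.rv_c + self.t_rv)

    @property
    def aortic_center(self) -> Tuple[float, float]:
        return (0.0, 0.0)

    @property
    def pulmonary_center(self) -> Tuple[float, float]:
        return (self.rv_cx, 0.0)

    def capsule_geometry(self, z: np.ndarray
                         ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(R_lv, R_rv, x_rv_disk) of the epicardial capsule at depth z.

        The RV disk circumscribes the flattened RV cross section: the max
        distance of the limacon from a center offset by r*beta is
        r*sqrt(1+beta^2).
        """
        z = np.asarray(z, dtype=float)
        c0 = self.lv_c + self.t_lv
        c1 = self.rv_c + self.t_rv
        r0 = (self.lv_a + self.t_lv) * np.sqrt(np.clip(1.0 - (z / c0) ** 2, 0.0, None))
        s1 = np.sqrt(np.clip(1.0 - (z / c1) ** 2, 0.0, None))
        r1 = (self.rv_r * math.sqrt(1.0 + self.rv_beta ** 2) + self.t_rv) * s1
        xd = self.rv_axis_x(z) + self.rv_r * self.rv_beta * s1
        return r0, r1, xd


# ---------------------------------------------------------------------------
# capsule cross sections
# ---------------------------------------------------------------------------

def _capsule_polygons(p: ShapeParams, z: np.ndarray, n: int = _N_POLY) -> np.ndarray:
    """CCW boundary polygons (Z, n, 2) of the capsule cross sections.

    The convex hull of disk0 (center 0, radius R0) and disk1 (center xe,
    radius R1) is two circular arcs joined by the external tangent lines;
    when one disk swallows the other the polygon degenerates to that circle.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    r0, r1, xd = p.capsule_geometry(z)  # (Z,)
    nz = z.size
    ns = n // 6                # points per tangent segment
    n1 = (n - 2 * ns) // 2     # RV-side arc
    n0 = n - 2 * ns - n1       # LV-side arc
    dist = np.maximum(xd, 1e-9)
    gam = np.arcsin(np.clip((r1 - r0) / dist, -1.0, 1.0))  # (Z,)

    u1 = np.linspace(0.0, 1.0, n1)[None, :]
    a1 = (-(0.5 * math.pi + gam))[:, None] + u1 * (math.pi + 2 * gam)[:, None]
    u0 = np.linspace(0.0, 1.0, n0)[None, :]
    a0 = (0.5 * math.pi + gam)[:, None] + u0 * (math.pi - 2 * gam)[:, None]
    pts1 = np.stack([xd[:, None] + r1[:, None] * np.cos(a1), r1[:, None] * np.sin(a1)], axis=-1)
    pts0 = np.stack([r0[:, None] * np.cos(a0), r0[:, None] * np.sin(a0)], axis=-1)
    tseg = (np.arange(1, ns + 1) / (ns + 1))[None, :, None]
    seg_top = pts1[:, -1:, :] + tseg * (pts0[:, :1, :] - pts1[:, -1:, :])
    seg_bot = pts0[:, -1:, :] + tseg * (pts1[:, :1, :] - pts0[:, -1:, :])
    out = np.concatenate([pts1, seg_top, pts0, seg_bot], axis=1)

    degenerate = xd <= np.abs(r1 - r0)
    if degenerate.any():
        th = np.linspace(0, 2 * math.pi, n, endpoint=False)
        for i in np.flatnonzero(degenerate):
            if r1[i] >= r0[i]:
                out[i, :, 0] = xd[i] + r1[i] * np.cos(th)
                out[i, :, 1] = r1[i] * np.sin(th)
            else:
                out[i, :, 0] = r0[i] * np.cos(th)
                out[i, :, 1] = r0[i] * np.sin(th)
    return out


def _shoelace(poly: np.ndarray) -> np.ndarray:
    """Signed areas of stacked closed polygons (..., n, 2)."""
    x = poly[..., 0]
    y = poly[..., 1]
    xr = np.roll(x, -1, axis=-1)
    yr = np.roll(y, -1, axis=-1)
    return 0.5 * (x * yr - xr * y).sum(axis=-1)


def _epi_volumes(p: ShapeParams) -> Tuple[float, float]:
    """(total capsule volume, volume right of the split plane), mm^3.

    The split plane tilts with the RV axis (x - rv_tilt*z = wall_split_x);
    clamping polygon x-coordinates at the per-depth cut line integrates the
    right-side region exactly up to polygon discretization.
    """
    z = np.linspace(-p.epi_c, 0.0, _N_Z)
    polys = _capsule_polygons(p, z)
    a_total = _shoelace(polys)
    x_cut = p.wall_split_x + p.rv_tilt * z
    clamped = polys.copy()
    np.maximum(clamped[..., 0], x_cut[:, None], out=clamped[..., 0])
    a_right = _shoelace(clamped)
    return float(np.trapezoid(a_total, z)), float(np.trapezoid(a_right, z))


def _polar_radius(poly: np.ndarray, origin: np.ndarray,
                  angles: np.ndarray) -> np.ndarray:
    """Polar radius of a convex polygon about an interior origin at angles."""
    d = poly - origin[None, :]
    ang = np.arctan2(d[:, 1], d[:, 0])
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang)
    ang_s = ang[order]
    rad_s = rad[order]
    ang_ext = np.concatenate([ang_s - 2 * math.pi, ang_s, ang_s + 2 * math.pi])
    rad_ext = np.concatenate([rad_s, rad_s, rad_s])
    query = np.mod(np.asarray(angles) + math.pi, 2 * math.pi) - math.pi
    return np.interp(query, ang_ext, rad_ext)


def _capsule_origin(p: ShapeParams, z: float) -> np.ndarray:
    """Interior polar origin sliding between the lobe centers with depth."""
    r0, r1, xd = p.capsule_geometry(np.array([z]))
    R0, R1, XD = float(r0[0]), float(r1[0]), float(xd[0])
    if R0 + R1 <= 0:
        return np.array([0.5 * XD, 0.0])
    return np.array([XD * R1 / (R0 + R1), 0.0])


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _half_ellipsoid_volume(a: float, b: float, c: float) -> float:
    return (2.0 / 3.0) * math.pi * a * b * c


def analytic_volumes(p: ShapeParams) -> Dict[str, float]:
    """Cavity/wall volumes (mL) of the closed parametric surfaces."""
    v_lv = _half_ellipsoid_volume(p.lv_a, p.lv_a, p.lv_c)
    v_rv = math.pi * p.rv_r ** 2 * (1.0 + 0.5 * p.rv_beta ** 2) * (2.0 * p.rv_c / 3.0)
    v_epi, v_epi_rv_side = _epi_volumes(p)
    return {
        "lv": v_lv / 1000.0,
        "rv": v_rv / 1000.0,
        "epi": v_epi / 1000.0,
        "wall_total": (v_epi - v_lv - v_rv) / 1000.0,
        "wall_lv": (v_epi - v_epi_rv_side - v_lv) / 1000.0,
        "wall_rv": (v_epi_rv_side - v_rv) / 1000.0,
    }


def _chord_newton2(fun, x0: np.ndarray, lo: float, hi: float,
                   tol: float = 0.05, max_iter: int = 10) -> np.ndarray:
    """Solve fun(x)=0 for 2 unknowns; the map is near-linear in x, so one
    finite-difference Jacobian (chord method) converges in a few steps."""
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    f = fun(x)
    h = 0.5
    j = np.empty((2, 2))
    for k in range(2):
        xp = x.copy()
        xp[k] += h
        j[:, k] = (fun(xp) - f) / h
    for _ in range(max_iter):
        if np.abs(f).max() < tol:
            break
        try:
            dx = np.linalg.solve(j, -f)
        except np.linalg.LinAlgError:
            break
        x = np.clip(x + np.clip(dx, -10.0, 10.0), lo, hi)
        f = fun(x)
    return x


def solve_epicardium(p: ShapeParams, wall_lv_ml: float, wall_rv_ml: float) -> ShapeParams:
    """Solve the free-wall clearance parameters for per-side wall targets."""

    def resid(t: np.ndarray) -> np.ndarray:
        q = replace(p, t_lv=float(t[0]), t_rv=float(t[1]), rv_cx=p.rv_cx)
        v = analytic_volumes(q)
        return np.array([v["wall_lv"] - wall_lv_ml, v["wall_rv"] - wall_rv_ml])

    x = _chord_newton2(resid, np.array([max(p.t_lv, 3.0), max(p.t_rv, 2.5)]),
                       lo=1.0, hi=45.0)
    return replace(p, t_lv=float(x[0]), t_rv=float(x[1]), rv_cx=p.rv_cx)


# ---------------------------------------------------------------------------
# meridian arc lengths and analytic strains
# ---------------------------------------------------------------------------

_PHI_GRID = np.linspace(0.0, 0.5 * math.pi, 121)


def meridian_length(rho: float, c: float, shear: float = 0.0,
                    cos_psi: float = 1.0) -> float:
    """Arc length of one meridian from apex pole to base.

    The meridian lies at circumferential angle psi on a half spheroid of
    in-plane radius ``rho``, depth ``c``, whose axis is sheared in x by
    ``shear`` per unit depth (the tilted RV long axis); for an untilted
    ventricle the result is the half-ellipse arc length.
    """
    phi = _PHI_GRID
    sin_psi_sq = max(1.0 - cos_psi ** 2, 0.0)
    dx = rho * cos_psi * np.cos(phi) + shear * c * np.sin(phi)
    dy_sq = rho ** 2 * sin_psi_sq * np.cos(phi) ** 2
    dz = c * np.sin(phi)
    integrand = np.sqrt(dx ** 2 + dy_sq + dz ** 2)
    return float(integrate.simpson(integrand, x=phi))


def _rv_rho(p: ShapeParams, theta: float) -> float:
    return p.rv_r * (1.0 + p.rv_beta * math.cos(theta))


def mean_longitudinal_strain(ed: ShapeParams, es: ShapeParams, ventricle: str,
                             n_theta: int = 12) -> float:
    """Mean Cauchy strain (%) of the continuous meridian lines, ED -> ES."""
    if ventricle == "LV":
        l0 = meridian_length(ed.lv_a, ed.lv_c)
        l1 = meridian_length(es.lv_a, es.lv_c)
        return 100.0 * (l1 - l0) / l0
    thetas = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    strains = []
    for th in thetas:
        l0 = meridian_length(_rv_rho(ed, th), ed.rv_c, ed.rv_tilt, math.cos(th))
        l1 = meridian_length(_rv_rho(es, th), es.rv_c, es.rv_tilt, math.cos(th))
        strains.append(100.0 * (l1 - l0) / l0)
    return float(np.mean(strains))


def _epi_ray_crossing(p: ShapeParams, z: float, cx: float,
                      psi: np.ndarray) -> np.ndarray:
    """Distance from (cx, 0) along directions psi to the epicardial contour
    at depth z (polar lookup on the closed-form cross-section polygon)."""
    poly = _capsule_polygons(p, np.array([z]), n=192)[0]
    return _polar_radius(poly, np.array([cx, 0.0]), np.asarray(psi, dtype=float))


def analytic_mean_thickness(p: ShapeParams, ventricle: str,
                            lv_c_ref: Optional[float] = None,
                            slice_fracs: Optional[np.ndarray] = None,
                            sector_half_angle_deg: float = 100.0,
                            n_psi: int = 40) -> float:
    """Mean analytic free-wall thickness (mm) over the short-axis stack.

    ``lv_c_ref`` fixes the apex-base extent used to place slices (defaults
    to the shape's own LV depth)."""
    if slice_fracs is None:
        slice_fracs = np.linspace(0.1, 0.9, 8)
    half = math.radians(sector_half_angle_deg)
    away = math.pi if ventricle == "LV" else 0.0
    c_ref = lv_c_ref if lv_c_ref is not None else p.lv_c
    c_v = p.lv_c if ventricle == "LV" else p.rv_c
    zs = -(1.0 - np.asarray(slice_fracs)) * c_ref
    zs = zs[np.abs(zs) < c_v]
    psi = away + np.linspace(-half, half, n_psi)
    polys = _capsule_polygons(p, zs, n=192)
    vals = []
    for z, poly in zip(zs, polys):
        s = math.sqrt(1.0 - (z / c_v) ** 2)
        if ventricle == "LV":
            cx = 0.0
            rho = p.lv_a * s * np.ones(n_psi)
        else:
            cx = float(p.rv_axis_x(z))
            rho = p.rv_r * (1.0 + p.rv_beta * np.cos(psi)) * s
        th = _polar_radius(poly, np.array([cx, 0.0]), psi) - rho
        vals.extend(th[th > 0].tolist())
    if not vals:
        raise ValueError("no valid thickness stations")
    return float(np.mean(vals))


def analytic_radial_strain(ed: ShapeParams, es: ShapeParams, ventricle: str,
                           slice_fracs: Optional[np.ndarray] = None,
                           sector_half_angle_deg: float = 100.0,
                           n_psi: int = 40) -> float:
    """Radial strain (%) from analytic endo->epi thickness along radial rays.

    The free-wall sector faces away from the other ventricle (-x for the LV,
    +x for the RV); slices sit at fixed fractions of the LV apex-base extent.
    This is the generator's independent ground truth for the centerline-based
    radial strain computed by the strain module.
    """
    if slice_fracs is None:
        slice_fracs = np.linspace(0.1, 0.9, 8)
    half = math.radians(sector_half_angle_deg)
    away = math.pi if ventricle == "LV" else 0.0
    vals = []
    for f in slice_fracs:
        z_ed = -(1.0 - f) * ed.lv_c
        z_es = -(1.0 - f) * es.lv_c
        c_ed = ed.lv_c if ventricle == "LV" else ed.rv_c
        c_es = es.lv_c if ventricle == "LV" else es.rv_c
        if abs(z_ed) >= c_ed or abs(z_es) >= c_es:
            continue
        s_ed = math.sqrt(1.0 - (z_ed / c_ed) ** 2)
        s_es = math.sqrt(1.0 - (z_es / c_es) ** 2)
        psi = away + np.linspace(-half, half, n_psi)
        if ventricle == "LV":
            cx_ed = cx_es = 0.0
            rho_ed = ed.lv_a * s_ed * np.ones(n_psi)
            rho_es = es.lv_a * s_es * np.ones(n_psi)
        else:
            cx_ed = float(ed.rv_axis_x(z_ed))
            cx_es = float(es.rv_axis_x(z_es))
            rho_ed = ed.rv_r * (1.0 + ed.rv_beta * np.cos(psi)) * s_ed
            rho_es = es.rv_r * (1.0 + es.rv_beta * np.cos(psi)) * s_es
        th_ed = _epi_ray_crossing(ed, z_ed, cx_ed, psi) - rho_ed
        th_es = _epi_ray_crossing(es, z_es, cx_es, psi) - rho_es
        ok = (th_ed > 0.25) & (th_es > 0.25)
        if ok.sum() < n_psi // 4:
            continue
        # slice-mean thickness ratio, matching the measurement convention
        vals.append(100.0 * (th_es[ok].mean() - th_ed[ok].mean()) / th_ed[ok].mean())
    if not vals:
        raise ValueError("no valid analytic thickness stations")
    return float(np.mean(vals))


def contracted_params(ed: ShapeParams, lam_c_lv: float, lam_l_lv: float,
                      lam_c_rv: float, lam_l_rv: float) -> ShapeParams:
    """ES shape from per-ventricle circumferential / longitudinal scales.

    Cavity volumes scale exactly by ``lam_c^2 * lam_l``; ring radii by
    ``lam_c``.  The RV axis stays in place, so the septal gap widens as the
    cavities contract (septal thickening).  The epicardium keeps the ED
    clearance parameters until re-solved (e.g. for wall-volume conservation).
    """
    return replace(
        ed,
        lv_a=ed.lv_a * lam_c_lv,
        lv_c=ed.lv_c * lam_l_lv,
        rv_r=ed.rv_r * lam_c_rv,
        rv_c=ed.rv_c * lam_l_rv,
        rv_cx=ed.rv_cx,
    )


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _hemi_grid(radius_at: Callable[[float, np.ndarray], np.ndarray],
               center_at: Callable[[float], np.ndarray], depth: float,
               n_rings: int, n_mer: int, offset: int
               ) -> Tuple[np.ndarray, np.ndarray, StructuredGrid]:
    """Apex pole + stacked rings, outward oriented.

    ``radius_at(z, theta)`` gives the ring's polar radii about
    ``center_at(z)`` (a 2-vector) at depth z.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, n_mer, endpoint=False)
    phis = (np.arange(1, n_rings + 1) / n_rings) * (0.5 * math.pi)
    apex_c = center_at(-depth)
    verts = [np.array([[apex_c[0], apex_c[1], -depth]])]
    for phi in phis:
        z = -depth * math.cos(phi)
        c = center_at(z)
        r = radius_at(z, theta)
        ring = np.column_stack([c[0] + r * np.cos(theta), c[1] + r * np.sin(theta),
                                np.full(n_mer, z)])
        verts.append(ring)
    verts = np.vstack(verts)
    pole = offset
    rings = offset + 1 + np.arange(n_rings * n_mer).reshape(n_rings, n_mer)
    tris: List[Tuple[int, int, int]] = []
    r0 = rings[0]
    for j in range(n_mer):
        jn = (j + 1) % n_mer
        tris.append((pole, r0[jn], r0[j]))
    for k in range(n_rings - 1):
        ra, rb = rings[k], rings[k + 1]
        for j in range(n_mer):
            jn = (j + 1) % n_mer
            tris.append((ra[j], ra[jn], rb[jn]))
            tris.append((ra[j], rb[jn], rb[j]))
    grid = StructuredGrid(pole=pole, rings=rings)
    return verts, np.array(tris, dtype=np.int64), grid


def _cycle_fractions(points: np.ndarray) -> np.ndarray:
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum[:-1] / cum[-1]


def _zipper(outer_idx: np.ndarray, inner_idx: np.ndarray,
            positions: np.ndarray) -> np.ndarray:
    """Triangulate the band between two CCW closed cycles (+z winding)."""
    op = positions[outer_idx][:, :2]
    ip = positions[inner_idx][:, :2]
    c = ip.mean(axis=0)
    ang_out0 = math.atan2(*(op[0] - c)[::-1])
    ang_in = np.arctan2(ip[:, 1] - c[1], ip[:, 0] - c[0])
    k = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang_in - ang_out0))))))
    inner_idx = np.roll(inner_idx, -k)
    ip = positions[inner_idx][:, :2]
    fo = np.append(_cycle_fractions(op), 1.0)
    fi = np.append(_cycle_fractions(ip), 1.0)
    out = np.append(outer_idx, outer_idx[0])
    inn = np.append(inner_idx, inner_idx[0])
    tris: List[Tuple[int, int, int]] = []
    o = i = 0
    while o < len(out) - 1 or i < len(inn) - 1:
        adv_out = o < len(out) - 1 and (i == len(inn) - 1 or fo[o + 1] <= fi[i + 1])
        if adv_out:
            tris.append((out[o], out[o + 1], inn[i]))
            o += 1
        else:
            tris.append((inn[i + 1], inn[i], out[o]))
            i += 1
    return np.array(tris, dtype=np.int64)


def build_surface(p: ShapeParams, res: Resolution, subject_id: str,
                  phase: str) -> BiventricularSurface:
    """Assemble the labeled biventricular surface for one parameter set."""
    res.validate()
    verts_all: List[np.ndarray] = []
    tris_all: List[np.ndarray] = []
    labels: List[np.ndarray] = []
    grids: Dict[int, StructuredGrid] = {}
    offset = 0

    # LV endocardium
    def lv_radius(z: float, th: np.ndarray) -> np.ndarray:
        s = math.sqrt(max(1.0 - (z / p.lv_c) ** 2, 0.0))
        return np.full(th.shape, p.lv_a * s)

    v, t, g = _hemi_grid(lv_radius, lambda z: np.zeros(2), p.lv_c,
                         res.endo_rings, res.endo_meridians, offset)
    verts_all.append(v); tris_all.append(t)
    labels.append(np.full(len(v), int(SurfaceLabel.LV_ENDO)))
    grids[int(SurfaceLabel.LV_ENDO)] = g
    mitral_ring = g.rings[-1].copy()
    offset += len(v)

    # RV endocardium (septally flattened)
    def rv_radius(z: float, th: np.ndarray) -> np.ndarray:
        s = math.sqrt(max(1.0 - (z / p.rv_c) ** 2, 0.0))
        return p.rv_r * (1.0 + p.rv_beta * np.cos(th)) * s

    v, t, g = _hemi_grid(rv_radius, lambda z: np.array([float(p.rv_axis_x(z)), 0.0]),
                         p.rv_c, res.endo_rings, res.endo_meridians, offset)
    verts_all.append(v); tris_all.append(t)
    labels.append(np.full(len(v), int(SurfaceLabel.RV_ENDO)))
    grids[int(SurfaceLabel.RV_ENDO)] = g
    tricuspid_ring = g.rings[-1].copy()
    offset += len(v)

    # epicardial capsule shell
    def epi_radius(z: float, th: np.ndarray) -> np.ndarray:
        poly = _capsule_polygons(p, np.array([z]))[0]
        return _polar_radius(poly, _capsule_origin(p, z), th)

    v, t, g = _hemi_grid(epi_radius, lambda z: _capsule_origin(p, z), p.epi_c,
                         res.epi_rings, res.epi_meridians, offset)
    verts_all.append(v); tris_all.append(t)
    labels.append(np.full(len(v), int(SurfaceLabel.EPI)))
    grids[int(SurfaceLabel.EPI)] = g
    basal_ring = g.rings[-1].copy()
    offset += len(v)

    # basal plate: flat at z=0 with aortic and pulmonary holes
    positions = np.vstack(verts_all)
    ao_c, po_c = p.aortic_center, p.pulmonary_center
    x_mid = 0.5 * (ao_c[0] + po_c[0])
    hole_theta = np.linspace(0.0, 2.0 * math.pi, res.hole_points, endpoint=False)
    aortic_ring = offset + np.arange(res.hole_points)
    ao_pts = np.column_stack([ao_c[0] + p.aortic_r * np.cos(hole_theta),
                              ao_c[1] + p.aortic_r * np.sin(hole_theta),
                              np.zeros(res.hole_points)])
    offset += res.hole_points
    pulmonary_ring = offset + np.arange(res.hole_points)
    po_pts = np.column_stack([po_c[0] + p.pulmonary_r * np.cos(hole_theta),
                              po_c[1] + p.pulmonary_r * np.sin(hole_theta),
                              np.zeros(res.hole_points)])
    offset += res.hole_points

    hull0 = _capsule_origin(p, 0.0)
    ring_pos = positions[basal_ring]
    theta_ring = np.arctan2(ring_pos[:, 1], ring_pos[:, 0] - hull0[0]) % (2 * math.pi)
    order = np.argsort(theta_ring)
    ring_sorted = basal_ring[order]
    theta_sorted = theta_ring[order]
    # split the basal ring at the two vertices nearest the dividing chord
    ring_x = positions[ring_sorted][:, 0]
    upper = theta_sorted <= math.pi
    th_c = float(theta_sorted[upper][np.argmin(np.abs(ring_x[upper] - x_mid))])
    i_top = int(np.argmin(np.abs(theta_sorted - th_c)))
    i_bot = int(np.argmin(np.abs(theta_sorted - (2 * math.pi - th_c))))
    left_arc = ring_sorted[i_top:i_bot + 1]    # theta ascending: top -> left -> bottom
    right_arc = np.concatenate([ring_sorted[i_bot:], ring_sorted[:i_top + 1]])
    top_v = int(left_arc[0])
    bot_v = int(left_arc[-1])
    p_top, p_bot = positions[top_v], positions[bot_v]
    fr = (np.arange(1, res.seam_points + 1) / (res.seam_points + 1))[:, None]
    seam_pts = p_bot[None, :] + fr * (p_top - p_bot)[None, :]
    seam = offset + np.arange(res.seam_points)  # ordered bottom -> top
    offset += res.seam_points

    positions = np.vstack([positions, ao_pts, po_pts, seam_pts])
    labels.append(np.full(2 * res.hole_points + res.seam_points, int(SurfaceLabel.EPI)))

    left_cycle = np.concatenate([left_arc, seam])            # CCW
    right_cycle = np.concatenate([right_arc, seam[::-1]])    # CCW
    tris_all.append(_zipper(left_cycle, aortic_ring, positions))
    tris_all.append(_zipper(right_cycle, pulmonary_ring, positions))

    surface = BiventricularSurface(
        subject_id=subject_id,
        phase=phase,
        vertices=positions,
        triangles=np.vstack(tris_all),
        surface_label=np.concatenate(labels),
        annulus_rings={
            "mitral": mitral_ring,
            "tricuspid": tricuspid_ring,
            "aortic": aortic_ring,
            "pulmonary": pulmonary_ring,
        },
        wall_assignment=np.where(
            positions[:, 0] - p.rv_tilt * positions[:, 2] <= p.wall_split_x,
            int(WallSide.LV), int(WallSide.RV)),
        wall_plane=p.wall_plane_vector(),
        grids=grids,
    )
    # endocardial vertices always belong to their own ventricle's wall
    surface.wall_assignment[surface.label_mask(SurfaceLabel.LV_ENDO)] = int(WallSide.LV)
    surface.wall_assignment[surface.label_mask(SurfaceLabel.RV_ENDO)] = int(WallSide.RV)
    return surface


def generate_template(resolution: Optional[Resolution] = None,
                      params: Optional[ShapeParams] = None,
                      subject_id: str = "template",
                      phase: str = "ED") -> Tuple[BiventricularSurface, Dict[str, float]]:
    """Build the reference template surface and its analytic volumes."""
    res = resolution or Resolution()
    p = params or ShapeParams()
    surf = build_surface(p, res, subject_id, phase)
    surf.validate()
    return surf, analytic_volumes(p)
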