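"""Named smooth deformation fields planted into synthetic cohorts.

Each field is a per-vertex displacement pattern on the template expressing
one of the regional remodeling features the shape-mode analysis is meant to
recover: RV apical dilation, RV basal bulging, LV dilation, LV conicity and
pulmonary-annulus dilation.  Fields are smooth, localized to the structures
they name, have their rigid-motion component projected out (so generalized
alignment cannot absorb them), and are mutually near-orthogonal as stacked
3N vectors, which makes the planted low-dimensional shape variation
recoverable by PCA.

A field's *natural* magnitude is normalized so that one unit of coefficient
produces 1 mm of its characteristic displacement (peak radial displacement;
for the pulmonary field, 1 mm of annulus radius increase).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from ..geometry import BiventricularSurface, SurfaceLabel, WallSide

__all__ = [
    "DEFORMATION_NAMES",
    "deformation_field",
    "deformation_basis",
    "apply_named_deformation",
]

DEFORMATION_NAMES = (
    "RV_APICAL_DILATION",
    "RV_BASAL_BULGE",
    "LV_DILATION",
    "LV_CONICITY",
    "PV_ANNULUS_DILATION",
)


def _project_out_rigid(field: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Remove translation and infinitesimal-rotation components."""
    n = verts.shape[0]
    centered = verts - verts.mean(axis=0)
    basis = []
    for ax in range(3):
        e = np.zeros((n, 3))
        e[:, ax] = 1.0
        basis.append(e.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        basis.append(np.cross(np.broadcast_to(omega, (n, 3)), centered).ravel())
    B = np.array(basis).T  # (3n, 6)
    q, _ = np.linalg.qr(B)
    flat = field.ravel()
    flat = flat - q @ (q.T @ flat)
    return flat.reshape(n, 3)


def _radial_about(verts: np.ndarray, axis_xy: Tuple[float, float]) -> Tuple[np.ndarray, np.ndarray]:
    """Unit in-plane radial directions and radii about a vertical axis."""
    d = verts[:, :2] - np.asarray(axis_xy)[None, :]
    r = np.linalg.norm(d, axis=1)
    u = np.zeros_like(verts)
    nz = r > 1e-9
    u[nz, :2] = d[nz] / r[nz, None]
    return u, r


def _lv_mask(surface: BiventricularSurface) -> np.ndarray:
    m = surface.label_mask(SurfaceLabel.LV_ENDO)
    if surface.wall_assignment is not None:
        m = m | (surface.label_mask(SurfaceLabel.EPI)
                 & (surface.wall_assignment == int(WallSide.LV)))
    return m


def _rv_mask(surface: BiventricularSurface) -> np.ndarray:
    m = surface.label_mask(SurfaceLabel.RV_ENDO)
    if surface.wall_assignment is not None:
        m = m | (surface.label_mask(SurfaceLabel.EPI)
                 & (surface.wall_assignment == int(WallSide.RV)))
    return m


def deformation_field(surface: BiventricularSurface, name: str) -> np.ndarray:
    """The (N, 3) displacement field for one named deformation, natural units."""
    v = surface.vertices
    n = surface.n_vertices
    field = np.zeros((n, 3))

    if name in ("LV_DILATION", "LV_CONICITY"):
        mask = _lv_mask(surface)
        lv_pts = v[surface.label_mask(SurfaceLabel.LV_ENDO)]
        axis_xy = tuple(lv_pts[:, :2].mean(axis=0))
        u, r = _radial_about(v, axis_xy)
        depth = -v[mask][:, 2].min()
        rad_profile = np.sqrt(np.clip(1.0 - (v[:, 2] / depth) ** 2, 0.0, 1.0))
        if name == "LV_DILATION":
            w = rad_profile
        else:
            # base dilates, apex narrows: linear ramp in depth, made
            # orthogonal to the uniform dilation pattern over the LV mask
            zeta = 1.0 + 2.0 * (v[:, 2] / depth)  # +1 at base, -1 at apex
            w = rad_profile * zeta
            w_dil = rad_profile
            num = float((w[mask] * w_dil[mask]).sum())
            den = float((w_dil[mask] ** 2).sum())
            w = w - (num / den) * w_dil
        field[mask] = (w[:, None] * u)[mask]

    elif name in ("RV_APICAL_DILATION", "RV_BASAL_BULGE"):
        mask = _rv_mask(surface)
        rv_pts = v[surface.label_mask(SurfaceLabel.RV_ENDO)]
        axis_xy = tuple(rv_pts[:, :2].mean(axis=0))
        u, r = _radial_about(v, axis_xy)
        depth = -v[mask][:, 2].min()
        rad_profile = np.sqrt(np.clip(1.0 - (v[:, 2] / depth) ** 2, 0.0, 1.0))
        if name == "RV_APICAL_DILATION":
            g = np.exp(-(((v[:, 2] + 0.72 * depth) / (0.20 * depth)) ** 2))
            w = rad_profile * g
        else:
            g = np.exp(-(((v[:, 2] + 0.15 * depth) / (0.18 * depth)) ** 2))
            # free wall faces away from the LV (+x side of the RV axis)
            psi = np.arctan2(v[:, 1] - axis_xy[1], v[:, 0] - axis_xy[0])
            w = rad_profile * g * 0.5 * (1.0 + np.cos(psi))
        field[mask] = (w[:, None] * u)[mask]

    elif name == "PV_ANNULUS_DILATION":
        ring = surface.annulus_rings["pulmonary"]
        ring_pts = v[ring]
        center = ring_pts.mean(axis=0)
        ring_r = float(np.linalg.norm(ring_pts[:, :2] - center[None, :2], axis=1).mean())
        mask = surface.label_mask(SurfaceLabel.EPI)
        u, r = _radial_about(v, (center[0], center[1]))
        sigma = 0.6 * ring_r
        w = np.exp(-(((r - ring_r) ** 2 + (v[:, 2] - center[2]) ** 2) / (2.0 * sigma ** 2)))
        field[mask] = (w[:, None] * u)[mask]

    else:
        raise ValueError(f"unknown deformation name {name!r}")

    field = _project_out_rigid(field, v)

    # renormalize natural units after the rigid projection
    if name == "PV_ANNULUS_DILATION":
        ring = surface.annulus_rings["pulmonary"]
        center = v[ring].mean(axis=0)
        u_ring, _ = _radial_about(v[ring], (center[0], center[1]))
        char = float(np.einsum("ij,ij->i", field[ring], u_ring).mean())
    else:
        char = float(np.abs(field).max())
    if char <= 0:
        raise ValueError(f"degenerate deformation field {name!r}")
    return field / char


def apply_named_deformation(surface: BiventricularSurface, name: str,
                            magnitude: float) -> np.ndarray:
    """Deformed vertex array: template plus ``magnitude`` (mm) of one field."""
    return surface.vertices + magnitude * deformation_field(surface, name)


def deformation_basis(surface: BiventricularSurface,
                      names: Sequence[str] = DEFORMATION_NAMES,
                      max_pair_cosine: float = 0.2) -> Dict[str, np.ndarray]:
    """All named fields, verified mutually near-orthogonal as 3N vectors."""
    fields = {name: deformation_field(surface, name) for name in names}
    flat = {k: f.ravel() / np.linalg.norm(f) for k, f in fields.items()}
    keys = list(flat)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            c = abs(float(flat[a] @ flat[b]))
            if c >= max_pair_cosine:
                raise ValueError(
                    f"deformation fields {a} and {b} not near-orthogonal (|cos|={c:.3f})"
                )
    return fields
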