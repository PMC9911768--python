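"""Geometric strain: arc-length Cauchy strains and centerline radial strain."""

import dataclasses
import math

import numpy as np
import pytest

from bivatlas.geometry import BiventricularSurface, StructuredGrid, SurfaceLabel
from bivatlas.strain import (
    cauchy_strain,
    compute_strains,
    directional_strain,
    radial_strain_centerline,
    sample_parameter_lines,
)
from bivatlas.synthetic import ShapeParams, Resolution, build_surface
from bivatlas.synthetic.template import contracted_params, mean_longitudinal_strain


@pytest.mark.parametrize("l0,l1,expected", [(10.0, 8.0, -20.0),
                                            (10.0, 10.0, 0.0),
                                            (10.0, 11.5, 15.0)])
def test_cauchy_strain_formula(l0, l1, expected):
    assert cauchy_strain(l0, l1) == pytest.approx(expected)


def test_cauchy_strain_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        cauchy_strain(0.0, 5.0)


# ---------------------------------------------------------------------------
# parameter lines on the structured grid
# ---------------------------------------------------------------------------

class TestParameterLines:
    def test_counts_and_closure(self, template):
        surf, _ = template
        g = surf.grids[int(SurfaceLabel.LV_ENDO)]
        longs = sample_parameter_lines(surf, "LONGITUDINAL", "LV")
        rings = sample_parameter_lines(surf, "CIRCUMFERENTIAL", "LV")
        assert len(longs) == g.n_meridians
        assert len(rings) == g.n_rings
        for r in rings:
            assert r[0] == r[-1]  # closed
        for ln in longs:
            assert ln[0] == g.pole

    def test_lines_carry_requested_label(self, template):
        surf, _ = template
        for vent, label in (("LV", SurfaceLabel.LV_ENDO),
                            ("RV", SurfaceLabel.RV_ENDO)):
            for ln in sample_parameter_lines(surf, "LONGITUDINAL", vent):
                assert (surf.surface_label[ln] == int(label)).all()

    def test_unstructured_mesh_rejected(self, template):
        surf, _ = template
        bare = dataclasses.replace(surf, grids={})
        with pytest.raises(ValueError, match="slice-based"):
            sample_parameter_lines(bare, "LONGITUDINAL", "LV")


# ---------------------------------------------------------------------------
# affine phantoms on the parametric template
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def template_pair():
    p = ShapeParams()
    res = Resolution()
    ed = build_surface(p, res, "phantom", "ED")
    return p, res, ed


class TestDirectionalStrain:
    def test_identity_deformation_is_exactly_zero(self, template_pair):
        _, _, ed = template_pair
        es = dataclasses.replace(ed, phase="ES")
        for vent in ("LV", "RV"):
            assert directional_strain(ed, es, "LONGITUDINAL", vent) == 0.0
            assert directional_strain(ed, es, "CIRCUMFERENTIAL", vent) == 0.0

    def test_ring_scaling_gives_exact_circumferential_strain(self, template_pair):
        p, res, ed = template_pair
        pes = contracted_params(p, 0.9, 1.0, 0.9, 1.0)
        es = build_surface(pes, res, "phantom", "ES")
        for vent in ("LV", "RV"):
            cs = directional_strain(ed, es, "CIRCUMFERENTIAL", vent)
            assert cs == pytest.approx(-10.0, abs=1e-9)

    def test_long_axis_scaling_matches_quadrature_oracle(self, template_pair):
        """Mesh-measured longitudinal strain under a 0.85 long-axis scaling
        equals the continuous-meridian arc-length value within 0.5%."""
        p, res, ed = template_pair
        pes = contracted_params(p, 1.0, 0.85, 1.0, 0.85)
        es = build_surface(pes, res, "phantom", "ES")
        for vent in ("LV", "RV"):
            measured = directional_strain(ed, es, "LONGITUDINAL", vent)
            oracle = mean_longitudinal_strain(
                p, pes, vent, n_theta=res.endo_meridians)
            assert measured == pytest.approx(oracle, abs=0.5)

    def test_lv_only_deformation_leaves_rv_strains_zero(self, template_pair):
        _, _, ed = template_pair
        verts = ed.vertices.copy()
        lv = ed.label_mask(SurfaceLabel.LV_ENDO)
        center = verts[lv].mean(axis=0)
        verts[lv] = center + 0.9 * (verts[lv] - center)
        es = dataclasses.replace(ed, phase="ES", vertices=verts)
        assert directional_strain(ed, es, "LONGITUDINAL", "RV") == 0.0
        assert directional_strain(ed, es, "CIRCUMFERENTIAL", "RV") == 0.0
        assert directional_strain(ed, es, "CIRCUMFERENTIAL", "LV") < -5.0


# ---------------------------------------------------------------------------
# annulus phantom for the centerline radial strain
# ---------------------------------------------------------------------------

def cylinder_phantom(r_endo, r_epi, height=80.0, n_z=24, n_theta=48):
    """Concentric open cylinders: LV endo inside, epicardium outside.

    The top endo ring doubles as the mitral annulus so the slice stack has
    a long axis; there is no RV, so the full contour is used.
    """
    theta = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    zs = np.linspace(-height, 0.0, n_z)
    verts = []
    labels = []
    for radius, label in ((r_endo, SurfaceLabel.LV_ENDO),
                          (r_epi, SurfaceLabel.EPI)):
        for z in zs:
            ring = np.column_stack([radius * np.cos(theta),
                                    radius * np.sin(theta),
                                    np.full(n_theta, z)])
            verts.append(ring)
        labels.append(np.full(n_z * n_theta, int(label)))
    verts = np.vstack(verts)

    tris = []
    for block in (0, n_z * n_theta):
        for k in range(n_z - 1):
            for j in range(n_theta):
                jn = (j + 1) % n_theta
                a = block + k * n_theta + j
                b = block + k * n_theta + jn
                c = block + (k + 1) * n_theta + jn
                d = block + (k + 1) * n_theta + j
                tris.extend([(a, b, c), (a, c, d)])
    mitral = np.arange((n_z - 1) * n_theta, n_z * n_theta)
    grid = StructuredGrid(pole=0, rings=np.arange(n_z * n_theta).reshape(n_z, n_theta))
    return BiventricularSurface(
        subject_id="annulus", phase="ED", vertices=verts,
        triangles=np.array(tris), surface_label=np.concatenate(labels),
        annulus_rings={"mitral": mitral},
        grids={int(SurfaceLabel.LV_ENDO): grid})


class TestRadialStrainCenterline:
    def test_annulus_thickening_matches_closed_form(self):
        ed = cylinder_phantom(r_endo=25.0, r_epi=33.0)  # 8 mm wall
        es_surf = cylinder_phantom(r_endo=25.0, r_epi=35.0)  # 10 mm wall
        es = dataclasses.replace(es_surf, phase="ES")
        rs = radial_strain_centerline(ed, es, "LV")
        assert rs == pytest.approx(25.0, abs=1.0)

    def test_annulus_invariant_to_plane_orientation(self, rng):
        ed = cylinder_phantom(25.0, 33.0)
        es = dataclasses.replace(cylinder_phantom(25.0, 35.0), phase="ES")
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-40, 40, 3)
        ed_r = dataclasses.replace(ed, vertices=ed.vertices @ q.T + t)
        es_r = dataclasses.replace(es, vertices=es.vertices @ q.T + t)
        rs = radial_strain_centerline(ed_r, es_r, "LV")
        assert rs == pytest.approx(25.0, abs=1.0)

    def test_identity_and_halved_thickness(self):
        ed = cylinder_phantom(25.0, 33.0)
        assert radial_strain_centerline(
            ed, dataclasses.replace(ed, phase="ES"), "LV") == pytest.approx(0.0, abs=1e-9)
        es = dataclasses.replace(cylinder_phantom(25.0, 29.0), phase="ES")
        rs = radial_strain_centerline(ed, es, "LV")  # 8 mm -> 4 mm
        assert rs == pytest.approx(-50.0, abs=1.0)

    def test_too_few_valid_slices_raises(self):
        ed = cylinder_phantom(25.0, 33.0)
        es = dataclasses.replace(ed, phase="ES")
        short = [(np.array([0.0, 0.0, 500.0]), np.array([0.0, 0.0, 1.0]))] * 4
        with pytest.raises(ValueError, match="valid short-axis slices"):
            radial_strain_centerline(ed, es, "LV", slice_planes=short)


# ---------------------------------------------------------------------------
# full strain set on clean generated subjects
# ---------------------------------------------------------------------------

class TestComputeStrains:
    def test_matches_generator_truth_on_clean_subjects(self, clean_pair):
        """With no noise, no planted variation and no misalignment, the
        measured strains equal the analytic truth: arc-length strains to
        numerical precision, radial strains within mesh-discretization
        tolerance (the RV free wall is only ~2-3 mm thick, so polygonal
        inscription error is a visible fraction of its thickness)."""
        co = clean_pair
        for i in range(len(co.records)):
            sr = compute_strains(co.ed_surfaces[i], co.es_surfaces[i]).as_dict()
            t = co.truth[i].strains
            for key in ("lv_ls", "rv_ls", "lv_cs", "rv_cs"):
                assert sr[key] == pytest.approx(t[key], abs=0.05)
            assert sr["lv_rs"] == pytest.approx(t["lv_rs"], abs=1.5)
            assert sr["rv_rs"] == pytest.approx(t["rv_rs"], abs=13.0)

    def test_rv_radial_error_shrinks_with_resolution(self):
        from bivatlas.synthetic import CohortConfig, generate_cohort

        errs = {}
        for tag, res in (("coarse", None),
                         ("fine", Resolution(endo_rings=24, endo_meridians=48,
                                             epi_rings=28, epi_meridians=72))):
            kw = dict(seed=4, vertex_noise_sd=0.0, misalign_rot_deg=0.0,
                      misalign_trans_mm=0.0, planted_modes=[])
            if res is not None:
                kw["resolution"] = res
            cfg = CohortConfig(**kw)
            cfg.pvr.n = 1
            cfg.no_pvr.n = 2
            co = generate_cohort(cfg)
            sr = compute_strains(co.ed_surfaces[0], co.es_surfaces[0]).as_dict()
            errs[tag] = abs(sr["rv_rs"] - co.truth[0].strains["rv_rs"])
        assert errs["fine"] < errs["coarse"]

    def test_invariant_to_common_rigid_transform(self, clean_pair, rng):
        co = clean_pair
        ed, es = co.ed_surfaces[0], co.es_surfaces[0]
        base = compute_strains(ed, es).as_dict()
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-30, 30, 3)
        ed_r = dataclasses.replace(ed, vertices=ed.vertices @ q.T + t)
        es_r = dataclasses.replace(es, vertices=es.vertices @ q.T + t)
        moved = compute_strains(ed_r, es_r).as_dict()
        for key in base:
            assert moved[key] == pytest.approx(base[key], abs=1e-6)

    def test_all_six_fields_populated(self, clean_pair):
        co = clean_pair
        sr = compute_strains(co.ed_surfaces[0], co.es_surfaces[0])
        d = sr.as_dict()
        assert set(d) == {"lv_ls", "rv_ls", "lv_cs", "rv_cs", "lv_rs", "rv_rs"}
        assert all(np.isfinite(v) for v in d.values())
        # contracting ventricles shorten; thickening walls have positive RS
        assert d["lv_ls"] < 0 and d["rv_ls"] < 0
        assert d["lv_cs"] < 0 and d["rv_cs"] < 0
        assert d["lv_rs"] > 0 and d["rv_rs"] > 0
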