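"""Mesh volumes, masses and imaging indices."""

import numpy as np
import pytest
import trimesh

from bivatlas import geometry as G
from bivatlas.synthetic import CohortConfig, generate_cohort, generate_template


def unit_cube_surface():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return G.ClosedSurface(np.asarray(box.vertices), np.asarray(box.faces))


class TestEnclosedVolume:
    def test_unit_cube_is_one_microliter(self):
        # 1 mm^3 = 0.001 mL
        assert G.enclosed_volume(unit_cube_surface()) == pytest.approx(0.001)

    @pytest.mark.parametrize("subdiv,rtol", [(1, 0.14), (2, 0.04), (3, 0.01)])
    def test_icosphere_converges_to_closed_form(self, subdiv, rtol):
        sphere = trimesh.creation.icosphere(subdivisions=subdiv, radius=10.0)
        vol = G.enclosed_volume(G.ClosedSurface(np.asarray(sphere.vertices),
                                                np.asarray(sphere.faces)))
        exact = 4.0 / 3.0 * np.pi * 1000.0 / 1000.0  # mL
        assert vol == pytest.approx(exact, rel=rtol)
        if subdiv >= 3:  # >= 1280 faces: inside 1 percent
            assert abs(vol - exact) / exact < 0.01

    def test_error_decreases_monotonically_with_refinement(self):
        exact = 4.0 / 3.0 * np.pi
        errs = []
        for k in (1, 2, 3):
            s = trimesh.creation.icosphere(subdivisions=k, radius=10.0)
            v = G.enclosed_volume(G.ClosedSurface(np.asarray(s.vertices),
                                                  np.asarray(s.faces)))
            errs.append(abs(v - exact))
        assert errs[0] > errs[1] > errs[2]

    def test_rigid_invariance_and_scaling_equivariance(self, rng):
        s = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        verts = np.asarray(s.vertices)
        faces = np.asarray(s.faces)
        v0 = G.enclosed_volume(G.ClosedSurface(verts, faces))
        # random rotation + translation
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = verts @ q.T + rng.uniform(-50, 50, 3)
        v1 = G.enclosed_volume(G.ClosedSurface(moved, faces))
        assert v1 == pytest.approx(v0, rel=1e-9)
        v2 = G.enclosed_volume(G.ClosedSurface(2.0 * verts, faces))
        assert v2 == pytest.approx(8.0 * v0, rel=1e-12)

    def test_open_surface_rejected(self):
        cs = unit_cube_surface()
        assert G.enclosed_volume(cs) > 0
        with pytest.raises(G.TopologyError):
            G.enclosed_volume(G.ClosedSurface(cs.vertices, cs.triangles[:-1]))


class TestCloseSurface:
    def test_capped_subsurfaces_are_spheres(self, template):
        surf, _ = template
        for label in G.SurfaceLabel:
            cs = G.close_surface(surf, label)
            v, f = len(cs.vertices), len(cs.triangles)
            assert v - 3 * f // 2 + f == 2  # Euler characteristic

    def test_already_closed_surface_unchanged(self):
        box = trimesh.creation.box(extents=(2, 2, 2))
        surf = G.BiventricularSurface(
            subject_id="x", phase="ED", vertices=np.asarray(box.vertices),
            triangles=np.asarray(box.faces),
            surface_label=np.zeros(len(box.vertices), dtype=int),
            annulus_rings={})
        cs = G.close_surface(surf, G.SurfaceLabel.LV_ENDO)
        assert len(cs.vertices) == len(box.vertices)
        assert len(cs.triangles) == len(box.faces)

    def test_dangling_boundary_not_in_ring_raises(self, template):
        surf, _ = template
        broken = G.BiventricularSurface(
            subject_id=surf.subject_id, phase=surf.phase,
            vertices=surf.vertices, triangles=surf.triangles[:-2],
            surface_label=surf.surface_label,
            annulus_rings=surf.annulus_rings, grids=surf.grids)
        with pytest.raises(G.TopologyError):
            G.close_surface(broken, G.SurfaceLabel.EPI)


class TestCavityAndWallVolumes:
    def test_cavities_match_analytic_within_2pct(self, template):
        surf, truth = template
        vols = G.compute_cavity_volumes(surf)
        for key in ("lv", "rv", "epi"):
            assert vols[key] == pytest.approx(truth[key], rel=0.02)

    def test_similarity_scaling_cubes_volumes(self, template):
        surf, _ = template
        vols = G.compute_cavity_volumes(surf)
        import dataclasses
        scaled = dataclasses.replace(surf, vertices=2.0 * surf.vertices)
        vols2 = G.compute_cavity_volumes(scaled)
        for key in vols:
            assert vols2[key] == pytest.approx(8.0 * vols[key], rel=1e-9)

    def test_wall_split_matches_analytic(self, template):
        surf, truth = template
        wv = G.wall_volumes(surf)
        assert wv["total"] == pytest.approx(truth["wall_total"], rel=0.02)
        assert wv["lv"] == pytest.approx(truth["wall_lv"], rel=0.03)
        assert wv["rv"] == pytest.approx(truth["wall_rv"], rel=0.03)

    def test_wall_split_without_explicit_plane(self, template):
        surf, truth = template
        import dataclasses
        surf2 = dataclasses.replace(surf, wall_plane=None)
        wv = G.wall_volumes(surf2)
        # estimated interface plane: coarser but still close
        assert wv["lv"] == pytest.approx(truth["wall_lv"], rel=0.10)

    def test_incompressible_deformation_conserves_wall(self):
        # clean cohort: the property under test is the ED->ES deformation's
        # wall-volume conservation, so planted shape variation (which
        # displaces both phases by the same field and therefore changes
        # their wall volumes unequally) and measurement noise are off
        cfg = CohortConfig(seed=3, strain_mode="incompressible",
                           vertex_noise_sd=0.0, planted_modes=[])
        cfg.pvr.n = 3
        cfg.no_pvr.n = 3
        co = generate_cohort(cfg)
        for ed, es in zip(co.ed_surfaces[:3], co.es_surfaces[:3]):
            ved = G.compute_cavity_volumes(ed)
            ves = G.compute_cavity_volumes(es)
            wall_ed = ved["epi"] - ved["lv"] - ved["rv"]
            wall_es = ves["epi"] - ves["lv"] - ves["rv"]
            assert wall_es == pytest.approx(wall_ed, rel=0.02)


class TestMassesAndIndices:
    def test_density_product(self):
        m = G.compute_masses({"lv": 100.0, "rv": 0.0})
        assert m["lv_mass"] == pytest.approx(105.0)
        assert m["rv_mass"] == 0.0

    def test_zero_wall_flag(self):
        with pytest.raises(ValueError):
            G.compute_masses({"lv": 0.0, "rv": 0.0})
        m = G.compute_masses({"lv": 0.0, "rv": 0.0}, allow_zero=True)
        assert m == {"lv_mass": 0.0, "rv_mass": 0.0}

    def test_negative_wall_rejected(self):
        with pytest.raises(ValueError):
            G.compute_masses({"lv": -1.0, "rv": 5.0})

    @pytest.mark.parametrize("edv,esv,expected", [
        (100.0, 50.0, 50.0),
        (140.0, 87.0, 100.0 * 53.0 / 140.0),
        (80.0, 80.0, 0.0),
    ])
    def test_ejection_fraction(self, edv, esv, expected):
        assert G.ejection_fraction(edv, esv) == pytest.approx(expected)

    def test_ejection_fraction_rejects_nonpositive_edv(self):
        with pytest.raises(ValueError):
            G.ejection_fraction(0.0, 10.0)

    def test_bsa_indexing(self):
        assert G.index_to_bsa(160.0, 2.0) == 80.0
        assert G.index_to_bsa(0.0, 1.3) == 0.0
        assert G.index_to_bsa(196.0, 1.4) == pytest.approx(140.0)
        with pytest.raises(ValueError):
            G.index_to_bsa(10.0, 0.0)

    def test_imaging_indices_have_ten_features(self, small_cohort):
        co = small_cohort
        idx = G.compute_imaging_indices(co.ed_surfaces[0], co.es_surfaces[0],
                                        co.records[0])
        assert len(idx.as_array()) == 10
        assert len(G.ImagingIndexSet.FIELD_ORDER) == 10

    def test_identical_phases_give_zero_ef(self, small_cohort):
        co = small_cohort
        import dataclasses
        es = dataclasses.replace(co.ed_surfaces[0], phase="ES")
        idx = G.compute_imaging_indices(co.ed_surfaces[0], es, co.records[0])
        assert idx.lv_ef == pytest.approx(0.0, abs=1e-9)
        assert idx.rv_ef == pytest.approx(0.0, abs=1e-9)

    def test_subject_mismatch_rejected(self, small_cohort):
        co = small_cohort
        with pytest.raises(ValueError):
            G.compute_imaging_indices(co.ed_surfaces[0], co.es_surfaces[1],
                                      co.records[0])

    def test_prescribed_ef_recovered_within_2pct(self, clean_pair):
        co = clean_pair
        for i in range(len(co.records)):
            idx = G.compute_imaging_indices(co.ed_surfaces[i], co.es_surfaces[i],
                                            co.records[i])
            t = co.truth[i]
            ef_lv = 100.0 * (1 - t.volumes_es["lv"] / t.volumes_ed["lv"])
            ef_rv = 100.0 * (1 - t.volumes_es["rv"] / t.volumes_ed["rv"])
            assert idx.lv_ef == pytest.approx(ef_lv, abs=2.0)
            assert idx.rv_ef == pytest.approx(ef_rv, abs=2.0)


class TestSubjectRecord:
    def test_invariants_enforced(self):
        kwargs = dict(subject_id="a", group="PVR", sex="M",
                      repair_type="CONDUIT", age_at_repair=1.0, age_at_cmr=10.0,
                      time_after_repair=9.0, height=150.0, weight=40.0,
                      bsa=1.3, symptomatic=True, prvi=25.0, prf=40.0)
        G.SubjectRecord(**kwargs)
        with pytest.raises(ValueError):
            G.SubjectRecord(**{**kwargs, "bsa": 0.0})
        with pytest.raises(ValueError):
            G.SubjectRecord(**{**kwargs, "time_after_repair": -1.0})
        with pytest.raises(ValueError):
            G.SubjectRecord(**{**kwargs, "prf": 130.0})
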