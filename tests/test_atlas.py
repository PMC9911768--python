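"""Alignment, PCA atlas, Z-scores and chi-square mode selection."""

import numpy as np
import pytest
from scipy import optimize, stats as sps

from bivatlas.atlas import (
    ShapeAtlas,
    build_atlas,
    cumulative_variance_cut,
    project_zscores,
    rank_modes_chi2,
    reconstruct_shape,
    rigid_align,
    select_top_modes,
)


def random_rotation(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestRigidAlign:
    def test_exact_recovery_of_known_transform(self, rng):
        pts = rng.normal(size=(40, 3)) * 20
        rot = random_rotation(rng)
        trans = rng.uniform(-30, 30, 3)
        moved = pts @ rot.T + trans
        aligned, tf = rigid_align(moved, pts)
        assert np.abs(aligned - pts).max() < 1e-8
        # recovered transform inverts (R, t)
        assert np.abs(tf.rotation @ rot - np.eye(3)).max() < 1e-8
        assert abs(np.linalg.det(tf.rotation) - 1.0) < 1e-10

    def test_identity_when_reference_equals_points(self, rng):
        pts = rng.normal(size=(25, 3))
        aligned, tf = rigid_align(pts, pts)
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-10
        assert np.abs(tf.translation).max() < 1e-10

    def test_matches_direct_numerical_minimization(self, rng):
        """Closed-form alignment equals brute-force optimization over the
        6 rigid parameters on a noisy instance."""
        pts = rng.normal(size=(30, 3)) * 15
        rot = random_rotation(rng)
        moved = pts @ rot.T + rng.uniform(-10, 10, 3) + rng.normal(0, 1.0, (30, 3))
        aligned, _ = rigid_align(moved, pts)
        closed_form = float(((aligned - pts) ** 2).sum())

        def cost(params):
            w = params[:3]
            t = params[3:]
            theta = np.linalg.norm(w)
            if theta < 1e-12:
                r = np.eye(3)
            else:
                k = w / theta
                kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
                r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx
            return float(((moved @ r.T + t - pts) ** 2).sum())

        best = min(
            optimize.minimize(cost, x0, method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12,
                                       "maxiter": 20000}).fun
            for x0 in (np.zeros(6), rng.normal(size=6) * 0.5))
        assert closed_form <= best + 1e-6

    def test_degenerate_points_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            rigid_align(line, line + 1.0)


def make_planted_dataset(rng, n_subj=20, n_pts=60, n_modes=5, noise=0.0,
                         sds=(8.0, 6.0, 5.0, 4.0, 3.0)):
    """Shapes = base + sum of known orthonormal 3N modes with drawn scores.

    The planted basis is projected out of the base shape's rigid-motion
    subspace first: generalized alignment removes pose, so any rigid
    component of a planted mode would (correctly) not be recoverable.
    """
    base = rng.normal(size=(n_pts, 3)) * 30
    centered = base - base.mean(axis=0)
    rigid = []
    for ax in range(3):
        e = np.zeros((n_pts, 3))
        e[:, ax] = 1.0
        rigid.append(e.ravel())
        omega = np.zeros(3)
        omega[ax] = 1.0
        rigid.append(np.cross(np.broadcast_to(omega, (n_pts, 3)), centered).ravel())
    q_rigid, _ = np.linalg.qr(np.array(rigid).T)
    d = 3 * n_pts
    raw = rng.normal(size=(d, n_modes))
    raw -= q_rigid @ (q_rigid.T @ raw)
    basis = np.linalg.qr(raw)[0].T  # (K, 3N), orthonormal, pose-free
    scores = rng.normal(size=(n_subj, n_modes)) * np.array(sds[:n_modes])
    shapes = base.ravel()[None, :] + scores @ basis
    shapes = shapes + rng.normal(0, noise, shapes.shape)
    return [s.reshape(n_pts, 3) for s in shapes], basis, scores


class TestBuildAtlas:
    def test_mode_count_is_subjects_minus_one(self, rng):
        shapes = [rng.normal(size=(30, 3)) * 10 for _ in range(8)]
        atlas = build_atlas(shapes)
        atlas.validate()
        assert atlas.n_modes == 7
        assert atlas.variance_explained.sum() == pytest.approx(100.0)

    def test_planted_modes_without_noise_carry_all_variance(self, rng):
        shapes, basis, scores = make_planted_dataset(rng, noise=0.0)
        atlas = build_atlas(shapes)
        cum = np.cumsum(atlas.variance_explained)
        assert cum[4] > 99.9

    def test_planted_variances_recovered_and_subspace_aligned(self, rng):
        shapes, basis, scores = make_planted_dataset(rng, n_subj=40, noise=0.05)
        atlas = build_atlas(shapes)
        # recovered leading eigenvalues match the eigenvalues of the planted
        # scores' sample covariance within 10% (finite-sample scores are not
        # exactly uncorrelated, so per-column variances are not the target)
        expect = np.sort(np.linalg.eigvalsh(np.cov(scores.T, ddof=1)))[::-1]
        assert np.allclose(atlas.variances[:5], expect, rtol=0.10)
        # principal angles between planted and recovered subspaces < 5 deg
        m = atlas.modes[:5] @ basis.T
        angles = np.degrees(np.arccos(np.clip(np.linalg.svd(m)[1], 0, 1)))
        assert angles.max() < 5.0

    def test_projection_matches_training_zscores(self, small_cohort):
        atlas = build_atlas(small_cohort.ed_surfaces)
        z = project_zscores(atlas, small_cohort.ed_surfaces[3])
        assert np.abs(z - atlas.zscores[3]).max() < 1e-8

    def test_atlas_invariant_to_rigid_input_transforms(self, rng, small_cohort):
        surfaces = [s.vertices for s in small_cohort.ed_surfaces]
        atlas0 = build_atlas(surfaces)
        moved = []
        for s in surfaces:
            rot = random_rotation(rng)
            moved.append(s @ rot.T + rng.uniform(-20, 20, 3))
        atlas1 = build_atlas(moved)
        # modes may flip or mix within degenerate eigenvalues; Z-scores of
        # matched modes agree up to sign
        agree = np.abs(np.abs(np.diag(
            np.corrcoef(atlas0.zscores.T, atlas1.zscores.T)[
                :atlas0.n_modes, atlas0.n_modes:])) - 1.0)
        assert agree[:5].max() < 1e-6

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            build_atlas([rng.normal(size=(10, 3)) for _ in range(2)])


class TestReconstruction:
    def test_zero_scores_give_mean(self, small_cohort):
        atlas = build_atlas(small_cohort.ed_surfaces)
        rec = reconstruct_shape(atlas, np.zeros(atlas.n_modes))
        assert np.allclose(rec, atlas.mean_shape)

    def test_full_roundtrip(self, small_cohort):
        atlas = build_atlas(small_cohort.ed_surfaces)
        z = atlas.zscores[2]
        rec = reconstruct_shape(atlas, z)
        aligned, _ = rigid_align(small_cohort.ed_surfaces[2].vertices,
                                 atlas.mean_shape.reshape(-1, 3))
        rms = np.sqrt(((rec.reshape(-1, 3) - aligned) ** 2).mean())
        assert rms < 1e-6

    def test_plus_minus_two_sd_average_to_mean(self, small_cohort):
        atlas = build_atlas(small_cohort.ed_surfaces)
        z = np.zeros(atlas.n_modes)
        z[4] = 2.0
        plus = reconstruct_shape(atlas, z)
        minus = reconstruct_shape(atlas, -z)
        assert np.allclose(0.5 * (plus + minus), atlas.mean_shape)
        # and the +2 SD shape projects back to Z = 2 at mode 4
        zback = project_zscores(atlas, plus.reshape(-1, 3))
        assert zback[4] == pytest.approx(2.0, abs=1e-6)

    def test_out_of_range_mode_count(self, small_cohort):
        atlas = build_atlas(small_cohort.ed_surfaces)
        with pytest.raises(ValueError):
            reconstruct_shape(atlas, np.zeros(3), n_modes=atlas.n_modes + 1)


def synthetic_atlas(variances):
    variances = np.asarray(variances, dtype=float)
    m = len(variances)
    rng = np.random.default_rng(0)
    modes = np.linalg.qr(rng.normal(size=(30, m)))[0].T
    z = rng.normal(size=(12, m))
    z = (z - z.mean(0)) / z.std(0, ddof=1)
    return ShapeAtlas(mean_shape=np.zeros(30), modes=modes,
                      variances=variances, zscores=z,
                      subject_ids=[f"s{i}" for i in range(12)])


class TestModeSelection:
    def test_cumulative_cut_arithmetic(self):
        atlas = synthetic_atlas([60.0, 30.0, 6.0, 4.0])
        assert cumulative_variance_cut(atlas, 95.0) == [0, 1, 2]
        assert cumulative_variance_cut(atlas, 100.0) == [0, 1, 2, 3]

    def test_cumulative_cut_matches_prefix_scan(self, rng):
        for _ in range(20):
            v = np.sort(rng.uniform(0.5, 40.0, size=rng.integers(3, 12)))[::-1]
            atlas = synthetic_atlas(v)
            got = cumulative_variance_cut(atlas, 95.0)
            pct = 100.0 * v / v.sum()
            expect = next(i + 1 for i in range(len(v))
                          if pct[:i + 1].sum() > 95.0)
            assert got == list(range(expect))

    def test_chi2_ranking_matches_textbook_oracle(self, rng):
        """Quantile binning + Pearson chi-square replicated independently
        with pandas crosstab and scipy.chi2_contingency."""
        import pandas as pd
        from scipy.stats import chi2_contingency

        for trial in range(25):
            z = rng.normal(size=(60, 6))
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            ranking = rank_modes_chi2(z, y, list(range(6)), n_bins=5)
            for i in range(6):
                edges = np.unique(np.quantile(z[:, i], np.linspace(0, 1, 6)))
                bins = np.clip(np.searchsorted(edges, z[:, i], side="right") - 1,
                               0, len(edges) - 2)
                table = pd.crosstab(bins, y).to_numpy()
                p = chi2_contingency(table, correction=False).pvalue
                assert ranking.importance[i] == pytest.approx(-np.log10(p),
                                                              abs=1e-10)

    def test_planted_shift_ranked_first(self):
        """A mode with a 1.5-SD group mean shift beats 29 noise modes in
        at least 95 of 100 replicates at the study's sample sizes."""
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            y = np.array([1] * 48 + [0] * 36)
            z = rng.normal(size=(84, 30))
            z[:, 7] += 1.5 * y
            ranking = rank_modes_chi2(z, y, list(range(30)))
            wins += ranking.rank[0] == 7
        assert wins >= 95

    def test_permuted_labels_give_uniformish_pvalues(self):
        """Under label permutation the chi-square p-values should look
        uniform (coarse Kolmogorov-Smirnov sanity check)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(60):
            z = rng.normal(size=(84, 4))
            y = rng.permutation([1] * 48 + [0] * 36)
            r = rank_modes_chi2(z, y, [0, 1, 2, 3])
            pvals.extend(10.0 ** (-r.importance))
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3

    def test_identical_columns_tie_broken_by_index(self, rng):
        z = rng.normal(size=(50, 3))
        z[:, 2] = z[:, 0]
        y = rng.integers(0, 2, 50)
        r = rank_modes_chi2(z, y, [0, 1, 2])
        assert r.importance[0] == pytest.approx(r.importance[2])
        assert r.rank.index(0) < r.rank.index(2)

    def test_constant_mode_warns_and_scores_zero(self, rng):
        z = rng.normal(size=(40, 2))
        z[:, 1] = 3.14
        y = rng.integers(0, 2, 40)
        with pytest.warns(RuntimeWarning):
            r = rank_modes_chi2(z, y, [0, 1])
        assert r.importance[1] == 0.0

    def test_top_k_selection_matches_sort(self, rng):
        z = rng.normal(size=(80, 30))
        y = rng.integers(0, 2, 80)
        r = rank_modes_chi2(z, y, list(range(30)))
        sel = select_top_modes(r, 10)
        order = np.argsort([-r.importance[i] for i in range(30)], kind="stable")
        assert sel == [int(i) for i in order[:10]]
        assert select_top_modes(r, 30) == r.rank
        assert len(select_top_modes(r, 1)) == 1
        with pytest.raises(ValueError):
            select_top_modes(r, 31)
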