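"""Statistical shape atlas: alignment, PCA, Z-scores, mode selection.

The atlas condenses corresponded biventricular end-diastolic surfaces into
orthogonal shape modes.  Subjects are rigidly aligned to an iteratively
re-estimated population mean (generalized alignment, no scaling — heart
size is biologically meaningful and is instead handled as a regression
covariate downstream), PCA is applied to the stacked 3N coordinate vectors,
and each subject's projection onto a mode divided by the mode's population
SD is its morphometric Z-score.

For the feature subset used in classification, modes inside the 95%
cumulative-variance cut are ranked by a Pearson chi-square test of
quantile-binned Z-scores against the binary intervention label, and the
top-k (k = 10, matching the number of standard imaging indices) are
retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .geometry import BiventricularSurface

__all__ = [
    "ShapeAtlas",
    "ModeRanking",
    "RigidTransform",
    "rigid_align",
    "build_atlas",
    "project_zscores",
    "reconstruct_shape",
    "cumulative_variance_cut",
    "rank_modes_chi2",
    "select_top_modes",
]

_DEGENERACY_RTOL = 1e-10  # eigenvalue threshold relative to the largest


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, det(rotation) = +1."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class ShapeAtlas:
    """Mean shape, orthonormal modes, per-mode variance and training Z-scores."""

    mean_shape: np.ndarray          # (3N,) mm
    modes: np.ndarray               # (M, 3N), rows orthonormal
    variances: np.ndarray           # (M,) mm^2, descending
    zscores: np.ndarray             # (S, M)
    subject_ids: List[str]
    converged: bool = True
    n_iterations: int = 0

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    @property
    def variance_explained(self) -> np.ndarray:
        """Percent of total shape variance per mode (sums to 100)."""
        return 100.0 * self.variances / self.variances.sum()

    def validate(self) -> None:
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(self.n_modes), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances are not non-increasing")
        sd = self.zscores.std(axis=0, ddof=1)
        if not np.allclose(sd, 1.0, atol=1e-6):
            raise ValueError("Z-score columns do not have unit sample SD")


@dataclass
class ModeRanking:
    """Chi-square predictive ranking of candidate shape modes."""

    candidate_modes: List[int]
    importance: np.ndarray  # -log10(p), aligned with candidate_modes
    rank: List[int]         # candidates ordered by descending importance
    selected: List[int] = field(default_factory=list)


def _as_points(surface_or_points: Union[BiventricularSurface, np.ndarray]) -> np.ndarray:
    if isinstance(surface_or_points, BiventricularSurface):
        return surface_or_points.vertices
    return np.asarray(surface_or_points, dtype=float)


def rigid_align(points: np.ndarray, reference: np.ndarray
                ) -> Tuple[np.ndarray, RigidTransform]:
    """Least-squares rigid registration of corresponded point sets.

    Finds the rotation (det +1, no scaling or reflection) and translation
    minimizing the mean squared distance between corresponded points
    (Kabsch/Umeyama); returns the aligned points and the transform.
    """
    p = np.asarray(points, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("points and reference must be matching N x 3 arrays")
    pc = p - p.mean(axis=0)
    rc = r - r.mean(axis=0)
    h = pc.T @ rc
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate point set: points are collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = r.mean(axis=0) - rot @ p.mean(axis=0)
    tf = RigidTransform(rotation=rot, translation=trans)
    return tf.apply(p), tf


def build_atlas(cohort_ed_surfaces: Sequence[Union[BiventricularSurface, np.ndarray]],
                max_iter: int = 20, tol: float = 1e-6,
                subject_ids: Optional[Sequence[str]] = None) -> ShapeAtlas:
    """Generalized rigid alignment followed by PCA on stacked coordinates.

    All subjects are aligned to the current mean shape, the mean is
    recomputed, and the loop repeats until the mean moves less than ``tol``
    mm per vertex on average (or ``max_iter`` is reached, which is recorded
    as non-convergence but still yields an atlas from the last iterate).
    The first subject seeds the initial reference.
    """
    pts = [_as_points(s) for s in cohort_ed_surfaces]
    n_subj = len(pts)
    if n_subj < 3:
        raise ValueError("need at least 3 subjects to build an atlas")
    shape0 = pts[0].shape
    if any(q.shape != shape0 for q in pts):
        raise ValueError("surfaces are not in vertex correspondence")
    if subject_ids is None:
        if all(isinstance(s, BiventricularSurface) for s in cohort_ed_surfaces):
            subject_ids = [s.subject_id for s in cohort_ed_surfaces]
        else:
            subject_ids = [f"s{i:03d}" for i in range(n_subj)]

    ref = pts[0] - pts[0].mean(axis=0)
    aligned = list(pts)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = [rigid_align(q, ref)[0] for q in pts]
        new_mean = np.mean(aligned, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = float(np.linalg.norm(new_mean - ref, axis=1).mean())
        ref = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"generalized alignment did not converge in {max_iter} "
                      "iterations; using last iterate", RuntimeWarning)
    # final pass against the converged mean
    aligned = [rigid_align(q, ref)[0] for q in pts]

    x = np.stack([a.ravel() for a in aligned])  # (S, 3N)
    mean_shape = x.mean(axis=0)
    xc = x - mean_shape
    # PCA in subject space: eigen-decompose the S x S Gram matrix
    gram = xc @ xc.T / (n_subj - 1)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    keep = evals > _DEGENERACY_RTOL * evals[0]
    evals = evals[keep]
    evecs = evecs[:, keep]
    modes = (xc.T @ evecs) / np.sqrt(evals * (n_subj - 1))  # (3N, M) unit cols
    modes = modes.T
    # sign convention: largest-magnitude coordinate of each mode is positive
    flip = modes[np.arange(modes.shape[0]), np.argmax(np.abs(modes), axis=1)] < 0
    modes[flip] *= -1.0
    scores = xc @ modes.T
    zscores = scores / np.sqrt(evals)[None, :]
    atlas = ShapeAtlas(mean_shape=mean_shape, modes=modes, variances=evals,
                       zscores=zscores, subject_ids=list(subject_ids),
                       converged=converged, n_iterations=it)
    return atlas


def project_zscores(atlas: ShapeAtlas,
                    surface: Union[BiventricularSurface, np.ndarray]) -> np.ndarray:
    """Morphometric Z-scores of a surface against the atlas.

    The surface is rigidly aligned to the atlas mean first, so the result is
    invariant to the pose in which the surface is supplied.
    """
    pts = _as_points(surface)
    mean_pts = atlas.mean_shape.reshape(-1, 3)
    if pts.shape != mean_pts.shape:
        raise ValueError("surface vertex count does not match the atlas")
    aligned, _ = rigid_align(pts, mean_pts)
    centered = aligned.ravel() - atlas.mean_shape
    return (centered @ atlas.modes.T) / np.sqrt(atlas.variances)


def reconstruct_shape(atlas: ShapeAtlas, zscores: np.ndarray,
                      n_modes: Optional[int] = None) -> np.ndarray:
    """Mean shape plus Z-score-weighted modes (3N vector).

    ``reconstruct_shape(atlas, z, m)`` = mean + sum over the first m modes of
    z_k * sqrt(variance_k) * mode_k.
    """
    z = np.asarray(zscores, dtype=float)
    if n_modes is None:
        n_modes = z.shape[-1]
    if not (0 <= n_modes <= atlas.n_modes) or z.shape[-1] < n_modes:
        raise ValueError("n_modes out of range")
    amp = z[:n_modes] * np.sqrt(atlas.variances[:n_modes])
    return atlas.mean_shape + amp @ atlas.modes[:n_modes]


def cumulative_variance_cut(atlas: ShapeAtlas, threshold: float = 95.0) -> List[int]:
    """Smallest prefix of modes explaining more than ``threshold`` percent."""
    cum = np.cumsum(atlas.variance_explained)
    n = int(np.searchsorted(cum, threshold, side="right")) + 1
    return list(range(min(n, atlas.n_modes)))


def rank_modes_chi2(zscores: np.ndarray, labels: np.ndarray,
                    candidates: Sequence[int], n_bins: int = 10) -> ModeRanking:
    """Rank candidate modes for predicting a binary label by chi-square.

    Each candidate's Z-scores are discretized into ``n_bins`` quantile bins
    (empty bins merged by unique quantile edges); the Pearson chi-square
    statistic of the bin-by-label contingency table gives a p-value, and
    importance = -log10(p).  Ties rank the lower mode index first.
    """
    z = np.asarray(zscores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate modes")
    importance = np.zeros(len(candidates))
    for i, m in enumerate(candidates):
        col = z[:, m]
        if np.ptp(col) < 1e-12:
            warnings.warn(f"mode {m} has constant scores; importance set to 0",
                          RuntimeWarning)
            importance[i] = 0.0
            continue
        edges = np.unique(np.quantile(col, np.linspace(0.0, 1.0, n_bins + 1)))
        bins = np.clip(np.searchsorted(edges, col, side="right") - 1,
                       0, len(edges) - 2)
        table = np.zeros((len(edges) - 1, 2))
        classes = np.unique(y)
        for b in range(table.shape[0]):
            for c, cls in enumerate(classes):
                table[b, c] = np.sum((bins == b) & (y == cls))
        table = table[table.sum(axis=1) > 0]  # merge away empty bins
        if table.shape[0] < 2:
            importance[i] = 0.0
            continue
        p = _pearson_chi2_p(table)
        importance[i] = -np.log10(max(p, 1e-300))
    # descending importance; ties broken by lower mode index
    order = sorted(range(len(candidates)),
                   key=lambda i: (-importance[i], candidates[i]))
    rank = [candidates[i] for i in order]
    return ModeRanking(candidate_modes=candidates, importance=importance, rank=rank)


def _pearson_chi2_p(table: np.ndarray) -> float:
    observed = np.asarray(table, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    stat = float(((observed - expected) ** 2 / expected).sum())
    dof = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    return float(sps.chi2.sf(stat, dof))


def select_top_modes(ranking: ModeRanking, k: int = 10) -> List[int]:
    """The k highest-importance candidate modes."""
    if k > len(ranking.rank):
        raise ValueError(f"k={k} exceeds the {len(ranking.rank)} candidates")
    selected = ranking.rank[:k]
    ranking.selected = selected
    return selected
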