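"""Unsupervised two-cluster discrimination of PVR status.

K-means with the cosine distance (1 - cosine similarity) splits the cohort
into two clusters on a small z-normalized feature set; the cosine metric
deliberately ignores the absolute sizes of measurements and compares only
their relative pattern.  Each cluster predicts the class of its dominant
cohort, giving a 2x2 matching matrix whose quality is summarized by the
Matthews correlation coefficient (MCC), sensitivity and specificity.

A deterministic threshold-criteria classifier (RV EDVi / RV ESVi / RV EF /
LV EF cut-offs, relaxed for symptomatic patients) provides the guideline
comparator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import ImagingIndexSet

__all__ = [
    "MatchingMatrix",
    "CriteriaThresholds",
    "kmeans_cosine",
    "match_clusters",
    "mcc",
    "sensitivity_specificity",
    "criteria_classify",
]


@dataclass
class MatchingMatrix:
    """2x2 cluster-prediction vs cohort confusion counts (positive = PVR)."""

    tp: int
    fn: int
    fp: int
    tn: int
    degenerate: bool = False  # both clusters predicted the same class

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def validate(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    if (norms < 1e-12).any():
        raise ValueError("zero-norm feature row: cosine distance undefined")
    return x / norms[:, None]


def _inertia(xn: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float((1.0 - np.einsum("ij,ij->i", xn, centroids[labels])).sum())


def kmeans_cosine(features: np.ndarray, k: int = 2, n_restarts: int = 50,
                  seed: Optional[int] = None,
                  max_iter: int = 100) -> np.ndarray:
    """Lloyd's k-means under cosine distance; best of ``n_restarts``.

    Rows are normalized to the unit sphere; a centroid is the renormalized
    mean of its members' unit vectors, which maximizes the within-cluster
    cosine similarity.  An emptied cluster is reseeded at the point farthest
    from its nearest centroid.  Deterministic given the seed.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least two feature columns")
    if seed is None:
        raise ValueError("seed is mandatory for reproducible clustering")
    xn = _normalize_rows(x)
    n = xn.shape[0]
    rng = np.random.default_rng(seed)
    # for small cohorts, sweep every point pair as an initial centroid pair
    # (deterministic and in practice recovers the global optimum); larger
    # cohorts use random restarts
    if k == 2 and n <= 16:
        inits = [np.array(pair) for pair in itertools.combinations(range(n), 2)]
    else:
        inits = [rng.choice(n, size=k, replace=False) for _ in range(n_restarts)]
    best_labels: Optional[np.ndarray] = None
    best_inertia = np.inf
    for idx in inits:
        centroids = xn[idx].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            sim = xn @ centroids.T
            new_labels = np.argmax(sim, axis=1)
            for c in range(k):
                if not (new_labels == c).any():
                    far = int(np.argmin(np.max(sim, axis=1)))
                    new_labels[far] = c
            if (new_labels == labels).all() and _ > 0:
                break
            labels = new_labels
            for c in range(k):
                m = xn[labels == c].mean(axis=0)
                nm = np.linalg.norm(m)
                centroids[c] = m / nm if nm > 1e-12 else xn[rng.integers(n)]
        inertia = _inertia(xn, labels, centroids)
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            best_labels = labels.copy()
    assert best_labels is not None
    return best_labels


def match_clusters(cluster_labels: np.ndarray, true_groups: np.ndarray
                   ) -> MatchingMatrix:
    """Matching matrix with each cluster predicting its dominant cohort.

    ``true_groups`` is boolean-like with True = PVR (positive class).  A
    majority tie inside a cluster is resolved toward the assignment that
    maximizes the MCC (then toward PVR).  If both clusters share the same
    majority the prediction is degenerate and flagged.
    """
    c = np.asarray(cluster_labels)
    y = np.asarray(true_groups).astype(bool)
    ids = np.unique(c)
    if len(ids) != 2:
        raise ValueError("expected exactly 2 clusters, found "
                         f"{len(ids)} (empty cluster?)")

    def matrix_for(assign: Tuple[bool, bool]) -> MatchingMatrix:
        pred = np.where(c == ids[0], assign[0], assign[1])
        return MatchingMatrix(
            tp=int(np.sum(pred & y)), fn=int(np.sum(~pred & y)),
            fp=int(np.sum(pred & ~y)), tn=int(np.sum(~pred & ~y)),
            degenerate=(assign[0] == assign[1]))

    choices = []
    for cid in ids:
        n_pvr = int(np.sum(y[c == cid]))
        n_other = int(np.sum(~y[c == cid]))
        if n_pvr > n_other:
            choices.append([True])
        elif n_pvr < n_other:
            choices.append([False])
        else:
            choices.append([True, False])  # tie: decide by MCC below
    candidates = [matrix_for((a, b)) for a in choices[0] for b in choices[1]]
    # ties resolved toward maximal MCC, then toward predicting PVR
    return max(candidates, key=lambda m: (mcc(m), m.tp + m.fp))


def mcc(m: MatchingMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    m.validate()
    denom = ((m.tp + m.fp) * (m.tp + m.fn) * (m.tn + m.fp) * (m.tn + m.fn))
    if denom == 0:
        return 0.0
    return (m.tp * m.tn - m.fp * m.fn) / math.sqrt(denom)


def sensitivity_specificity(m: MatchingMatrix) -> Dict[str, float]:
    """tp/(tp+fn) and tn/(tn+fp); NaN flags an undefined ratio."""
    m.validate()
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else float("nan")
    spec = m.tn / (m.tn + m.fp) if (m.tn + m.fp) else float("nan")
    return {"sensitivity": sens, "specificity": spec}


@dataclass
class CriteriaThresholds:
    """Guideline-style thresholds for PVR referral.

    The volume cut-offs (RV EDVi > 160 mL/m^2, RV ESVi > 80 mL/m^2) are the
    commonly cited indication thresholds; the EF thresholds and the
    criteria-count rule (symptomatic patients need fewer positive criteria)
    are package defaults, configurable by the user.
    """

    rv_edvi_gt: float = 160.0  # mL/m^2
    rv_esvi_gt: float = 80.0   # mL/m^2
    rv_ef_lt: float = 47.0     # %
    lv_ef_lt: float = 55.0     # %
    n_required_asymptomatic: int = 2
    n_required_symptomatic: int = 1

    def __post_init__(self) -> None:
        if self.n_required_symptomatic >= self.n_required_asymptomatic:
            raise ValueError("symptomatic patients must require fewer criteria")


def criteria_classify(indices: ImagingIndexSet, symptomatic: bool,
                      thresholds: Optional[CriteriaThresholds] = None) -> bool:
    """Deterministic threshold prediction: True = refer for PVR."""
    t = thresholds or CriteriaThresholds()
    for name in ("rv_edvi", "rv_esvi", "rv_ef", "lv_ef"):
        if getattr(indices, name) is None or not np.isfinite(getattr(indices, name)):
            raise ValueError(f"missing imaging index {name}")
    n_met = int(indices.rv_edvi > t.rv_edvi_gt) \
        + int(indices.rv_esvi > t.rv_esvi_gt) \
        + int(indices.rv_ef < t.rv_ef_lt) \
        + int(indices.lv_ef < t.lv_ef_lt)
    need = t.n_required_symptomatic if symptomatic else t.n_required_asymptomatic
    return n_met >= need
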