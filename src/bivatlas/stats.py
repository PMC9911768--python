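"""Cohort statistics: group comparisons, confounder-adjusted associations
with PVR status, and univariate strain-feature regressions.

Group summaries follow the usual reporting convention: Shapiro-Wilk decides
between the unpaired two-sample t-test and the Wilcoxon rank-sum test for
continuous variables; categorical tables use Pearson's chi-square without
continuity correction.

The multivariate association model is ordinary least squares with the
response variable being one imaging index or one shape-mode Z-score and the
predictors being PVR status, sex and repair type (dummy-coded against
No-PVR / female / transannular-patch references), time after repair, and —
for shape-mode responses only — BSA (imaging indices are already indexed to
BSA).  All continuous variables, including the response, are z-normalized
before fitting, and the reported association is the two-sided p-value of
the PVR coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .geometry import RepairType, Sex, SubjectRecord

__all__ = [
    "AssociationResult",
    "normality_test",
    "compare_groups",
    "chi2_contingency_test",
    "pvr_association",
    "strain_feature_regression",
]

ALPHA_NORMALITY = 0.05


@dataclass
class AssociationResult:
    response_name: str
    pvr_coefficient: float  # standardized units
    pvr_p_value: float
    table: pd.DataFrame  # estimate, SE, t, p per predictor
    n_used: int
    design_rank: int


def normality_test(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality test")
    return float(sps.shapiro(x).pvalue)


def compare_groups(values: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    """Two-group comparison with a normality gate.

    Both groups passing Shapiro-Wilk at 0.05 selects the unpaired two-sample
    t-test, otherwise the Wilcoxon rank-sum test; returns the test used and
    its two-sided p-value.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    a = x[y == groups[0]]
    b = x[y == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    try:
        normal = (normality_test(a) > ALPHA_NORMALITY
                  and normality_test(b) > ALPHA_NORMALITY)
    except ValueError:
        normal = False
    if normal:
        stat, p = sps.ttest_ind(a, b)
        return {"test_name": "t-test", "p": float(p), "statistic": float(stat)}
    stat, p = sps.ranksums(a, b)
    return {"test_name": "rank-sum", "p": float(p), "statistic": float(stat)}


def chi2_contingency_test(table: np.ndarray) -> Dict[str, float]:
    """Pearson chi-square for an R x C count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a non-negative 2-D count array")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("table has a zero marginal row or column")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return {"statistic": float(stat), "df": int(dof), "p": float(p)}


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-normalize a constant variable")
    return (x - x.mean()) / sd


def pvr_association(response: np.ndarray, records: Sequence[SubjectRecord],
                    response_kind: str, response_name: str = "response",
                    include_bsa: bool | None = None) -> AssociationResult:
    """Confounder-adjusted OLS association of one response with PVR status.

    ``response_kind`` is "IMAGING_INDEX" or "SHAPE_MODE"; BSA enters the
    model only for shape modes (imaging indices are already BSA-indexed)
    unless overridden with ``include_bsa``.
    """
    if response_kind not in ("IMAGING_INDEX", "SHAPE_MODE"):
        raise ValueError("response_kind must be IMAGING_INDEX or SHAPE_MODE")
    if include_bsa is None:
        include_bsa = response_kind == "SHAPE_MODE"
    y = _zscore(np.asarray(response, dtype=float))
    n = y.size
    if n != len(records):
        raise ValueError("response length does not match records")

    cols: Dict[str, np.ndarray] = {
        "pvr": np.array([r.group == "PVR" for r in records], dtype=float),
        "sex_m": np.array([r.sex == Sex.M.value for r in records], dtype=float),
        "repair_valve_sparing": np.array(
            [r.repair_type == RepairType.VALVE_SPARING.value for r in records],
            dtype=float),
        "repair_conduit": np.array(
            [r.repair_type == RepairType.CONDUIT.value for r in records],
            dtype=float),
        "time_after_repair": _zscore([r.time_after_repair for r in records]),
    }
    if include_bsa:
        cols["bsa"] = _zscore([r.bsa for r in records])
    x = pd.DataFrame(cols)
    # drop dummy columns that are constant in this cohort (absent level)
    for c in ("repair_valve_sparing", "repair_conduit", "sex_m"):
        if x[c].nunique() == 1:
            x = x.drop(columns=c)
    if n <= x.shape[1] + 2:
        raise ValueError("too few subjects for the number of predictors")
    design = sm.add_constant(x)
    rank = int(np.linalg.matrix_rank(design.to_numpy()))
    if rank < design.shape[1]:
        corr = design.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design: columns {worst} are aliased")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    return AssociationResult(
        response_name=response_name,
        pvr_coefficient=float(fit.params["pvr"]),
        pvr_p_value=float(fit.pvalues["pvr"]),
        table=table,
        n_used=n,
        design_rank=rank,
    )


def strain_feature_regression(strain: np.ndarray, feature: np.ndarray
                              ) -> Dict[str, float]:
    """Simple linear regression of a strain on one feature: slope, Pearson
    r and the two-sided slope p-value."""
    y = np.asarray(strain, dtype=float)
    x = np.asarray(feature, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need matching vectors with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant feature")
    res = sps.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue)}
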