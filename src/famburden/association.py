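"""Score-versus-status inference: logistic odds ratios, Bonferroni
adjustment, group comparison grids, within-family trends, and allele
frequency correlation.

Odds ratios come from a plain maximum-likelihood logistic regression of
case status on one score (no covariates; relatedness is knowingly ignored
as mixed models are not identifiable at these family sample sizes), with
Wald 95% confidence intervals and Bonferroni adjustment across the
comparisons of each score type.  When the predictor is a Z-normalized
score, the OR is per standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "fit_logistic_or",
    "bonferroni_adjust",
    "compare_groups",
    "within_family_trend",
    "freq_correlation",
]

GROUPS = [
    "familial_case",
    "unaffected_relative",
    "sporadic_case",
    "control_family",
    "population_control",
]


@dataclass
class AssociationResult:
    comparison: str
    score_type: str
    beta: float
    se: float
    odds_ratio: float
    ci95: Tuple[float, float]
    p_raw: float
    p_adjusted: Optional[float]
    n_case: int
    n_control: int
    separated: bool = False


def fit_logistic_or(
    scores: Sequence[float],
    labels: Sequence[int],
    comparison: str = "",
    score_type: str = "",
) -> AssociationResult:
    """Logistic regression of a binary label on one score.

    Newton-type ML fit (gradient tolerance 1e-8) with Wald SE from the
    observed information.  Complete separation returns a flagged result
    with an infinite-OR sentinel rather than raising.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(scores, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one case and one control")
    if np.var(x) == 0:
        raise ValueError("score variance is zero")
    X = sm.add_constant(x)
    n_case, n_control = int(y.sum()), int(y.size - y.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100,
                                     disp=False)
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            separated = not np.isfinite(se) or se > 1e4 or abs(beta) > 50
        except Exception:  # perfect separation or non-convergence
            separated = True
            beta, se = np.nan, np.nan
    if separated:
        logger.warning("complete separation in %s/%s; OR reported as inf",
                       comparison, score_type)
        sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
        return AssociationResult(
            comparison, score_type, beta=np.inf * sign, se=np.inf,
            odds_ratio=np.inf if sign > 0 else 0.0, ci95=(0.0, np.inf),
            p_raw=np.nan, p_adjusted=None, n_case=n_case,
            n_control=n_control, separated=True,
        )
    or_ = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        comparison, score_type, beta=beta, se=se, odds_ratio=or_, ci95=ci,
        p_raw=float(p), p_adjusted=None, n_case=n_case, n_control=n_control,
    )


def bonferroni_adjust(
    p_values: Sequence[float], m: Optional[int] = None
) -> List[float]:
    """p_adj = min(1, m * p); ``m`` defaults to the number of p-values."""
    p = np.asarray(p_values, dtype=float)
    finite = p[np.isfinite(p)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mm = len(p) if m is None else int(m)
    if mm < 1:
        raise ValueError("m must be >= 1")
    return [float(min(1.0, mm * v)) if np.isfinite(v) else np.nan for v in p]


def compare_groups(
    score_table: pd.DataFrame,
    comparisons: Sequence[Tuple[str, str]],
    score_types: Sequence[str] = ("prs_z", "weighted_sum_score"),
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Pairwise group comparisons, one logistic fit per (comparison, score).

    ``score_table`` needs a ``group`` column plus one column per score
    type; in each comparison the first group is the case.  Bonferroni m
    defaults to the number of non-skipped comparisons within each score
    type.  Returns a tidy report table.
    """
    if "group" not in score_table.columns:
        raise ValueError("score table lacks a 'group' column")
    rows: List[AssociationResult] = []
    for st in score_types:
        if st not in score_table.columns:
            raise ValueError(f"score table lacks score column {st!r}")
        fits: List[AssociationResult] = []
        for ga, gb in comparisons:
            a = score_table.loc[score_table["group"] == ga, st].dropna()
            b = score_table.loc[score_table["group"] == gb, st].dropna()
            if a.empty or b.empty:
                logger.warning("comparison %s vs %s skipped (empty group)", ga, gb)
                continue
            x = np.concatenate([a.to_numpy(), b.to_numpy()])
            y = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
            fits.append(fit_logistic_or(x, y, f"{ga}_vs_{gb}", st))
        padj = bonferroni_adjust([f.p_raw for f in fits], m)
        for f, pa in zip(fits, padj):
            f.p_adjusted = pa
        rows.extend(fits)
    return pd.DataFrame(
        [
            {
                "score_type": r.score_type,
                "comparison": r.comparison,
                "odds_ratio": r.odds_ratio,
                "ci_lower": r.ci95[0],
                "ci_upper": r.ci95[1],
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "separated": r.separated,
            }
            for r in rows
        ]
    )


def within_family_trend(
    score_table: pd.DataFrame,
    weighted_col: str = "weighted_sum_score",
    prs_col: str = "prs",
) -> Tuple[pd.DataFrame, int, List[str]]:
    """Affected-vs-unaffected score trend within each family.

    A family is trend-positive when the affected members' mean exceeds the
    unaffected members' mean *strictly* on both the weighted sum score and
    the PRS.  Families without both an affected and an unaffected scored
    member are reported as not comparable.  Returns (per-family summary,
    trend-positive count, non-comparable family ids).
    """
    for col in ("family_id", "status", weighted_col, prs_col):
        if col not in score_table.columns:
            raise ValueError(f"score table lacks column {col!r}")
    rows = []
    not_comparable: List[str] = []
    for fam, sub in score_table.groupby("family_id", sort=True):
        aff = sub[sub["status"] == "affected"]
        un = sub[sub["status"] == "unaffected"]
        if aff.empty or un.empty:
            not_comparable.append(str(fam))
            continue
        mw_a, mw_u = aff[weighted_col].mean(), un[weighted_col].mean()
        mp_a, mp_u = aff[prs_col].mean(), un[prs_col].mean()
        rows.append(
            {
                "family_id": fam,
                "n_affected": len(aff),
                "n_unaffected": len(un),
                "weighted_mean_affected": mw_a,
                "weighted_mean_unaffected": mw_u,
                "prs_mean_affected": mp_a,
                "prs_mean_unaffected": mp_u,
                "trend_positive": bool(mw_a > mw_u and mp_a > mp_u),
            }
        )
    summary = pd.DataFrame(rows)
    count = int(summary["trend_positive"].sum()) if len(summary) else 0
    return summary, count, not_comparable


def freq_correlation(
    freqs_a: Sequence[float], freqs_b: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation (r, r^2) between two allele-frequency vectors."""
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance in a frequency vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r
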