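"""Nonparametric group statistics across the ROI atlas.

The battery mirrors a standard MEG ROI analysis: for each spectral metric
and each behavioral contrast (low vs high IAP, A vs P type), a two-sided
Mann-Whitney U test per ROI, Benjamini-Hochberg FDR correction across the
16-ROI family (families are never merged across metrics or contrasts),
and a pooled-SD Cohen's d reported as a magnitude. Spearman correlations
relate continuous behavioral scores (IAP score, delta RT) to per-ROI
metrics. A summary-statistic pooled two-sample t test is included for
behavioral contrasts where only group means/SDs/ns are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from painattn.atlas import roi_network

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "total_alpha_power",
    "total_theta_power",
    "paf_speed",
    "paf_power",
)

EXACT_PAIR_LIMIT = 400  # exact MWU enumeration up to n1*n2 = 400, ties absent


class EmptyInputError(ValueError):
    pass


class InsufficientGroupError(ValueError):
    """A contrast group has fewer than 2 usable subjects."""


class DegenerateSamplesError(ValueError):
    pass


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is the pair-count statistic for the first sample (pairs with
    x_i > y_j, ties counted 1/2). The p value is exact when the samples are
    tie-free and n1*n2 <= 400, else the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if not has_ties and x.size * y.size <= EXACT_PAIR_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving.

    The caller defines the family; here it is always the set of ROIs for
    one metric and one contrast.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise EmptyInputError("no p values")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Pooled-SD Cohen's d, reported as a magnitude.

    pooled SD^2 = [(n1-1)s1^2 + (n2-1)s2^2] / (n1 + n2 - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientGroupError("need n >= 2 per group for Cohen's d")
    s1 = np.var(x, ddof=1)
    s2 = np.var(y, ddof=1)
    pooled = ((x.size - 1) * s1 + (y.size - 1) * s2) / (x.size + y.size - 2)
    if pooled == 0:
        raise DegenerateSamplesError("zero pooled variance")
    return float(abs(np.mean(x) - np.mean(y)) / math.sqrt(pooled))


def spearman_corr(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise DegenerateSamplesError("constant input; correlation undefined")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Student's pooled-variance two-sample t from summary statistics.

    Returns (t, two-sided p) with df = n1 + n2 - 2. The summary-statistic
    form makes printed group summaries directly checkable.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("SDs must be nonnegative and not both zero")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(pooled_var * (1 / n1 + 1 / n2))
    t = (mean1 - mean2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass(frozen=True)
class GroupComparisonRow:
    roi: str
    network: str
    metric: str
    u_statistic: float
    p_uncorrected: float
    p_fdr: float
    cohen_d: float
    n_group1: int
    n_group2: int
    significant: bool


_CONTRAST_COLUMNS = {
    "iap": ("iap_group", ("low", "high")),
    "ap": ("ap_type", ("A", "P")),
}


def _split_groups(
    metrics_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    contrast: str,
) -> tuple[pd.DataFrame, tuple[str, str]]:
    if contrast not in _CONTRAST_COLUMNS:
        raise ValueError(f"unknown contrast {contrast!r}; expected iap or ap")
    column, labels = _CONTRAST_COLUMNS[contrast]
    pheno = phenotypes[["subject_id", column]].copy()
    merged = metrics_table.merge(pheno, on="subject_id", how="left")
    if merged[column].isna().any():
        missing = sorted(merged.loc[merged[column].isna(), "subject_id"].unique())
        raise ValueError(f"subjects missing a phenotype label: {missing}")
    n_boundary = (merged[column] == "boundary").sum()
    if n_boundary:
        logger.warning(
            "excluding %d boundary-labelled rows from the %s contrast",
            int(n_boundary),
            contrast,
        )
        merged = merged[merged[column] != "boundary"]
    merged = merged.rename(columns={column: "group_label"})
    return merged, labels


def run_group_comparison(
    metrics_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    contrast: str,
    metric: str,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI Mann-Whitney contrast of one metric, BH-corrected across ROIs.

    ``metrics_table`` is long-format (subject_id, roi, <metric columns>);
    ``phenotypes`` carries iap_group / ap_type labels. Boundary subjects are
    excluded (logged). Returns one row per ROI with U, raw and adjusted p,
    Cohen's d magnitude, group sizes, and a significance flag at
    ``p_fdr < fdr_threshold``.
    """
    if metric not in metrics_table.columns:
        raise ValueError(f"metric {metric!r} not in metrics table")
    merged, labels = _split_groups(metrics_table, phenotypes, contrast)
    rois = list(dict.fromkeys(metrics_table["roi"]))
    rows = []
    for roi in rois:
        sub = merged[merged["roi"] == roi]
        g1 = sub.loc[sub["group_label"] == labels[0], metric].to_numpy()
        g2 = sub.loc[sub["group_label"] == labels[1], metric].to_numpy()
        if g1.size < 2 or g2.size < 2:
            raise InsufficientGroupError(
                f"contrast {contrast!r} at ROI {roi!r}: group sizes "
                f"{g1.size} vs {g2.size} (need >= 2 each)"
            )
        u, p = mann_whitney_u(g1, g2)
        rows.append(
            {
                "roi": roi,
                "network": roi_network(roi),
                "metric": metric,
                "u_statistic": u,
                "p_uncorrected": p,
                "cohen_d": cohens_d(g1, g2),
                "n_group1": g1.size,
                "n_group2": g2.size,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p_uncorrected"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_threshold
    return table[
        [
            "roi",
            "network",
            "metric",
            "u_statistic",
            "p_uncorrected",
            "p_fdr",
            "cohen_d",
            "n_group1",
            "n_group2",
            "significant",
        ]
    ]


def run_correlations(
    metrics_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    predictor: str,
    metric: str,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI Spearman correlation of a behavioral score with a metric.

    ``predictor`` is a continuous phenotype column (iap_score or
    delta_rt_mean); boundary subjects are included, since the correlation
    uses the continuous score. BH correction across the ROI family.
    """
    if predictor not in phenotypes.columns:
        raise ValueError(f"predictor {predictor!r} not in phenotype table")
    merged = metrics_table.merge(
        phenotypes[["subject_id", predictor]], on="subject_id", how="inner"
    )
    rois = list(dict.fromkeys(metrics_table["roi"]))
    rows = []
    for roi in rois:
        sub = merged[merged["roi"] == roi].dropna(subset=[predictor, metric])
        rho, p = spearman_corr(sub[predictor].to_numpy(), sub[metric].to_numpy())
        rows.append(
            {
                "roi": roi,
                "network": roi_network(roi),
                "predictor": predictor,
                "metric": metric,
                "spearman_rho": rho,
                "p_uncorrected": p,
                "n": len(sub),
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p_uncorrected"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_threshold
    return table
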