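"""Component enrichment scoring and gene-signature survival validation.

Per-sample enrichment of a discovered network component is the mean fold
change over its measured member genes, tested against zero with a one-sided
one-sample t-test (a Wilcoxon signed-rank alternative is available for
outlier robustness).  For survival validation, a combined risk score per
sample is the mean CNA (as-is) or mean expression z-score over the component
genes; samples are dichotomized at the median (inclusive) or at zero, and
compared by Kaplan-Meier/log-rank.  Cox proportional-hazards models (Efron
tie handling) quantify the continuous score's effect with optional age and
genome-altered-fraction covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .data_model import OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RiskGroups:
    scores: pd.Series
    labels: pd.Series        # "altered" / "unaltered"
    rule: str
    threshold: float
    degenerate: bool = False


def component_enrichment(matrix: OmicsMatrix, component,
                         alternative: str = "greater",
                         method: str = "t") -> pd.DataFrame:
    """Per-sample test of the mean component fold change against zero.

    Uses the component genes measured in the matrix (>= 2 required).  The
    effect size (mean FC) is reported for every sample regardless of
    significance; samples with zero variance across component genes are
    flagged degenerate with an undefined P.
    """
    genes = [g for g in component if g in set(matrix.genes)]
    if len(genes) < 2:
        raise ValidationError("fewer than 2 component genes measured")
    sub = matrix.data.loc[genes]
    rows = []
    for sample in matrix.samples:
        vals = sub[sample].dropna().to_numpy()
        effect = float(vals.mean()) if vals.size else np.nan
        degenerate = vals.size < 2 or np.ptp(vals) == 0
        if degenerate:
            stat, p = np.nan, np.nan
        elif method == "t":
            res = stats.ttest_1samp(vals, 0.0, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        elif method == "wilcoxon":
            res = stats.wilcoxon(vals, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append({"sample_id": sample, "layer": matrix.layer,
                     "effect_size": effect, "statistic": stat, "pvalue": p,
                     "n_genes": int(vals.size), "degenerate": degenerate})
    return pd.DataFrame(rows)


def zscore_genes(matrix: OmicsMatrix) -> OmicsMatrix:
    """Per-gene z-scores across the matrix's samples (ddof=1, R convention)."""
    data = matrix.data.sub(matrix.data.mean(axis=1), axis=0)
    sd = matrix.data.std(axis=1, ddof=1)
    data = data.div(sd.replace(0.0, np.nan), axis=0)
    return OmicsMatrix(layer=matrix.layer, data=data)


def combined_risk_score(matrix: OmicsMatrix, component,
                        zscore: bool = False) -> pd.Series:
    """Mean value over measured component genes per sample.

    With ``zscore=True`` the matrix is per-gene z-scored across its samples
    first (the expression convention); CNA matrices are used as-is.  Samples
    with no measured component gene get a missing score.
    """
    if zscore:
        matrix = zscore_genes(matrix)
    genes = [g for g in component if g in set(matrix.genes)]
    if not genes:
        raise ValidationError("no component gene measured in the matrix")
    return matrix.data.loc[genes].mean(axis=0, skipna=True).rename("risk_score")


def dichotomize(scores: pd.Series, rule: str = "median") -> RiskGroups:
    """Split samples into altered/unaltered risk groups.

    ``median``: altered iff score >= median (inclusive, so ties at the median
    are altered and the altered group holds at least half the samples);
    ``positive``: altered iff score > 0 (for discretized CNA scores).
    """
    scores = scores.dropna()
    if len(scores) < 2:
        raise ValidationError("need >= 2 non-missing scores")
    if rule == "median":
        threshold = float(scores.median())
        labels = pd.Series(np.where(scores >= threshold, "altered", "unaltered"),
                           index=scores.index)
    elif rule == "positive":
        threshold = 0.0
        labels = pd.Series(np.where(scores > 0.0, "altered", "unaltered"),
                           index=scores.index)
    else:
        raise ValidationError(f"unknown dichotomization rule {rule!r}")
    degenerate = labels.nunique() < 2
    if degenerate:
        logger.warning("dichotomization produced a single group (%s rule)", rule)
    return RiskGroups(scores=scores, labels=labels, rule=rule,
                      threshold=threshold, degenerate=degenerate)


def km_logrank(groups: RiskGroups, survival: pd.DataFrame):
    """Kaplan-Meier curves per risk group and the two-group log-rank test.

    ``survival`` is indexed like the scores (sample or patient identifiers)
    with ``time`` and ``event`` columns.  Returns (curves, result dict).
    """
    merged = survival.loc[survival.index.intersection(groups.labels.index)].copy()
    merged["group"] = groups.labels.loc[merged.index]
    curves = {}
    for name, sub in merged.groupby("group"):
        if sub.empty:
            raise ValidationError(f"empty risk group {name!r}")
        km = KaplanMeierFitter(label=name)
        km.fit(sub["time"], sub["event"])
        curves[name] = km
        if sub["event"].sum() == 0:
            logger.warning("risk group %s has no events; log-rank P unreliable", name)
    if merged["group"].nunique() < 2:
        raise ValidationError("log-rank test needs two non-empty groups")
    a = merged[merged["group"] == "altered"]
    u = merged[merged["group"] == "unaltered"]
    res = logrank_test(a["time"], u["time"], a["event"], u["event"])
    return curves, {"statistic": float(res.test_statistic),
                    "pvalue": float(res.p_value),
                    "n_altered": len(a), "n_unaltered": len(u)}


def cox_fit(score: pd.Series, survival: pd.DataFrame,
            covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Cox proportional-hazards fit of survival on the continuous risk score.

    ``covariates`` names optional columns of ``survival`` (e.g. ``age``,
    ``genome_altered_fraction``).  Rows with missing values are dropped
    listwise (logged).  Efron tie handling.  Returns the summary table
    (coefficient, hazard ratio, P per variable) with the score first.
    """
    df = survival.loc[survival.index.intersection(score.index),
                      ["time", "event", *covariates]].copy()
    df["risk_score"] = score.loc[df.index]
    before = len(df)
    df = df.dropna()
    if len(df) < before:
        logger.info("Cox fit: dropped %d rows with missing values", before - len(df))
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure / separation
        raise ValidationError(f"Cox model did not converge: {exc}") from exc
    summary = cph.summary[["coef", "exp(coef)", "se(coef)", "p"]].copy()
    summary.columns = ["coef", "hazard_ratio", "se", "pvalue"]
    order = ["risk_score"] + [c for c in summary.index if c != "risk_score"]
    return summary.loc[order]


def burden_confounding(score: pd.Series, burden: pd.Series):
    """Pearson correlation of the risk score with overall CNA burden."""
    joint = pd.concat([score, burden], axis=1, join="inner").dropna()
    if len(joint) < 3:
        raise ValidationError("need >= 3 paired values")
    a, b = joint.iloc[:, 0], joint.iloc[:, 1]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValidationError("zero variance in burden-confounding inputs")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
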