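"""Intra- versus inter-patient molecular heterogeneity per layer.

For every patient with two characterized tumor areas, the Pearson
correlation between TA1 and TA2 over the genes measured in both samples
quantifies within-patient similarity; all pairwise correlations between
different patients' samples within a grade group form the between-patient
background.  A one-sided Wilcoxon rank-sum test compares the two, and
"correlating the correlations" across layers asks whether patients whose
tumor areas are genomically similar are also similar at the mRNA and
protein level.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import TestResult, pearson_pairwise_complete, rank_sum_test
from .data_model import CohortAnnotation, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)


def paired_similarity(matrix: OmicsMatrix, annotation: CohortAnnotation,
                      min_genes: int = 3) -> pd.Series:
    """Pearson r(TA1, TA2) per patient over genes measured in both areas."""
    cols = set(matrix.samples)
    out = {}
    for pid in annotation.paired_patients():
        try:
            s1 = annotation.sample_of(pid, "TA1")
            s2 = annotation.sample_of(pid, "TA2")
        except KeyError:
            continue
        if s1 not in cols or s2 not in cols:
            continue
        r = pearson_pairwise_complete(matrix.data[s1].to_numpy(),
                                      matrix.data[s2].to_numpy(), min_values=min_genes)
        if np.isnan(r):
            logger.warning("patient %s: <%d shared genes or degenerate profiles at %s",
                           pid, min_genes, matrix.layer)
        out[pid] = r
    return pd.Series(out, name=f"r_{matrix.layer}")


def intergroup_similarity(matrix: OmicsMatrix, annotation: CohortAnnotation,
                          min_genes: int = 3) -> dict[str, list[float]]:
    """All within-grade-group pairwise correlations between different patients.

    Samples are grouped by their area grade; same-patient pairs are excluded
    from the between-patient background.  Singleton groups yield empty lists.
    """
    tum = annotation.tumor_samples()
    tum = tum[tum["sample_id"].isin(set(matrix.samples))]
    out: dict[str, list[float]] = {}
    for grade, grp in tum.groupby("area_grade"):
        rs = []
        recs = list(grp[["sample_id", "patient_id"]].itertuples(index=False))
        for (s1, p1), (s2, p2) in itertools.combinations(recs, 2):
            if p1 == p2:
                continue
            r = pearson_pairwise_complete(matrix.data[s1].to_numpy(),
                                          matrix.data[s2].to_numpy(), min_values=min_genes)
            if np.isfinite(r):
                rs.append(r)
        out[grade] = rs
    return out


def within_vs_between_test(within, between) -> TestResult:
    """One-sided Wilcoxon rank-sum: within-patient r exceeds the background."""
    within = np.asarray(pd.Series(within).dropna(), dtype=float)
    between = np.asarray(pd.Series(between).dropna(), dtype=float)
    if within.size == 0 or between.size == 0:
        raise ValidationError("empty similarity list")
    return rank_sum_test(within, between, alternative="greater")


def correlate_correlations(r_layer_a: pd.Series, r_layer_b: pd.Series):
    """Pearson correlation across patients of two layers' TA1-TA2 correlations."""
    joint = pd.concat([r_layer_a, r_layer_b], axis=1, join="inner").dropna()
    if len(joint) < 3:
        raise ValidationError("need >= 3 patients with both correlations")
    res = stats.pearsonr(joint.iloc[:, 0], joint.iloc[:, 1])
    return float(res.statistic), float(res.pvalue)


def heterogeneity_summary(matrices: dict[str, OmicsMatrix],
                          annotation: CohortAnnotation) -> dict:
    """Within/between similarities, tests, and layer-pair correlation table."""
    layers = [l for l in ("cna", "mrna", "protein") if l in matrices]
    within = {l: paired_similarity(matrices[l], annotation) for l in layers}
    between = {l: intergroup_similarity(matrices[l], annotation) for l in layers}
    tests = {}
    for l in layers:
        pooled = [r for rs in between[l].values() for r in rs]
        tests[l] = within_vs_between_test(within[l], pooled)
    pairs = {}
    for a, b in itertools.combinations(layers, 2):
        pairs[f"{a}_vs_{b}"] = correlate_correlations(within[a], within[b])
    return {"within": within, "between": between, "tests": tests,
            "correlation_of_correlations": pairs}
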