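"""Per-sample molecular perturbation scores and cross-layer correlation analyses.

Two burden-style scores summarize how strongly each tumor sample deviates
from the benign reference at a given layer: DE_count is the number of
mutated/differentially expressed genes (absolute fold change above a
layer-specific threshold; a 1-entry at the mutation layer), and DE_sum is the
sum of absolute fold changes over *all* measured genes.  Grade groups are
compared with a one-sided Wilcoxon rank-sum test (higher scores expected in
the pooled high-grade group).

The module also houses the per-gene cis correlation (CNA vs mRNA/protein
Spearman), the protein-complex buffering test, and the top-protein
prioritization by mean absolute fold change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import TestResult, rank_sum_test, spearman_rows, welch_t_test
from .data_model import CohortAnnotation, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

#: default |log2 FC| thresholds per layer; the CNA threshold is lower because
#: copy-number ratios span a narrower range than expression fold changes
DEFAULT_THRESHOLDS = {"cna": 0.5, "mrna": 1.0, "protein": 1.0}


def binarize_mutations(matrix: OmicsMatrix) -> OmicsMatrix:
    """Set all non-zero mutation events to 1; missing counts as 0.  Idempotent."""
    if matrix.layer != "mutation":
        raise ValidationError("binarize_mutations expects the mutation layer")
    data = (matrix.data.fillna(0.0) != 0).astype(float)
    return OmicsMatrix(layer="mutation", data=data)


def perturbation_scores(matrix: OmicsMatrix, threshold: float | None = None) -> pd.DataFrame:
    """DE_count and DE_sum per sample.

    de_count = #{genes : |value| > threshold} (mutation layer: #{value == 1});
    de_sum = sum of |value| over all measured genes (omitted for mutations).
    Missing values are excluded from both scores.
    """
    if matrix.layer == "mutation":
        binary = binarize_mutations(matrix)
        de_count = (binary.data == 1).sum(axis=0)
        return pd.DataFrame({
            "sample_id": matrix.samples,
            "layer": matrix.layer,
            "de_count": de_count.to_numpy(dtype=int),
            "de_sum": np.nan,
            "threshold": np.nan,
        })
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[matrix.layer]
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    absval = matrix.data.abs()
    return pd.DataFrame({
        "sample_id": matrix.samples,
        "layer": matrix.layer,
        "de_count": (absval > threshold).sum(axis=0).to_numpy(dtype=int),
        "de_sum": absval.sum(axis=0, skipna=True).to_numpy(dtype=float),
        "threshold": threshold,
    })


def compare_grade_groups(scores: pd.DataFrame, annotation: CohortAnnotation,
                         value: str = "de_count",
                         high_grades=("G3", "G4_5"), low_grades=("G1", "G2"),
                         method: str = "asymptotic") -> TestResult:
    """One-sided Wilcoxon rank-sum test for higher scores in the pooled high group.

    Default pooling gathers G3 with G4/5 against G1 with G2.  The default
    method is the tie-corrected normal approximation (appropriate at cohort
    scale); ``method='auto'`` switches to the exact null for small tie-free
    groups.
    """
    merged = scores.merge(annotation.tumor_samples()[["sample_id", "area_grade"]],
                          on="sample_id", how="inner")
    high = merged.loc[merged["area_grade"].isin(set(high_grades)), value].dropna()
    low = merged.loc[merged["area_grade"].isin(set(low_grades)), value].dropna()
    if high.empty or low.empty:
        raise ValidationError("empty grade pool in comparison")
    return rank_sum_test(high, low, alternative="greater", method=method)


def cis_correlations(cna: OmicsMatrix, other: OmicsMatrix,
                     min_samples: int = 3) -> pd.Series:
    """Per-gene Spearman correlation between CNA and a downstream layer.

    Restricted to genes present in both layers and to the intersection of
    their samples; genes with fewer than ``min_samples`` complete pairs or a
    constant value vector are returned as NaN.
    """
    genes = [g for g in cna.genes if g in set(other.genes)]
    samples = [s for s in cna.samples if s in set(other.samples)]
    if not samples:
        raise ValidationError("no shared samples between the two layers")
    A = cna.data.loc[genes, samples].to_numpy()
    B = other.data.loc[genes, samples].to_numpy()
    rho = spearman_rows(A, B, min_samples=min_samples)
    return pd.Series(rho, index=genes, name=f"rho_{cna.layer}_{other.layer}")


def buffering_test(rho: pd.Series, complex_flag: pd.Series) -> TestResult:
    """Welch one-sided t-test: complex members correlate less than non-members.

    ``rho`` holds per-gene mRNA-protein correlations; the alternative is
    mean(rho | complex) < mean(rho | non-complex), i.e. stronger buffering of
    mRNA changes for proteins in stable complexes.
    """
    flag = complex_flag.reindex(rho.index)
    cx = rho[flag.astype(bool)].dropna()
    nc = rho[~flag.astype(bool)].dropna()
    if len(cx) < 2 or len(nc) < 2:
        raise ValidationError("each complex-membership group needs >= 2 finite values")
    return welch_t_test(cx, nc, alternative="less")


def rank_top_proteins(protein: OmicsMatrix, k: int) -> pd.DataFrame:
    """Top-k proteins by mean absolute fold change across measured samples.

    Ties are broken by lexicographic gene order (logged); k larger than the
    number of genes truncates with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    score = protein.data.abs().mean(axis=1, skipna=True)
    score = score.dropna()
    if k > len(score):
        logger.warning("k=%d exceeds %d scored proteins; truncating", k, len(score))
        k = len(score)
    order = sorted(score.index, key=lambda g: (-score[g], g))
    ranked = pd.DataFrame({"gene": order, "score": score.loc[order].to_numpy()})
    if ranked["score"].duplicated().any():
        logger.info("ties in protein scores broken lexicographically")
    return ranked.head(k).reset_index(drop=True)
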