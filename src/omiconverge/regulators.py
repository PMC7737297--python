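"""Trans-regulator nomination for a target gene via network neighborhood analysis.

Candidate regulators are the target's interaction-network neighbors at
combined confidence > 0.2 (together with the target itself, to capture
cis-effects); the remaining network genes with CNA measurements form the
background.  Genes whose copy number is altered (|log2 ratio| > 0.5) in
fewer than four tumor samples are filtered out of both groups.  The
neighborhood's CNA-target-mRNA correlations are compared against the
background with a one-sided Welch t-test, and a sparse elastic-net
regression (mixing 0.5, penalty chosen by seeded 10-fold cross-validation)
selects the significant regulators.  Signs are validated on external cohorts
by Spearman-correlation sign agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from ._stats import TestResult, spearman_rows, welch_t_test
from .data_model import GeneNetwork, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodSplit:
    target: str
    group1: list[str]          # target + confidence > threshold neighbors
    group2: list[str]          # remaining measured network genes
    conf_threshold: float
    group1_filtered: list[str] | None = None
    group2_filtered: list[str] | None = None


@dataclass
class RegulatorResult:
    target: str
    selected: pd.Series        # nonzero coefficients, original scale
    penalty: float
    rule: str
    n_folds: int
    seed: int
    cv_table: pd.DataFrame | None = None


def split_neighborhood(network: GeneNetwork, target: str, cna: OmicsMatrix,
                       conf_threshold: float = 0.2) -> NeighborhoodSplit:
    """Split the measured-gene universe into target neighborhood and complement.

    Uses the *unfiltered* confidence range of the network (edges > 0.2), not
    the high-confidence propagation graph.
    """
    if target not in network.graph:
        raise ValidationError(f"target {target!r} absent from the network")
    measured = set(cna.genes)
    if target not in measured:
        raise ValidationError(f"target {target!r} has no CNA measurements")
    neighbors = set(network.neighbors_above(target, conf_threshold))
    group1 = sorted(({target} | neighbors) & measured)
    group2 = sorted((set(network.graph.nodes) - {target} - neighbors) & measured)
    return NeighborhoodSplit(target=target, group1=group1, group2=group2,
                             conf_threshold=conf_threshold)


def cna_event_filter(genes, cna: OmicsMatrix, min_samples: int = 4,
                     magnitude: float = 0.5) -> list[str]:
    """Keep genes altered (|log2 ratio| > magnitude) in >= min_samples samples."""
    if magnitude <= 0:
        raise ValidationError("magnitude must be positive")
    genes = [g for g in genes if g in set(cna.genes)]
    counts = (cna.data.loc[genes].abs() > magnitude).sum(axis=1)
    return sorted(counts[counts >= min_samples].index)


def apply_event_filter(split: NeighborhoodSplit, cna: OmicsMatrix,
                       min_samples: int = 4, magnitude: float = 0.5) -> NeighborhoodSplit:
    split.group1_filtered = cna_event_filter(split.group1, cna, min_samples, magnitude)
    split.group2_filtered = cna_event_filter(split.group2, cna, min_samples, magnitude)
    return split


def neighbor_correlation_test(split: NeighborhoodSplit, cna: OmicsMatrix,
                              target_mrna: pd.Series,
                              alternative: str = "greater"):
    """Per-gene Spearman(CNA, target mRNA FC) and a one-sided group t-test.

    ``alternative='greater'`` tests whether the filtered neighborhood is more
    positively correlated with the target than the background complement
    (appropriate for a downregulated target whose positive regulators are
    deleted); the direction is parameterizable.

    Returns (rho_group1, rho_group2, TestResult).
    """
    g1 = split.group1_filtered if split.group1_filtered is not None else split.group1
    g2 = split.group2_filtered if split.group2_filtered is not None else split.group2
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs >= 2 genes after filtering")
    samples = [s for s in cna.samples if s in target_mrna.index]
    if len(samples) < 3:
        raise ValidationError("fewer than 3 samples with CNA and target mRNA")
    y = target_mrna.loc[samples].to_numpy(dtype=float)

    def group_rho(genes):
        A = cna.data.loc[genes, samples].to_numpy()
        B = np.tile(y, (len(genes), 1))
        return pd.Series(spearman_rows(A, B), index=genes)

    rho1, rho2 = group_rho(g1), group_rho(g2)
    mapping = {"greater": "greater", "less": "less"}
    res = welch_t_test(rho1.dropna(), rho2.dropna(), alternative=mapping[alternative])
    return rho1, rho2, res


def elastic_net_regulators(split: NeighborhoodSplit, cna: OmicsMatrix,
                           target_mrna: pd.Series, l1_ratio: float = 0.5,
                           n_folds: int = 10, seed: int = 0,
                           rule: str = "1se") -> RegulatorResult:
    """Sparse elastic-net selection of regulators from the filtered neighborhood.

    Predictors are the CNA profiles of the filtered group-1 genes (including
    the target's own CNA when it passes the event filter); the response is
    the target's mRNA fold change over the samples where it is available.
    Predictors are standardized internally; coefficients are reported on the
    original scale.  The penalty is chosen by seeded K-fold cross-validation,
    by default at the sparser "within one standard error of the CV minimum"
    point (``rule='min'`` selects the CV minimum instead).
    """
    predictors = split.group1_filtered if split.group1_filtered is not None else split.group1
    if not predictors:
        raise ValidationError("no predictors left after filtering")
    samples = [s for s in cna.samples if s in target_mrna.index
               and np.isfinite(target_mrna[s])]
    if len(samples) < 3:
        raise ValidationError("too few samples for regression")
    n_folds_eff = min(n_folds, len(samples))
    if n_folds_eff < n_folds:
        logger.warning("reducing folds from %d to %d (only %d samples)",
                       n_folds, n_folds_eff, len(samples))
    X = cna.data.loc[predictors, samples].T.to_numpy(dtype=float)
    y = target_mrna.loc[samples].to_numpy(dtype=float)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd

    cv = KFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    enet_cv = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=100, max_iter=50_000)
    enet_cv.fit(Xs, y)
    alphas = enet_cv.alphas_
    mse = enet_cv.mse_path_.mean(axis=1)
    se = enet_cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(enet_cv.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    if rule == "1se":
        within = np.flatnonzero(mse <= mse[i_min] + se[i_min])
        chosen = float(alphas[within].max())  # largest penalty within 1 SE
    elif rule == "min":
        chosen = float(alphas[i_min])
    else:
        raise ValidationError(f"unknown penalty rule {rule!r}")

    model = ElasticNet(alpha=chosen, l1_ratio=l1_ratio, max_iter=50_000)
    model.fit(Xs, y)
    coef = model.coef_ / x_sd  # back to original scale
    nz = np.abs(coef) > 1e-10
    selected = pd.Series(coef[nz], index=np.asarray(predictors)[nz],
                         name="coefficient").sort_values(key=np.abs, ascending=False)
    cv_table = pd.DataFrame({"alpha": alphas, "cv_mse": mse, "cv_se": se})
    return RegulatorResult(target=split.target, selected=selected, penalty=chosen,
                           rule=rule, n_folds=n_folds_eff, seed=seed, cv_table=cv_table)


def sign_validation(selected: pd.Series, discovery_rho: pd.Series,
                    cohorts: dict[str, tuple[OmicsMatrix, pd.Series]]) -> pd.DataFrame:
    """Spearman sign agreement of selected regulators across external cohorts.

    ``discovery_rho`` holds the discovery-cohort Spearman correlation per
    selected regulator; each external cohort is a (CNA matrix, target
    expression z-scores per sample) pair.  Regulators absent from a cohort
    are recorded as not evaluable rather than raising.
    """
    rows = []
    for cohort_name, (cna, target_expr) in cohorts.items():
        samples = [s for s in cna.samples if s in target_expr.index]
        for gene in selected.index:
            ref_rho = discovery_rho.get(gene, np.nan)
            if gene not in set(cna.genes) or len(samples) < 3:
                rows.append({"cohort": cohort_name, "regulator": gene,
                             "rho": np.nan, "reference_rho": ref_rho,
                             "sign_match": pd.NA, "evaluable": False})
                continue
            rho = spearman_rows(
                cna.data.loc[[gene], samples].to_numpy(),
                target_expr.loc[samples].to_numpy()[None, :])[0]
            match = bool(np.sign(rho) == np.sign(ref_rho)) \
                if np.isfinite(rho) and np.isfinite(ref_rho) else pd.NA
            rows.append({"cohort": cohort_name, "regulator": gene, "rho": rho,
                         "reference_rho": ref_rho, "sign_match": match,
                         "evaluable": np.isfinite(rho)})
    return pd.DataFrame(rows)
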