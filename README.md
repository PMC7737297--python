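# omiconverge

Network-convergence analysis of multi-omics tumor cohorts.

In prostate cancer, individual copy-number alterations (CNAs) are often too
weak and too heterogeneous across patients to be significant in isolation,
yet their effects can converge on common protein-interaction-network
regions. `omiconverge` implements a reusable pipeline for detecting such
convergent network perturbations from gene-level log2 fold-change matrices
(CNA, mRNA, protein, plus a binary mutation matrix) measured against a
benign reference, together with the downstream analyses that make the
finding interpretable: per-sample perturbation burden, survival validation
of discovered gene signatures, trans-regulator nomination, and intra- vs
inter-patient heterogeneity.

## What the pipeline computes

**Molecular perturbation scores.** For each tumor sample and layer,
`DE_count = #{genes : |log2 FC| > t}` (t = 0.5 for CNA, 1 for mRNA and
protein; mutated genes counted at the mutation layer) and
`DE_sum = Σ_genes |log2 FC|`. Grade groups are compared with a one-sided
Wilcoxon rank-sum test (G3 + G4/5 pooled against G1 + G2).

**Network propagation.** Fold changes are smoothed per sample over the
high-confidence interaction network (STRING-style combined scores; edges
with confidence ≤ 0.9 removed, then the largest connected component) by
iterating

    F ← α W′ F + (1 − α) F₀,   W′ = D^(−1/2) A D^(−1/2)

with α = 0.5 for 500 iterations, which converges to the solution of
(I − αW′)F = (1 − α)F₀. Nodes with no protein measurement on themselves or
any direct neighbor are excluded afterwards (protein-coverage filter).

**Differential sub-network discovery.** Per node and layer, one-sided
Wilcoxon rank-sum tests compare smoothed values between the G4/5 and G1
sample groups, once per direction. Nodes with P < 0.05 at *all three*
layers in the same direction form the differential set; its connected
components on the filtered network are the reported sub-networks. The
three-layer intersection is the implicit multiplicity control.

**Component scoring and survival validation.** Per sample, a one-sided
one-sample t-test asks whether the mean fold change over a component's
measured genes exceeds zero. A combined risk score (mean CNA, or mean
per-gene expression z-score) dichotomizes a cohort at the median
(inclusive) or at zero; groups are compared by Kaplan–Meier/log-rank, and
Cox proportional-hazards models (Efron ties) quantify the continuous score
with optional age and genome-altered-fraction covariates.

**Trans-regulator nomination.** For a target gene, candidate regulators are
its network neighbors at confidence > 0.2 (plus the target itself); genes
with |log2 CNA| > 0.5 in fewer than 4 tumor samples are filtered out. The
neighborhood's CNA–target-mRNA Spearman correlations are tested against the
network complement (one-sided Welch t), and an elastic net (mixing 0.5,
penalty by seeded 10-fold cross-validation) selects regulators; signs are
validated on independent cohorts by Spearman sign agreement.

**Heterogeneity.** Pearson correlation of paired tumor areas (TA1 vs TA2)
per patient and layer, compared against within-grade-group between-patient
correlations (one-sided Wilcoxon), and the "correlation of correlations"
across layers.

**Synthetic cohorts.** `omiconverge.simulate` generates cohorts with the
full structure the analysis assumes — a scale-free network with a planted
near-clique component carrying a weak, grade-dependent amplification;
attenuated CNA→mRNA→protein transmission with stronger buffering for
protein-complex members; clonal copy-number events driving planted
trans-regulators; partial protein detection; paired tumor areas with a
tunable clonal share; and Weibull survival whose hazard rises with the
planted component's dosage — together with the ground truth needed for
recovery tests.

## Worked example

```python
from omiconverge.simulate import SimulationConfig, simulate_dataset
from omiconverge.pipeline import discovery_pipeline

cohort = simulate_dataset(SimulationConfig(), seed=42)
print("planted component:", ", ".join(cohort.truth.component))

result = discovery_pipeline(cohort)
top = result["up"].components[0]
print("largest upregulated component:", ", ".join(top))
```

prints

```
planted component: g0095, g0209, g0290, g0484, g0576, g0814, g0816, g0831, g0962
largest upregulated component: g0095, g0209, g0290, g0484, g0576, g0610, g0814, g0831, g0962
```

Eight of the nine planted genes are recovered plus one attached neighbor
(Jaccard 0.80) — the module is found although its per-gene amplification
(0.12 log2 units in high-grade patients) is far below the single-gene
event threshold. Survival validation of such a signature belongs to large
external cohorts; on a simulated 300-patient cohort with a true log-hazard
ratio of 0.8 per standard deviation of the risk score:

```python
import numpy as np, pandas as pd
from omiconverge.simulate import simulate_survival
from omiconverge.survival import cox_fit, dichotomize, km_logrank

rng = np.random.default_rng(42)
z = rng.standard_normal(300)
time, event = simulate_survival(z, 0.8, rng=rng)
surv = pd.DataFrame({"time": time, "event": event},
                    index=[f"p{i}" for i in range(300)])
score = pd.Series(z, index=surv.index)
_, lg = km_logrank(dichotomize(score), surv)
cox = cox_fit(score, surv)
print(f"log-rank P (altered vs unaltered): {lg['pvalue']:.3g}")
print(f"Cox log-HR estimate: {cox.loc['risk_score','coef']:.2f}")
```

prints

```
log-rank P (altered vs unaltered): 2.04e-08
Cox log-HR estimate: 0.80
```

The median split separates recurrence-free survival decisively and the Cox
model recovers the generating coefficient.

A command-line interface mirrors the library
(`omiconverge simulate | perturb | propagate | discover | score | survfit |
regulators | heterogeneity | run-all`); `run-all --config pipeline.yaml
--outdir out/` executes every stage and writes a manifest sufficient to
reproduce all outputs bit for bit.

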