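"""End-to-end orchestration with a reproducibility manifest.

``run_pipeline`` executes simulate (or load) -> harmonize -> perturbation
scores -> propagation -> discovery -> component scoring -> survival ->
regulators -> heterogeneity, writing TSV/JSON outputs per stage and a
manifest that records parameters, derived seeds, package versions and
wall-clock times, sufficient to reproduce every output bit for bit.

A single global seed is stretched into independent per-stage seeds through
``numpy.random.SeedSequence`` spawning, so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    CohortAnnotation,
    GeneNetwork,
    OmicsMatrix,
    ValidationError,
    harmonize,
    read_annotation,
    read_matrix,
    read_network,
    write_annotation,
    write_matrix,
    write_network,
)
from .discovery import discover_differential_components
from .heterogeneity import heterogeneity_summary
from .perturbation import compare_grade_groups, perturbation_scores
from .propagation import PropagationConfig, smooth_layer
from .regulators import (
    apply_event_filter,
    elastic_net_regulators,
    neighbor_correlation_test,
    split_neighborhood,
)
from .simulate import SimulatedCohort, SimulationConfig, simulate_dataset
from .survival import combined_risk_score, cox_fit, dichotomize, km_logrank

logger = logging.getLogger(__name__)

#: STRING-style combined-score cutoff for the propagation graph
PROPAGATION_CONFIDENCE = 0.9


@dataclass
class PipelineConfig:
    """Config for ``run_pipeline``; either a simulate block or input paths."""

    seed: int = 0
    simulate: SimulationConfig | None = None
    # input paths (used when simulate is None)
    cna_path: str | None = None
    mrna_path: str | None = None
    protein_path: str | None = None
    mutation_path: str | None = None
    network_path: str | None = None
    annotation_path: str | None = None
    survival_path: str | None = None
    # stage parameters
    propagation_alpha: float = 0.5
    propagation_iterations: int = 500
    discovery_alpha: float = 0.05
    high_grades: tuple = ("G4_5",)
    ref_grades: tuple = ("G1",)
    dedup_policy: str = "none"
    risk_layer: str = "cna"
    risk_rule: str = "median"
    regulator_target: str | None = None   # default: the simulated truth target
    regulator_conf: float = 0.2
    regulator_min_events: int = 4
    regulator_magnitude: float = 0.5
    regulator_l1_ratio: float = 0.5
    regulator_folds: int = 10
    regulator_rule: str = "1se"

    def validate(self) -> None:
        if self.simulate is None:
            required = ("cna_path", "mrna_path", "protein_path",
                        "network_path", "annotation_path")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ValidationError(
                    f"no simulate block and missing input paths: {missing}")
        PropagationConfig(alpha=self.propagation_alpha,
                          n_iterations=self.propagation_iterations)
        if not 0 < self.discovery_alpha < 1:
            raise ValidationError("discovery_alpha must lie in (0, 1)")
        if self.risk_rule not in ("median", "positive"):
            raise ValidationError(f"unknown risk rule {self.risk_rule!r}")
        if self.dedup_policy not in ("none", "drop_same_grade_TA2"):
            raise ValidationError(f"unknown dedup policy {self.dedup_policy!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        config = cls(**raw)
        if sim is not None:
            if "n_patients_per_grade" in sim:
                sim["n_patients_per_grade"] = tuple(sim["n_patients_per_grade"])
            if "event_magnitude" in sim:
                sim["event_magnitude"] = tuple(sim["event_magnitude"])
            config.simulate = SimulationConfig(**sim)
        for key in ("high_grades", "ref_grades"):
            setattr(config, key, tuple(getattr(config, key)))
        return config


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent per-stage seeds derived from one global seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def propagation_network(network: GeneNetwork,
                        min_confidence: float = PROPAGATION_CONFIDENCE) -> GeneNetwork:
    """High-confidence largest connected component used for smoothing."""
    return network.confidence_filter(min_confidence).largest_connected_component()


def smooth_cohort(matrices: dict[str, OmicsMatrix], network: GeneNetwork,
                  config: PropagationConfig | None = None):
    """Harmonize the expression layers onto the propagation graph and smooth them.

    Returns (smoothed layers dict, harmonized AlignedDataset, filtered network).
    """
    net = propagation_network(network)
    expr = {l: matrices[l] for l in ("cna", "mrna", "protein") if l in matrices}
    aligned = harmonize(expr, net)
    smoothed = {
        layer: smooth_layer(layer, aligned.layers[layer], net,
                            aligned.measured["protein"], config)
        for layer in expr
    }
    return smoothed, aligned, net


def discovery_pipeline(cohort: SimulatedCohort,
                       propagation: PropagationConfig | None = None,
                       alpha: float = 0.05, high_grades=("G4_5",),
                       ref_grades=("G1",), dedup_policy: str = "none"):
    """Smoothing + discovery in one call (the planted-recovery entry point)."""
    smoothed, _, net = smooth_cohort(cohort.matrices, cohort.network, propagation)
    return discover_differential_components(
        smoothed, cohort.annotation, net, alpha=alpha,
        high_grades=high_grades, ref_grades=ref_grades, dedup_policy=dedup_policy)


def _load_inputs(config: PipelineConfig):
    matrices = {}
    for layer, attr in (("cna", "cna_path"), ("mrna", "mrna_path"),
                        ("protein", "protein_path"), ("mutation", "mutation_path")):
        path = getattr(config, attr)
        if path is not None:
            matrices[layer] = read_matrix(path, layer)
    network = read_network(config.network_path)
    annotation = read_annotation(config.annotation_path, config.survival_path)
    return matrices, network, annotation


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages, write outputs under ``outdir``, return the manifest."""
    config.validate()  # pre-flight: never partially execute on a bad config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": _jsonable(asdict(config)),
        "stages": {},
    }
    truth = None

    def record(name, t0, outputs):
        manifest["stages"][name] = {
            "outputs": [str(p) for p in outputs],
            "wall_clock_s": round(time.monotonic() - t0, 3),
        }
        logger.info("stage %s done (%.2fs)", name, time.monotonic() - t0)

    # 1. simulate or load
    t0 = time.monotonic()
    if config.simulate is not None:
        cohort = simulate_dataset(config.simulate, seed=seeds[0])
        matrices, network, annotation = cohort.matrices, cohort.network, cohort.annotation
        truth = cohort.truth
        outs = []
        for layer, m in matrices.items():
            p = outdir / f"{layer}.tsv"
            write_matrix(m, p)
            outs.append(p)
        write_network(network, outdir / "network.tsv")
        write_annotation(annotation, outdir / "annotation.tsv", outdir / "survival.tsv")
        truth_json = {
            "component": truth.component,
            "target": truth.target,
            "regulators": truth.regulators,
        }
        (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2))
        outs += [outdir / "network.tsv", outdir / "annotation.tsv",
                 outdir / "survival.tsv", outdir / "truth.json"]
        record("simulate", t0, outs)
    else:
        matrices, network, annotation = _load_inputs(config)
        cohort = SimulatedCohort(network=network, matrices=matrices,
                                 annotation=annotation, truth=None)
        record("load", t0, [])

    # 2. perturbation scores
    t0 = time.monotonic()
    score_frames, tests = [], {}
    for layer, m in matrices.items():
        scores = perturbation_scores(m)
        score_frames.append(scores)
        for value in ("de_count", "de_sum"):
            if scores[value].notna().any():
                res = compare_grade_groups(scores, annotation, value=value)
                tests[f"{layer}_{value}"] = {"statistic": res.statistic,
                                             "pvalue": res.pvalue}
    scores_df = pd.concat(score_frames, ignore_index=True)
    scores_df.to_csv(outdir / "perturbation_scores.tsv", sep="\t", index=False)
    (outdir / "perturbation_tests.json").write_text(json.dumps(tests, indent=2))
    record("perturb", t0, [outdir / "perturbation_scores.tsv",
                           outdir / "perturbation_tests.json"])

    # 3. propagation
    t0 = time.monotonic()
    prop = PropagationConfig(alpha=config.propagation_alpha,
                             n_iterations=config.propagation_iterations)
    smoothed, aligned, net = smooth_cohort(matrices, network, prop)
    outs = []
    for layer, sm in smoothed.items():
        p = outdir / f"smoothed_{layer}.tsv"
        sm.values.to_csv(p, sep="\t", float_format="%.10g")
        outs.append(p)
    record("propagate", t0, outs)

    # 4. discovery
    t0 = time.monotonic()
    disc = discover_differential_components(
        smoothed, annotation, net, alpha=config.discovery_alpha,
        high_grades=config.high_grades, ref_grades=config.ref_grades,
        dedup_policy=config.dedup_policy)
    comp_rows = []
    for direction in ("up", "down"):
        for rank, comp in enumerate(disc[direction].components, start=1):
            for gene in comp:
                comp_rows.append({"direction": direction, "component": rank,
                                  "gene": gene})
    pd.DataFrame(comp_rows, columns=["direction", "component", "gene"]).to_csv(
        outdir / "components.tsv", sep="\t", index=False)
    node_tables = pd.concat(
        {layer: t.table for layer, t in disc["tables"].items()}, axis=1)
    node_tables.to_csv(outdir / "node_tests.tsv", sep="\t")
    record("discover", t0, [outdir / "components.tsv", outdir / "node_tests.tsv"])

    up = disc["up"].components
    main_component = up[0] if up else (truth.component if truth else [])

    # 5. component risk scoring
    t0 = time.monotonic()
    score = None
    if main_component:
        layer = config.risk_layer
        score = combined_risk_score(matrices[layer], main_component,
                                    zscore=(layer != "cna"))
        score.rename("risk_score").to_csv(outdir / "risk_scores.tsv", sep="\t")
        record("score", t0, [outdir / "risk_scores.tsv"])
    else:
        record("score", t0, [])

    # 6. survival validation
    t0 = time.monotonic()
    outs = []
    surv_summary = {}
    if score is not None and annotation.survival is not None:
        # per-patient score from the index tumor area (TA1 / TA)
        tum = annotation.tumor_samples()
        index_samples = tum[tum["area"].isin(["TA", "TA1"])] \
            .set_index("patient_id")["sample_id"]
        patient_score = score.loc[index_samples.to_numpy()]
        patient_score.index = index_samples.index
        groups = dichotomize(patient_score, rule=config.risk_rule)
        surv = annotation.survival.set_index("patient_id")
        curves, logrank = km_logrank(groups, surv)
        covars = tuple(c for c in ("age", "genome_altered_fraction")
                       if c in surv.columns and surv[c].notna().all())
        cox = cox_fit(patient_score, surv, covariates=covars)
        groups.labels.rename("risk_group").to_csv(outdir / "risk_groups.tsv", sep="\t")
        cox.to_csv(outdir / "cox_summary.tsv", sep="\t")
        km_rows = []
        for name, km in curves.items():
            sf = km.survival_function_
            for t, s in zip(sf.index, sf.iloc[:, 0]):
                km_rows.append({"group": name, "time": t, "survival": s})
        pd.DataFrame(km_rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
        surv_summary = {"logrank": logrank,
                        "cox_risk_score_p": float(cox.loc["risk_score", "pvalue"])}
        outs = [outdir / "risk_groups.tsv", outdir / "cox_summary.tsv",
                outdir / "km_curves.tsv"]
    (outdir / "survival_summary.json").write_text(json.dumps(surv_summary, indent=2))
    record("survfit", t0, outs + [outdir / "survival_summary.json"])

    # 7. regulators
    t0 = time.monotonic()
    outs = []
    target = config.regulator_target or (truth.target if truth else None)
    if target is not None and "mrna" in matrices and target in matrices["mrna"].data.index:
        split = split_neighborhood(network, target, matrices["cna"],
                                   conf_threshold=config.regulator_conf)
        apply_event_filter(split, matrices["cna"],
                           min_samples=config.regulator_min_events,
                           magnitude=config.regulator_magnitude)
        target_mrna = matrices["mrna"].data.loc[target]
        rho1, rho2, test = neighbor_correlation_test(split, matrices["cna"], target_mrna)
        result = elastic_net_regulators(
            split, matrices["cna"], target_mrna, l1_ratio=config.regulator_l1_ratio,
            n_folds=config.regulator_folds, seed=seeds[6], rule=config.regulator_rule)
        result.selected.rename("coefficient").to_csv(
            outdir / "selected_regulators.tsv", sep="\t")
        pd.concat({"neighborhood": rho1, "complement": rho2}) \
            .rename("rho").to_csv(outdir / "neighborhood_rho.tsv", sep="\t")
        reg_summary = {"target": target, "neighborhood_test_p": test.pvalue,
                       "n_selected": int(len(result.selected)),
                       "penalty": result.penalty, "rule": result.rule}
        (outdir / "regulators_summary.json").write_text(json.dumps(reg_summary, indent=2))
        outs = [outdir / "selected_regulators.tsv", outdir / "neighborhood_rho.tsv",
                outdir / "regulators_summary.json"]
    record("regulators", t0, outs)

    # 8. heterogeneity
    t0 = time.monotonic()
    het = heterogeneity_summary(matrices, annotation)
    within_df = pd.DataFrame({l: s for l, s in het["within"].items()})
    within_df.to_csv(outdir / "within_patient_similarity.tsv", sep="\t")
    het_summary = {
        "tests": {l: {"statistic": t.statistic, "pvalue": t.pvalue}
                  for l, t in het["tests"].items()},
        "correlation_of_correlations": {k: {"r": v[0], "pvalue": v[1]}
                                        for k, v in het["correlation_of_correlations"].items()},
    }
    (outdir / "heterogeneity_summary.json").write_text(json.dumps(het_summary, indent=2))
    record("heterogeneity", t0, [outdir / "within_patient_similarity.tsv",
                                 outdir / "heterogeneity_summary.json"])

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
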