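"""Synthetic multi-omics cohort generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes for a
39-patient prostate-cancer cohort profiled at the CNA, mRNA and protein
layers against a benign reference:

* a scale-free gene network with STRING-style edge confidences, of which a
  configurable fraction survives the high-confidence (> 0.9) filter;
* a planted, connected, near-clique network component (emulating a protein
  complex module) whose member genes carry a weak DNA amplification that
  grows with the patient's overall grade;
* CNA -> mRNA -> protein transmission of the planted perturbation with
  attenuation, and mRNA -> protein transmission of *all* mRNA variation with
  stronger buffering for protein-complex members;
* clonal copy-number events shared by the two tumor areas of a patient,
  driving planted trans-regulator effects on one designated target gene's
  mRNA;
* partial protein detection (the planted component is only partially
  detected at the protein layer);
* paired tumor areas whose expected similarity is controlled by a per-patient
  clonal-share factor common to all layers; and
* recurrence-free survival times whose Weibull hazard increases with the
  planted component's realized copy-number dosage.

Background variation is layer-autonomous at the CNA -> mRNA step (matching
the near-zero average cis correlation of background genes), so under a null
configuration (all grade effects zero) the three layers' per-node tests are
approximately independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    CohortAnnotation,
    GeneNetwork,
    OmicsMatrix,
    ValidationError,
)

_OVERALL = ("low", "intermediate", "high")


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the reference study conditions."""

    # network
    n_network_nodes: int = 1000
    network_attachment: int = 3          # scale-free preferential-attachment m
    high_confidence_fraction: float = 0.55  # edges surviving the > 0.9 filter
    component_size: int = 9
    component_density: float = 0.9       # within-component edge completion prob

    # cohort composition (low / intermediate / high overall grade)
    n_patients_per_grade: tuple[int, int, int] = (12, 17, 10)

    # planted component effect (log2 units at the CNA layer, per overall grade)
    mu_cna: dict = field(default_factory=lambda: {
        "low": 0.02, "intermediate": 0.05, "high": 0.12})

    # cross-layer transmission
    beta_mrna: float = 0.8               # CNA -> mRNA
    beta_prot: float = 0.6               # mRNA -> protein
    complex_buffering_factor: float = 0.4  # extra attenuation for complex members
    fraction_complex_members: float = 0.3

    # per-layer background noise SDs (log2 units)
    noise_sd: dict = field(default_factory=lambda: {
        "cna": 0.02, "mrna": 0.05, "protein": 0.015})

    # intra-patient structure
    clonal_share: float = 0.8            # expected TA1-TA2 shared-signal fraction
    clonal_concentration: float = 12.0   # Beta concentration of per-patient share
    coupled_similarity: bool = True      # one clonal-share draw for all layers

    # copy-number events (segment-block level), concentrated on unstable blocks
    event_rate: float = 0.12             # per patient and unstable block
    event_block_size: int = 20
    event_magnitude: tuple[float, float] = (0.6, 1.2)
    fraction_unstable_blocks: float = 0.3
    event_gene_participation: float = 0.85  # per-gene segment-call dropout
    regulator_event_min: int = 14        # planted regulators are recurrently altered

    # layer coverage / mutations
    protein_detection_rate: float = 0.25
    mutation_rate: float = 0.01

    # planted trans-regulators of the designated target gene
    n_planted_regulators: int = 5
    regulator_effect: float = 0.5        # |mRNA change of target per CNA unit|
    regulator_conf_threshold: float = 0.2
    min_target_neighbors: int = 40

    # survival (Weibull proportional hazards on the standardized dosage)
    weibull_shape: float = 1.5
    weibull_scale: float = 60.0          # months
    log_hazard_ratio: float = 0.8        # per SD of component dosage
    censor_rate: float = 0.4

    def __post_init__(self) -> None:
        for name in ("high_confidence_fraction", "component_density", "clonal_share",
                     "event_rate", "protein_detection_rate", "mutation_rate",
                     "fraction_complex_members", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.component_size > self.n_network_nodes:
            raise ValidationError("component_size exceeds n_network_nodes")
        if self.component_size < 1:
            raise ValidationError("component_size must be >= 1")
        mus = [self.mu_cna[g] for g in _OVERALL]
        if not (mus[0] <= mus[1] <= mus[2]):
            raise ValidationError("component effect means must be nondecreasing with grade")

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground-truth key for parameter-recovery tests."""

    component: list[str]
    target: str | None
    regulators: list[tuple[str, int]]    # (gene, effect sign)
    regulator_effects: dict
    complex_flags: pd.Series             # per gene
    dosage: pd.Series                    # per patient, standardized
    config: SimulationConfig


@dataclass
class SimulatedCohort:
    network: GeneNetwork
    matrices: dict                        # layer -> OmicsMatrix
    annotation: CohortAnnotation
    truth: SyntheticTruth


def _node_name(i: int) -> str:
    return f"g{i + 1:04d}"


def simulate_network(config: SimulationConfig, seed: int) -> tuple[GeneNetwork, list[str]]:
    """Scale-free network with confidences, plus a planted connected component.

    The planted component is snowball-sampled on the > 0.9-filtered largest
    connected component and densified to a near-clique with high-confidence
    edges, so that component membership survives the propagation-graph filter
    and the module behaves like a protein complex in the interactome.
    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    g0 = nx.barabasi_albert_graph(config.n_network_nodes, config.network_attachment,
                                  seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(g0, {i: _node_name(i) for i in g0.nodes})
    for u, v in sorted(graph.edges):
        if rng.random() < config.high_confidence_fraction:
            conf = rng.uniform(0.901, 0.999)
        else:
            conf = rng.uniform(0.05, 0.9)
        graph.edges[u, v]["confidence"] = float(conf)

    # snowball-sample the component on the high-confidence subgraph's LCC
    hc = nx.Graph((u, v) for u, v, c in graph.edges(data="confidence") if c > 0.9)
    lcc = max(nx.connected_components(hc), key=len)
    if len(lcc) < config.component_size:
        raise ValidationError("high-confidence component too small to plant the module")
    hc_lcc = hc.subgraph(lcc)
    seed_node = sorted(lcc)[int(rng.integers(len(lcc)))]
    component = {seed_node}
    frontier = sorted(hc_lcc.neighbors(seed_node))
    while len(component) < config.component_size:
        if not frontier:  # cannot happen on a connected LCC of sufficient size
            raise ValidationError("snowball sampling exhausted the component frontier")
        nxt = frontier.pop(int(rng.integers(len(frontier))))
        if nxt in component:
            continue
        component.add(nxt)
        frontier.extend(n for n in sorted(hc_lcc.neighbors(nxt)) if n not in component)
    members = sorted(component)

    # densify the planted module with high-confidence edges (complex-like)
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            has = graph.has_edge(u, v) and graph.edges[u, v]["confidence"] > 0.9
            if not has and rng.random() < config.component_density:
                graph.add_edge(u, v, confidence=float(rng.uniform(0.901, 0.999)))
    return GeneNetwork(graph=graph), members


def _area_grade_plan(n_low: int, n_int: int, n_high: int):
    """Per-patient (overall_grade, [(area, area_grade), ...]) assignments.

    Low-grade patients contribute one G1 tumor area; intermediate- and
    high-grade patients contribute a TA1/TA2 pair with TA1 the higher-grade
    nodule.  The default 12/17/10 split reproduces a 26/10/18/12 sample
    composition over G1/G2/G3/G4_5.
    """
    plan = []
    for i in range(n_low):
        plan.append((f"L{i + 1}", "low", [("TA", "G1")]))
    n_g2_ta1 = int(round(7 / 17 * n_int))
    n_g1_ta2 = int(round(14 / 17 * n_int))
    for i in range(n_int):
        ta1 = "G2" if i < n_g2_ta1 else "G3"
        ta2 = "G1" if (i < n_g1_ta2 or ta1 == "G2") else "G2"
        plan.append((f"M{i + 1}", "intermediate", [("TA1", ta1), ("TA2", ta2)]))
    n_g45_ta2 = max(1, int(round(0.2 * n_high))) if n_high else 0
    for i in range(n_high):
        ta2 = "G4_5" if i >= n_high - n_g45_ta2 else "G3"
        plan.append((f"H{i + 1}", "high", [("TA1", "G4_5"), ("TA2", ta2)]))
    return plan


def simulate_survival(scores, log_hazard_ratio: float, shape: float = 1.5,
                      scale: float = 60.0, censor_rate: float = 0.4,
                      rng: np.random.Generator | None = None, seed: int | None = None):
    """Weibull proportional-hazards survival times for the given risk scores.

    The hazard is h(t) = h0(t) * exp(b * score); event times are drawn by
    closed-form inverse sampling.  Censoring is independent, from a Weibull
    with the same shape whose scale is calibrated so that a baseline subject
    is censored with probability ``censor_rate``.  Returns (time, event).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    z = np.asarray(scores, dtype=float)
    u = rng.uniform(size=z.shape)
    t_event = scale * np.exp(-log_hazard_ratio * z / shape) * (-np.log(u)) ** (1.0 / shape)
    if censor_rate <= 0.0:
        return t_event, np.ones_like(t_event, dtype=int)
    c_scale = scale * ((1.0 - censor_rate) / censor_rate) ** (1.0 / shape)
    t_cens = c_scale * (-np.log(rng.uniform(size=z.shape))) ** (1.0 / shape)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _background(rng, n_genes, shares, n_areas_per_patient, sd):
    """Per-sample background: sqrt(rho)*patient-shared + sqrt(1-rho)*area-private."""
    cols = []
    for p, rho in enumerate(shares):
        shared = rng.normal(0.0, sd, size=n_genes)
        for _ in range(n_areas_per_patient[p]):
            private = rng.normal(0.0, sd, size=n_genes)
            cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * private)
    return np.column_stack(cols)


def simulate_cohort(config: SimulationConfig, network: GeneNetwork,
                    component: list[str], seed: int,
                    planted: tuple[str, list[tuple[str, int]]] | None = None
                    ) -> SimulatedCohort:
    """Generate matrices, annotation, survival and truth for one cohort.

    ``planted`` optionally fixes the (target, [(regulator, sign), ...]) pair,
    so an independent validation cohort can share the discovery cohort's
    planted regulator structure.
    """
    if not set(component) <= set(network.graph.nodes):
        raise ValidationError("planted component must be a subset of network nodes")
    rng = np.random.default_rng(seed)
    genes = sorted(network.graph.nodes)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    comp_idx = np.array([gene_pos[g] for g in component], dtype=int)

    plan = _area_grade_plan(*config.n_patients_per_grade)
    patients = [p for p, _, _ in plan]
    n_areas = [len(areas) for _, _, areas in plan]
    sample_rows = []
    for pid, overall, areas in plan:
        for area, grade in areas:
            sample_rows.append({"sample_id": f"{pid}_{area}", "patient_id": pid,
                                "area": area, "area_grade": grade,
                                "overall_grade": overall})
    samples_df = pd.DataFrame(sample_rows)
    sample_ids = samples_df["sample_id"].tolist()
    sample_patient_idx = np.repeat(np.arange(len(plan)), n_areas)

    # per-patient clonal share (common latent factor across layers if coupled)
    def draw_shares():
        if config.clonal_concentration <= 0:
            return np.full(len(plan), config.clonal_share)
        a = config.clonal_share * config.clonal_concentration
        b = (1.0 - config.clonal_share) * config.clonal_concentration
        return rng.beta(a, b, size=len(plan))

    shared_rho = draw_shares()
    layer_rho = {
        layer: (shared_rho if config.coupled_similarity else draw_shares())
        for layer in ("cna", "mrna", "protein")
    }

    # designated target gene and its planted trans-regulators
    target, regulators, reg_signs, target_nbrs = None, [], [], []
    comp_set = set(component)
    if planted is not None:
        target, pairs = planted
        regulators = [g for g, _ in pairs]
        reg_signs = [s for _, s in pairs]
        target_nbrs = [v for v in
                       sorted(network.neighbors_above(target, config.regulator_conf_threshold))
                       if v not in comp_set]
    elif config.n_planted_regulators > 0:
        candidates = [
            (len([v for v in network.neighbors_above(g, config.regulator_conf_threshold)
                  if v not in comp_set]), g)
            for g in genes if g not in comp_set
        ]
        n_nb, target = max(candidates, key=lambda t: (t[0], t[1]))
        if n_nb < config.min_target_neighbors:
            raise ValidationError(
                f"best target has only {n_nb} eligible neighbors "
                f"(< {config.min_target_neighbors})")
        target_nbrs = [v for v in
                       sorted(network.neighbors_above(target, config.regulator_conf_threshold))
                       if v not in comp_set]

    # copy-number instability is concentrated on a subset of segment blocks:
    # the planted component sits in copy-number-quiet regions (its signal is a
    # weak, consistent amplification, not a large event), while the target's
    # network neighborhood is event-prone so the regulator analysis has its
    # candidate pool
    n_blocks = int(np.ceil(n_genes / config.event_block_size))
    block_of = np.arange(n_genes) // config.event_block_size
    component_blocks = {int(block_of[i]) for i in comp_idx}
    unstable = {int(block_of[gene_pos[g]]) for g in target_nbrs} - component_blocks
    n_unstable = max(len(unstable), int(round(config.fraction_unstable_blocks * n_blocks)))
    spare = [b for b in rng.permutation(n_blocks)
             if b not in unstable and b not in component_blocks]
    unstable |= {int(b) for b in spare[:n_unstable - len(unstable)]}
    unstable_mask = np.isin(block_of, sorted(unstable))
    # recurrent events at a locus are directionally consistent (a block is
    # recurrently deleted or recurrently amplified across patients)
    block_sign = rng.choice([-1.0, 1.0], size=n_blocks)

    if target is not None and planted is None:
        # one regulator per event block so planted predictors are not collinear
        eligible = [g for g in target_nbrs if unstable_mask[gene_pos[g]]]
        chosen_blocks: set[int] = set()
        for g in (str(x) for x in rng.permutation(eligible)):
            if block_of[gene_pos[g]] in chosen_blocks:
                continue
            regulators.append(g)
            chosen_blocks.add(block_of[gene_pos[g]])
            if len(regulators) == config.n_planted_regulators:
                break
        reg_signs = [1 if i % 2 == 0 else -1 for i in range(len(regulators))]

    # block-level events; each event is clonal (shared by both tumor areas)
    # with the patient's clonal-share probability, otherwise private to one
    # area; gene participation is subsampled to emulate imperfect
    # segment-to-gene assignment (breaking exact within-block collinearity)
    events = np.zeros((n_genes, len(sample_ids)))
    lo, hi = config.event_magnitude
    area_cols_of = []
    col = 0
    for pid, overall, areas in plan:
        area_cols_of.append(list(range(col, col + len(areas))))
        col += len(areas)

    def add_event(p: int, b: int, force_row: int | None = None) -> None:
        mag = rng.uniform(lo, hi) * block_sign[b]
        area_cols = area_cols_of[p]
        if len(area_cols) == 1 or rng.random() < layer_rho["cna"][p]:
            cols = area_cols
        else:
            cols = [area_cols[int(rng.integers(len(area_cols)))]]
        rows = np.flatnonzero(block_of == b)
        keep = rng.random(rows.size) < config.event_gene_participation
        if force_row is not None:
            keep[rows == force_row] = True
        for j in cols:
            events[rows[keep], j] += mag

    for p in range(len(plan)):
        for b in np.flatnonzero(rng.random(n_blocks) < config.event_rate):
            if b in unstable:
                add_event(p, int(b))

    # planted regulators must be recurrently altered (they would otherwise be
    # removed by the downstream copy-number event filter); top up with extra
    # patient events until each carries enough altered samples
    for g in regulators:
        row = gene_pos[g]
        while (np.abs(events[row]) > 0.5).sum() < config.regulator_event_min:
            add_event(int(rng.integers(len(plan))), int(block_of[row]), force_row=row)

    # planted component amplification, growing with overall patient grade
    mu_pat = np.array([config.mu_cna[overall] for _, overall, _ in plan])
    signal_cna = np.zeros((n_genes, len(sample_ids)))
    signal_cna[np.ix_(comp_idx, np.arange(len(sample_ids)))] = \
        mu_pat[sample_patient_idx][None, :]

    cna = signal_cna + events + _background(
        rng, n_genes, layer_rho["cna"], n_areas, config.noise_sd["cna"])

    # mRNA: attenuated planted signal + regulator trans-effects + own background
    mrna = config.beta_mrna * signal_cna + _background(
        rng, n_genes, layer_rho["mrna"], n_areas, config.noise_sd["mrna"])
    for g, s in zip(regulators, reg_signs):
        mrna[gene_pos[target], :] += s * config.regulator_effect * cna[gene_pos[g], :]

    # protein: buffered transmission of the full mRNA value + own background
    complex_flags = rng.random(n_genes) < config.fraction_complex_members
    beta_eff = np.where(complex_flags,
                        config.beta_prot * config.complex_buffering_factor,
                        config.beta_prot)
    protein = beta_eff[:, None] * mrna + _background(
        rng, n_genes, layer_rho["protein"], n_areas, config.noise_sd["protein"])

    # partial protein detection; the planted module is only partially detected
    detected = rng.random(n_genes) < config.protein_detection_rate
    k = len(comp_idx)
    if k > 1:
        # deterministic partial detection of the planted module (ceil(rate*k),
        # i.e. three of nine members at the defaults)
        n_det = int(np.clip(np.ceil(config.protein_detection_rate * k), 1, k - 1))
        detected[comp_idx] = False
        detected[rng.choice(comp_idx, size=n_det, replace=False)] = True

    mutation = (rng.random((n_genes, len(sample_ids))) < config.mutation_rate).astype(float)

    matrices = {
        "cna": OmicsMatrix("cna", pd.DataFrame(cna, index=genes, columns=sample_ids)),
        "mrna": OmicsMatrix("mrna", pd.DataFrame(mrna, index=genes, columns=sample_ids)),
        "protein": OmicsMatrix("protein", pd.DataFrame(
            protein[detected], index=[g for g, d in zip(genes, detected) if d],
            columns=sample_ids)),
        "mutation": OmicsMatrix("mutation", pd.DataFrame(
            mutation, index=genes, columns=sample_ids)),
    }

    # survival: hazard increases with the realized component CNA dosage (TA1/TA)
    index_area = {"L": "TA", "M": "TA1", "H": "TA1"}
    index_samples = [f"{pid}_{index_area[pid[0]]}" for pid, _, _ in plan]
    col_pos = {s: j for j, s in enumerate(sample_ids)}
    dosage = np.array([cna[comp_idx, col_pos[s]].mean() for s in index_samples])
    z = (dosage - dosage.mean()) / dosage.std(ddof=0) if dosage.std(ddof=0) > 0 \
        else np.zeros_like(dosage)
    time, event = simulate_survival(
        z, config.log_hazard_ratio, shape=config.weibull_shape,
        scale=config.weibull_scale, censor_rate=config.censor_rate, rng=rng)
    burden = np.array([
        (np.abs(cna[:, [col_pos[f"{pid}_{a}"] for a, _ in areas]]) > 0.5).mean()
        for pid, _, areas in plan
    ])
    survival_df = pd.DataFrame({
        "patient_id": patients,
        "time": time,
        "event": event,
        "age": np.round(rng.normal(65.0, 6.0, size=len(plan)), 1),
        "genome_altered_fraction": burden,
    })

    annotation = CohortAnnotation(samples=samples_df, survival=survival_df)
    truth = SyntheticTruth(
        component=list(component),
        target=target,
        regulators=list(zip(regulators, reg_signs)),
        regulator_effects={g: s * config.regulator_effect
                           for g, s in zip(regulators, reg_signs)},
        complex_flags=pd.Series(complex_flags, index=genes, name="complex_member"),
        dosage=pd.Series(z, index=patients, name="component_dosage"),
        config=config,
    )
    return SimulatedCohort(network=network, matrices=matrices,
                           annotation=annotation, truth=truth)


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedCohort:
    """Network + cohort in one call, with per-stage seeds derived from ``seed``."""
    config = config or SimulationConfig()
    net_seed, cohort_seed = (int(s) for s in
                             np.random.SeedSequence(seed).generate_state(2) % (2**31))
    network, component = simulate_network(config, net_seed)
    return simulate_cohort(config, network, component, cohort_seed)
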