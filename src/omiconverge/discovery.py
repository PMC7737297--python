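"""Cross-layer differential sub-network discovery on smoothed fold changes.

For every coverage-filtered network node and each layer, the smoothed values
of the high-grade group (default G4/5) are compared against the reference
group (default G1) with a one-sided Wilcoxon rank-sum test, once for
upregulation and once for downregulation.  Nodes significant (P < alpha,
strict) at all three layers in the same direction form the differential node
set, whose connected components on the high-confidence network are the
reported sub-networks.

No multiple-testing correction is applied by default: the three-layer
intersection is the implicit stringency.  An optional Benjamini-Hochberg
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import rank_sum_matrix
from .data_model import CohortAnnotation, GeneNetwork, ValidationError
from .propagation import SmoothedLayer

#: edge-confidence threshold for *reported* edges (kept iff confidence >= this);
#: membership itself is defined on the propagation (confidence > 0.9) graph
DISPLAY_EDGE_CONFIDENCE = 0.348


@dataclass
class NodeTestTable:
    """Per-node one-sided P values (up and down) for one layer."""

    layer: str
    table: pd.DataFrame            # index: nodes; columns: p_up, p_down
    high_grades: tuple
    ref_grades: tuple
    dedup_policy: str


@dataclass
class ComponentResult:
    direction: str
    nodes: list[str]
    components: list[list[str]]    # ordered by size desc, then smallest member
    edges: list[tuple[str, str, float]]
    display_edges: list[tuple[str, str, float]]


def _dedup_samples(annotation: CohortAnnotation, policy: str) -> set[str]:
    """Sample IDs to drop under the given de-duplication policy.

    ``drop_same_grade_TA2`` removes a patient's second tumor area when it has
    the same grade group as tumor area 1 (robustness variant).
    """
    if policy == "none":
        return set()
    if policy != "drop_same_grade_TA2":
        raise ValidationError(f"unknown dedup policy {policy!r}")
    drop: set[str] = set()
    tum = annotation.tumor_samples()
    for pid, grp in tum.groupby("patient_id"):
        by_area = grp.set_index("area")
        if "TA1" in by_area.index and "TA2" in by_area.index:
            if by_area.loc["TA1", "area_grade"] == by_area.loc["TA2", "area_grade"]:
                drop.add(by_area.loc["TA2", "sample_id"])
    return drop


def per_node_tests(smoothed: SmoothedLayer, annotation: CohortAnnotation,
                   high_grades=("G4_5",), ref_grades=("G1",),
                   dedup_policy: str = "none") -> NodeTestTable:
    """One-sided Wilcoxon rank-sum tests per coverage-filtered node.

    ``p_up`` tests for higher smoothed values in the high-grade group,
    ``p_down`` for lower.  Only nodes passing the protein-coverage filter are
    tested.
    """
    dropped = _dedup_samples(annotation, dedup_policy)
    available = set(smoothed.values.columns)
    high = [s for s in annotation.samples_in_grades(high_grades)
            if s not in dropped and s in available]
    ref = [s for s in annotation.samples_in_grades(ref_grades)
           if s not in dropped and s in available]
    if not high or not ref:
        raise ValidationError("empty group in per-node test")
    nodes = smoothed.coverage_pass[smoothed.coverage_pass].index
    X = smoothed.values.loc[nodes, high].to_numpy()
    Y = smoothed.values.loc[nodes, ref].to_numpy()
    table = pd.DataFrame({
        "p_up": rank_sum_matrix(X, Y, alternative="greater"),
        "p_down": rank_sum_matrix(X, Y, alternative="less"),
    }, index=nodes)
    return NodeTestTable(layer=smoothed.layer, table=table,
                         high_grades=tuple(high_grades), ref_grades=tuple(ref_grades),
                         dedup_policy=dedup_policy)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def cross_layer_intersection(tables: dict[str, NodeTestTable], alpha: float = 0.05,
                             direction: str = "up", adjust: str = "none") -> list[str]:
    """Nodes with P(direction) strictly below alpha in all three layers."""
    for layer in ("cna", "mrna", "protein"):
        if layer not in tables:
            raise ValidationError(f"missing layer {layer!r} in intersection")
    col = f"p_{direction}"
    universe = tables["cna"].table.index
    keep = np.ones(len(universe), dtype=bool)
    for layer in ("cna", "mrna", "protein"):
        p = tables[layer].table[col].reindex(universe).to_numpy()
        if adjust == "bh":
            p = _bh_adjust(p)
        keep &= p < alpha
    return sorted(universe[keep])


def extract_components(nodes, network: GeneNetwork,
                       display_confidence: float = DISPLAY_EDGE_CONFIDENCE) -> ComponentResult:
    """Connected components of the induced subgraph on the filtered network.

    Components are ordered by size descending, ties by smallest lexicographic
    member; singletons are retained.  The display-edge list additionally
    applies the evidence threshold (>=) but never affects membership.
    An empty node set yields an empty result.
    """
    nodes = sorted(set(nodes))
    unknown = [n for n in nodes if n not in network.graph]
    if unknown:
        raise ValidationError(f"nodes absent from the network: {unknown[:5]}")
    sub = network.graph.subgraph(nodes)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    edges = [(u, v, c) for u, v, c in sub.edges(data="confidence")]
    display = [(u, v, c) for u, v, c in edges if c >= display_confidence]
    return ComponentResult(direction="", nodes=nodes, components=comps,
                           edges=sorted(edges), display_edges=sorted(display))


def discover_differential_components(
        smoothed: dict[str, SmoothedLayer], annotation: CohortAnnotation,
        network: GeneNetwork, alpha: float = 0.05,
        high_grades=("G4_5",), ref_grades=("G1",),
        dedup_policy: str = "none", adjust: str = "none") -> dict[str, ComponentResult]:
    """Full discovery step: per-node tests, intersection, components per direction."""
    tables = {layer: per_node_tests(sm, annotation, high_grades, ref_grades, dedup_policy)
              for layer, sm in smoothed.items() if layer in ("cna", "mrna", "protein")}
    results = {}
    for direction in ("up", "down"):
        sig = cross_layer_intersection(tables, alpha=alpha, direction=direction,
                                       adjust=adjust)
        res = extract_components(sig, network)
        res.direction = direction
        results[direction] = res
    results["tables"] = tables
    return results
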