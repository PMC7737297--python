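"""Core containers for multi-omics matrices, gene networks, and cohort annotation.

The pipeline consumes gene-level log2 fold-change matrices (genes x samples)
for up to four molecular layers (mutation, CNA, mRNA, protein), a weighted
gene-interaction network (STRING-style edge list with combined confidence
scores), and a per-sample annotation table with patient identity, tumor-area
labels, histological grade groups, and per-patient survival records.

All on-disk formats are plain TSV; gene and sample identifiers are treated as
opaque strings (no online identifier mapping is ever consulted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("mutation", "cna", "mrna", "protein")

#: grade groups assignable to a tumor area (G4 and G5 are pooled)
AREA_GRADES = ("G1", "G2", "G3", "G4_5")

#: patient-level overall grades
OVERALL_GRADES = ("low", "intermediate", "high")


class ValidationError(ValueError):
    """A container invariant was violated."""


class ParseError(ValueError):
    """An input file could not be parsed."""


@dataclass
class OmicsMatrix:
    """One molecular layer's genes x samples value matrix.

    Values are log2 fold changes versus the benign reference for the
    cna/mrna/protein layers and nonnegative counts (or 0/1 after
    binarization) for the mutation layer.  Missing values (NaN) are allowed:
    protein and mRNA coverage is partial.
    """

    layer: str
    data: pd.DataFrame  # genes in rows, samples in columns

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def measured_genes(self) -> pd.Series:
        """Boolean per gene: has at least one non-missing value."""
        return self.data.notna().any(axis=1)


def read_matrix(path, layer: str) -> OmicsMatrix:
    """Read a genes-x-samples TSV (first column gene IDs, header sample IDs).

    Empty cells and "NA" become missing values.  A non-numeric cell raises
    :class:`ParseError` naming the offending row and column; duplicated gene
    rows raise :class:`ValidationError`.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      na_values=["NA", ""], keep_default_na=False)
    raw.index = raw.index.astype(str)
    data = raw.apply(pd.to_numeric, errors="coerce")
    bad = data.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {raw.iat[r, c]!r} at gene {data.index[r]!r}, "
            f"sample {data.columns[c]!r} in {path}"
        )
    return OmicsMatrix(layer=layer, data=data)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix in the TSV format :func:`read_matrix` accepts."""
    out = matrix.data.copy()
    out.index.name = "gene"
    # repr-level float formatting keeps a read/write round trip lossless
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


@dataclass
class GeneNetwork:
    """Undirected gene graph with per-edge combined confidence in [0, 1]."""

    graph: nx.Graph
    min_confidence: float | None = None  # threshold already applied, if any
    lcc_reduced: bool = False

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("network contains self-loops")
        for u, v, c in self.graph.edges(data="confidence"):
            if c is None or not (0.0 <= c <= 1.0):
                raise ValidationError(f"edge ({u}, {v}) confidence {c} outside [0, 1]")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence_filter(self, min_confidence: float) -> "GeneNetwork":
        """Keep an edge iff its confidence is strictly greater than the threshold.

        Mirrors the removal of STRING edges with combined score "smaller or
        equal to" the cutoff.  Nodes are retained even if they lose all edges.
        """
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(
            (u, v, {"confidence": c})
            for u, v, c in self.graph.edges(data="confidence")
            if c > min_confidence
        )
        return GeneNetwork(graph=g, min_confidence=min_confidence, lcc_reduced=False)

    def largest_connected_component(self) -> "GeneNetwork":
        if self.graph.number_of_nodes() == 0:
            raise ValidationError("cannot reduce an empty network")
        lcc = max(nx.connected_components(self.graph), key=lambda c: (len(c), sorted(c)[0]))
        g = self.graph.subgraph(lcc).copy()
        return GeneNetwork(graph=g, min_confidence=self.min_confidence, lcc_reduced=True)

    def neighbors_above(self, node: str, min_confidence: float) -> list[str]:
        """Neighbors connected by an edge with confidence > min_confidence."""
        return [
            v for v in self.graph.neighbors(node)
            if self.graph.edges[node, v]["confidence"] > min_confidence
        ]


def read_network(path, min_confidence: float | None = None,
                 reduce_to_lcc: bool = False) -> GeneNetwork:
    """Read a 3-column TSV edge list (nodeA, nodeB, confidence).

    Confidence may be on the [0, 1] or STRING's [0, 1000] scale; if any value
    exceeds 1 the whole column is divided by 1000.  A header line is skipped if
    its third field is non-numeric.  Duplicate edges keep the maximum
    confidence; self-loops are dropped.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                conf = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric confidence {raw!r}") from None
            edges.append((a, b, conf))
    if not edges:
        raise ParseError(f"{path}: no edges found")
    if max(c for _, _, c in edges) > 1.0:
        edges = [(a, b, c / 1000.0) for a, b, c in edges]
    g = nx.Graph()
    for a, b, c in edges:
        if a == b:
            continue
        if g.has_edge(a, b):
            g.edges[a, b]["confidence"] = max(g.edges[a, b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    net = GeneNetwork(graph=g)
    if min_confidence is not None:
        net = net.confidence_filter(min_confidence)
        if net.n_edges == 0:
            raise ValidationError(
                f"network empty after filtering at confidence > {min_confidence}"
            )
    if reduce_to_lcc:
        net = net.largest_connected_component()
    return net


def write_network(network: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("nodeA\tnodeB\tconfidence\n")
        for u, v, c in sorted(network.graph.edges(data="confidence")):
            fh.write(f"{u}\t{v}\t{c:.6g}\n")


ANNOTATION_COLUMNS = ["sample_id", "patient_id", "area", "area_grade", "overall_grade"]
SURVIVAL_COLUMNS = ["patient_id", "time", "event", "age", "genome_altered_fraction"]


@dataclass
class CohortAnnotation:
    """Per-sample annotation plus per-patient survival records.

    ``samples`` columns: sample_id, patient_id, area (BPH/TA/TA1/TA2),
    area_grade (G1/G2/G3/G4_5), overall_grade (low/intermediate/high).
    ``survival`` columns: patient_id, time (months), event (0/1), optional
    age (years) and genome_altered_fraction (proportion).
    """

    samples: pd.DataFrame
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if self.samples["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in annotation")
        bad = set(self.samples["area_grade"]) - set(AREA_GRADES) - {np.nan}
        if bad:
            raise ValidationError(f"unknown area grades {bad}")
        if self.survival is not None:
            if (self.survival["time"] < 0).any():
                raise ValidationError("negative survival time")
            if not self.survival["event"].isin([0, 1]).all():
                raise ValidationError("event indicator must be 0/1")

    def tumor_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["area"] != "BPH"]

    def samples_in_grades(self, grades) -> list[str]:
        tum = self.tumor_samples()
        return tum.loc[tum["area_grade"].isin(set(grades)), "sample_id"].tolist()

    def paired_patients(self) -> list[str]:
        """Patients with both TA1 and TA2 areas annotated."""
        tum = self.tumor_samples()
        counts = tum.groupby("patient_id")["area"].apply(set)
        return sorted(p for p, areas in counts.items() if {"TA1", "TA2"} <= areas)

    def sample_of(self, patient_id: str, area: str) -> str:
        sel = self.samples[
            (self.samples["patient_id"] == patient_id) & (self.samples["area"] == area)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique sample for patient {patient_id} area {area}")
        return sel["sample_id"].iloc[0]


def read_annotation(sample_path, survival_path=None) -> CohortAnnotation:
    samples = pd.read_csv(sample_path, sep="\t", dtype=str)
    survival = None
    if survival_path is not None:
        survival = pd.read_csv(survival_path, sep="\t")
        survival["patient_id"] = survival["patient_id"].astype(str)
    return CohortAnnotation(samples=samples, survival=survival)


def write_annotation(annotation: CohortAnnotation, sample_path, survival_path=None) -> None:
    annotation.samples.to_csv(sample_path, sep="\t", index=False)
    if survival_path is not None and annotation.survival is not None:
        annotation.survival.to_csv(survival_path, sep="\t", index=False, na_rep="NA")


@dataclass
class GeneMapping:
    """Raw symbol -> network node mapping with first-occurrence resolution.

    Both directions of ambiguity are resolved by keeping the first mapping in
    file (or input) order: a symbol maps to at most one node, and a node
    receives at most one symbol.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "GeneMapping":
        mapping: dict[str, str] = {}
        used_nodes: set[str] = set()
        for symbol, node in pairs:
            if symbol in mapping or node in used_nodes:
                logger.warning("dropping ambiguous mapping %s -> %s (first mapping kept)",
                               symbol, node)
                continue
            mapping[symbol] = node
            used_nodes.add(node)
        return cls(mapping=mapping)

    def apply(self, matrix: OmicsMatrix) -> OmicsMatrix:
        """Rename gene rows to network nodes, dropping unmapped/duplicate rows."""
        keep_rows, new_names = [], []
        seen: set[str] = set()
        for g in matrix.genes:
            node = self.mapping.get(g)
            if node is None or node in seen:
                continue
            keep_rows.append(g)
            new_names.append(node)
            seen.add(node)
        data = matrix.data.loc[keep_rows]
        data.index = pd.Index(new_names)
        return OmicsMatrix(layer=matrix.layer, data=data)


@dataclass
class AlignedDataset:
    """Per-layer matrices re-indexed on the full network node set.

    Measured genes carry their values; network nodes absent from a layer are
    zero-filled for propagation input but flagged unmeasured, so downstream
    filters can distinguish a measured 0 from an absent gene.  Missing cells
    within measured genes are also zero-filled in ``layers`` (the propagation
    input must be numeric) but remain visible through the original matrices.
    """

    layers: dict[str, pd.DataFrame]          # node x sample, zero-filled
    measured: dict[str, pd.Series]           # per node: measured in this layer?
    dropped: dict[str, list[str]]            # genes absent from the network
    nodes: list[str]


def harmonize(matrices: dict[str, OmicsMatrix], network: GeneNetwork,
              mapping: GeneMapping | None = None) -> AlignedDataset:
    """Align every layer onto the network node universe.

    Genes not present in the network are dropped (and logged); network nodes
    missing from a layer are zero-filled and flagged unmeasured.  Raises
    :class:`ValidationError` if a layer has no overlap with the network.
    """
    nodes = list(network.graph.nodes)
    node_index = pd.Index(nodes)
    layers: dict[str, pd.DataFrame] = {}
    measured: dict[str, pd.Series] = {}
    dropped: dict[str, list[str]] = {}
    for layer, matrix in matrices.items():
        if mapping is not None:
            matrix = mapping.apply(matrix)
        in_net = [g for g in matrix.genes if g in node_index]
        out_net = [g for g in matrix.genes if g not in node_index]
        if not in_net:
            raise ValidationError(f"layer {layer!r}: no genes overlap the network")
        if out_net:
            logger.warning("layer %s: dropping %d genes absent from the network",
                           layer, len(out_net))
        present = matrix.data.loc[in_net]
        meas = present.notna().any(axis=1).reindex(node_index, fill_value=False)
        full = present.reindex(node_index).fillna(0.0)
        layers[layer] = full
        measured[layer] = meas
        dropped[layer] = out_net
    return AlignedDataset(layers=layers, measured=measured, dropped=dropped, nodes=nodes)
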