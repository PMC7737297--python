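"""Network propagation (random-walk smoothing) of per-sample fold changes.

Node scores F0 are diffused over the confidence-filtered interaction network
by iterating

    F <- alpha * W' F + (1 - alpha) * F0

where W' = D^(-1/2) A D^(-1/2) is the symmetrically normalized adjacency of
the unweighted graph.  With 0 < alpha < 1 the iteration contracts
geometrically to the unique solution of (I - alpha W') F = (1 - alpha) F0;
a fixed iteration count (default 500) is used for bit-reproducibility, with
an optional tolerance-based early stop.

Signed fold changes are propagated as-is: the downstream tests look at both
up- and down-regulation of the smoothed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import GeneNetwork, ValidationError


@dataclass
class PropagationConfig:
    alpha: float = 0.5
    n_iterations: int = 500
    tolerance: float | None = None  # optional max-abs early stop, off by default

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


@dataclass
class SmoothedLayer:
    """Smoothed node x sample values plus the protein-coverage pass flags."""

    layer: str
    values: pd.DataFrame
    coverage_pass: pd.Series


def normalized_adjacency(network: GeneNetwork) -> tuple[sp.csr_matrix, list[str]]:
    """Symmetrically normalized binary adjacency W' = D^(-1/2) A D^(-1/2).

    Requires every node to have at least one edge (guaranteed after reduction
    to the largest connected component); the spectral radius of W' is <= 1.
    """
    nodes = list(network.graph.nodes)
    A = nx_adjacency(network, nodes)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        isolated = [nodes[i] for i in np.flatnonzero(deg == 0)[:5]]
        raise ValidationError(f"isolated nodes (degree 0): {isolated}")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A @ D).tocsr(), nodes


def nx_adjacency(network: GeneNetwork, nodes: list[str]) -> sp.csr_matrix:
    """Binary adjacency in the given node order."""
    import networkx as nx

    A = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, weight=None,
                                 format="csr", dtype=float)
    return sp.csr_matrix(A)


def propagate(F0, W: sp.csr_matrix, config: PropagationConfig | None = None):
    """Iterated propagation of F0 (vector, matrix, or node x sample DataFrame).

    Returns the smoothed values in the same container type and shape.
    The operation is linear in F0 and odd (propagate(-F0) = -propagate(F0)).
    """
    config = config or PropagationConfig()
    is_frame = isinstance(F0, pd.DataFrame)
    arr = F0.to_numpy(dtype=float) if is_frame else np.asarray(F0, dtype=float)
    if arr.shape[0] != W.shape[0]:
        raise ValidationError(
            f"F0 has {arr.shape[0]} rows but the network has {W.shape[0]} nodes"
        )
    F = arr.copy()
    base = (1.0 - config.alpha) * arr
    for _ in range(config.n_iterations):
        F_new = config.alpha * (W @ F) + base
        if config.tolerance is not None and np.max(np.abs(F_new - F)) < config.tolerance:
            F = F_new
            break
        F = F_new
    if is_frame:
        return pd.DataFrame(F, index=F0.index, columns=F0.columns)
    return F


def protein_coverage_filter(network: GeneNetwork, protein_measured: pd.Series) -> pd.Series:
    """Nodes with a protein measurement themselves or on a direct neighbor.

    ``protein_measured`` is the per-node measured flag from harmonization
    (a zero-filled unmeasured node is *not* measured).  Returns a boolean
    Series over the network nodes.
    """
    nodes = list(network.graph.nodes)
    measured = protein_measured.reindex(nodes, fill_value=False).astype(bool)
    passes = measured.copy()
    for node in nodes:
        if passes[node]:
            continue
        if any(measured[nbr] for nbr in network.graph.neighbors(node)):
            passes[node] = True
    return passes


def smooth_layer(layer: str, values: pd.DataFrame, network: GeneNetwork,
                 protein_measured: pd.Series,
                 config: PropagationConfig | None = None) -> SmoothedLayer:
    """Propagate one harmonized layer and attach the coverage flags."""
    W, nodes = normalized_adjacency(network)
    aligned = values.reindex(nodes).fillna(0.0)
    smoothed = propagate(aligned, W, config)
    coverage = protein_coverage_filter(network, protein_measured)
    return SmoothedLayer(layer=layer, values=smoothed, coverage_pass=coverage)
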