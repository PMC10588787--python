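"""Gaussian-graphical-model selection and sub-network extraction.

Each omics block is reduced to candidate sub-networks: a sparse
conditional-independence graph is estimated by neighborhood selection
(one L1-penalized regression of every analyte on all others), edges are
kept where both (AND) or either (OR) direction selects the pair, and the
connected components of the resulting graph are the block's sub-networks.

The sparsity is governed by a single scalar multiplier K on the universal
penalty: node j is regressed with

    lambda_j(K) = K * sigma_j * sqrt(2 * log(p) / n)

on internally standardized data (sigma_j is the response's sample sd on
that scale, i.e. 1 up to rounding). K is swept over a grid — 1 to 6 in
steps of 0.5 by default — and the downstream set analysis picks the K that
yields the most contrast-associated sub-networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .containers import AnalyteMatrix, TriomicsError

DEFAULT_K_GRID: Tuple[float, ...] = tuple(np.arange(1.0, 6.01, 0.5))

FAMILY_AND = "neighborhood_and"
FAMILY_OR = "neighborhood_or"


@dataclass
class GGMGraph:
    block_label: str
    K: float
    adjacency: pd.DataFrame  # symmetric boolean, zero diagonal

    def __post_init__(self) -> None:
        a = self.adjacency.to_numpy()
        if a.shape[0] != a.shape[1] or not (a == a.T).all():
            raise TriomicsError("adjacency must be square and symmetric")
        if np.diag(a).any():
            raise TriomicsError("adjacency must have a zero diagonal")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adjacency.index)
        a = self.adjacency.to_numpy()
        ids = list(self.adjacency.index)
        for i, j in zip(*np.nonzero(np.triu(a, k=1))):
            g.add_edge(ids[i], ids[j])
        return g


@dataclass(frozen=True)
class SubNetwork:
    """A connected analyte set (size >= 2) from one selected graph."""

    block_label: str
    members: Tuple[str, ...]
    K: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise TriomicsError("a sub-network needs at least 2 members")

    @property
    def id(self) -> str:
        return f"{self.block_label}:" + "+".join(self.members)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class KSweepResult:
    grid: Tuple[float, ...]
    graphs: Dict[float, Dict[str, GGMGraph]] = field(default_factory=dict)
    subnetworks: Dict[float, List[SubNetwork]] = field(default_factory=dict)

    def component_counts(self) -> pd.DataFrame:
        rows = [
            {
                "K": K,
                "n_subnetworks": len(subs),
                "n_edges": sum(g.n_edges for g in self.graphs[K].values()),
            }
            for K, subs in self.subnetworks.items()
        ]
        return pd.DataFrame(rows)


def select_graph(
    matrix: AnalyteMatrix, K: float, family: str = FAMILY_AND
) -> GGMGraph:
    """Neighborhood-selection graph of one block at penalty multiplier K."""
    if family not in (FAMILY_AND, FAMILY_OR):
        raise TriomicsError(f"unknown family {family!r}")
    matrix.require_complete("graph selection requires a complete matrix")
    n, p = matrix.values.shape
    if n < 5:
        raise TriomicsError("graph selection needs at least 5 samples")
    if p < 2:
        raise TriomicsError("graph selection needs at least 2 analytes")
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        flat = list(matrix.analyte_ids[sd == 0])
        raise TriomicsError(
            f"constant analyte(s) {flat[:5]}: filter before graph selection"
        )
    Z = (X - X.mean(axis=0)) / sd

    base = np.sqrt(2.0 * np.log(p) / n)
    selected = np.zeros((p, p), dtype=bool)
    if np.isfinite(K):
        for j in range(p):
            others = np.delete(np.arange(p), j)
            y = Z[:, j]
            sigma_j = y.std(ddof=1)  # ~1 after standardization
            lam = K * sigma_j * base
            model = Lasso(alpha=lam, fit_intercept=False, max_iter=10_000)
            model.fit(Z[:, others], y)
            selected[j, others] = model.coef_ != 0
    if family == FAMILY_AND:
        adj = selected & selected.T
    else:
        adj = selected | selected.T
    np.fill_diagonal(adj, False)
    ids = matrix.analyte_ids
    return GGMGraph(
        block_label=matrix.block_label,
        K=float(K),
        adjacency=pd.DataFrame(adj, index=ids, columns=ids),
    )


def extract_subnetworks(graph: GGMGraph, min_size: int = 2) -> List[SubNetwork]:
    """Connected components of size >= min_size, largest first then lexical."""
    g = graph.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), c))
    return [
        SubNetwork(block_label=graph.block_label, members=tuple(c), K=graph.K)
        for c in comps
    ]


def sweep_K(
    matrices: Dict[str, AnalyteMatrix],
    grid: Sequence[float] = DEFAULT_K_GRID,
    family: str = FAMILY_AND,
    min_size: int = 2,
) -> KSweepResult:
    """Select graphs and sub-networks for every K in the grid, per block."""
    grid = tuple(float(k) for k in grid)
    if not grid:
        raise TriomicsError("K grid must be non-empty")
    if any(b >= a for a, b in zip(grid[1:], grid)):
        raise TriomicsError("K grid must be strictly increasing")
    result = KSweepResult(grid=grid)
    for K in grid:
        graphs: Dict[str, GGMGraph] = {}
        subs: List[SubNetwork] = []
        for block, matrix in matrices.items():
            try:
                graph = select_graph(matrix, K, family=family)
            except TriomicsError as err:
                raise TriomicsError(f"K={K}, block {block!r}: {err}") from err
            graphs[block] = graph
            subs.extend(extract_subnetworks(graph, min_size=min_size))
        result.graphs[K] = graphs
        result.subnetworks[K] = subs
    return result


def graph_to_edge_table(graph: GGMGraph) -> pd.DataFrame:
    ids = list(graph.adjacency.index)
    a = graph.adjacency.to_numpy()
    rows = [
        {"source": ids[i], "target": ids[j], "K": graph.K, "block": graph.block_label}
        for i, j in zip(*np.nonzero(np.triu(a, k=1)))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "K", "block"])
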