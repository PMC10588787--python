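"""Cross-omics integration: variable pooling and the partial-correlation net.

For each contrast, the significant single analytes of all three blocks
(those not already represented through a chosen sub-network), every chosen
sub-network's principal-component scores, and the two covariates age and
sex are pooled into one samples × variables table. Partial correlations
between all pairs of columns — each conditioned on all remaining columns —
are computed from the inverse of the correlation matrix,

    R_ij = -P_ij / sqrt(P_ii * P_jj),  P = C^{-1},

and the integration network keeps exactly the edges with |R| strictly
above the threshold (0.6 by default), annotating nodes with their log2
fold-change for the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AnalyteMatrix, SampleMeta, TriomicsError, warn
from .linear_models import ContrastResult
from .set_analysis import SubNetworkSummary

EDGE_THRESHOLD = 0.6
RIDGE_DEFAULT = 1e-3


@dataclass
class VariableSet:
    """Pooled variables for one contrast: one row per sample."""

    data: pd.DataFrame
    contrast: str
    provenance: pd.DataFrame  # column -> kind/block/subnetwork

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dup = list(self.data.columns[self.data.columns.duplicated()])
            raise TriomicsError(f"duplicate variable columns: {dup[:5]}")
        if self.data.isna().to_numpy().any():
            raise TriomicsError("variable set must be complete")

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]


@dataclass
class PartialCorrelationMatrix:
    matrix: pd.DataFrame
    conditioning: str = "all-remaining-columns"
    ridge: float = 0.0

    def __post_init__(self) -> None:
        a = self.matrix.to_numpy()
        if not np.allclose(a, a.T, atol=1e-8):
            raise TriomicsError("partial-correlation matrix must be symmetric")


def build_variable_set(
    results: ContrastResult,
    summaries: Sequence[SubNetworkSummary],
    matrices: Dict[str, AnalyteMatrix],
    meta: SampleMeta,
    contrast: str,
) -> VariableSet:
    """Pool significant singles, sub-network PCs, age and sex for a contrast.

    An analyte that is both individually significant and a member of a
    summarized sub-network enters only through the sub-network PC
    (de-duplication).
    """
    covered = {
        m for s in summaries for m in s.subnetwork.members
    }
    columns: Dict[str, pd.Series] = {}
    prov_rows: List[dict] = []
    sample_ids = meta.sample_ids

    sub = results.table[
        (results.table["contrast"] == contrast) & results.table["significant"]
    ]
    for _, row in sub.iterrows():
        analyte, block = row["analyte"], row["block"]
        if analyte in covered:
            continue
        matrix = matrices[block]
        matrix.require_complete("variable pooling requires imputed matrices")
        series = matrix.values[analyte]
        if analyte in columns:
            raise TriomicsError(f"duplicate variable column {analyte!r}")
        columns[analyte] = series.loc[sample_ids]
        prov_rows.append({"column": analyte, "kind": "analyte", "block": block})

    for summary in summaries:
        for comp in summary.scores.columns:
            name = f"{summary.subnetwork.id}|{comp}"
            if name in columns:
                raise TriomicsError(f"duplicate variable column {name!r}")
            columns[name] = summary.scores[comp].loc[sample_ids]
            prov_rows.append(
                {
                    "column": name,
                    "kind": "subnetwork_pc",
                    "block": summary.subnetwork.block_label,
                }
            )

    columns["age"] = meta.age
    columns["sex"] = meta.sex
    prov_rows.append({"column": "age", "kind": "covariate", "block": ""})
    prov_rows.append({"column": "sex", "kind": "covariate", "block": ""})

    data = pd.DataFrame(columns, index=sample_ids)
    provenance = pd.DataFrame(prov_rows).set_index("column")
    return VariableSet(data=data, contrast=contrast, provenance=provenance)


def partial_correlations(
    varset: VariableSet, ridge: Optional[float] = None
) -> PartialCorrelationMatrix:
    """Full-order partial correlations between all variable-set columns.

    Each pair is conditioned on every remaining column (the convention of
    the usual partial-correlation packages). When the sample count does not
    comfortably exceed the column count the correlation matrix is made
    invertible with a small ridge on its diagonal; pass ``ridge`` to force
    or disable (0) regularization.
    """
    data = varset.data
    n, k = data.shape
    if k < 3:
        raise TriomicsError("partial correlations need at least 3 columns")
    sd = data.to_numpy().std(axis=0, ddof=1)
    if (sd == 0).any():
        flat = list(data.columns[sd == 0])
        raise TriomicsError(f"constant variable(s) {flat[:5]} in the variable set")
    corr = np.corrcoef(data.to_numpy(), rowvar=False)
    if ridge is None:
        ridge = 0.0 if n > k + 2 else RIDGE_DEFAULT
        if ridge:
            warn(
                f"n_samples={n} close to n_variables={k}: applying ridge "
                f"{ridge} to the correlation diagonal"
            )
    if ridge:
        corr = corr + np.eye(k) * ridge
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError as err:
        raise TriomicsError(
            "singular correlation matrix; enable ridge regularization "
            "(partial_correlations(..., ridge=1e-3))"
        ) from err
    d = np.sqrt(np.diag(prec))
    R = -prec / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return PartialCorrelationMatrix(
        matrix=pd.DataFrame(R, index=data.columns, columns=data.columns),
        ridge=float(ridge),
    )


@dataclass
class IntegrationNetwork:
    graph: nx.Graph
    contrast: str
    threshold: float = EDGE_THRESHOLD

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"node": node, **attrs} for node, attrs in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "R": attrs["R"]}
            for u, v, attrs in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "R"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    pcm: PartialCorrelationMatrix,
    node_attrs: pd.DataFrame,
    contrast: str,
    threshold: float = EDGE_THRESHOLD,
) -> IntegrationNetwork:
    """Threshold the partial-correlation matrix into the contrast network.

    Edges appear exactly where |R| is strictly greater than ``threshold``;
    isolated nodes are kept so the node set always equals the variable set.
    ``node_attrs`` must be indexed by node id (columns such as kind, block,
    log2fc, subnetwork membership are copied onto the nodes).
    """
    ids = list(pcm.matrix.index)
    missing = [i for i in ids if i not in node_attrs.index]
    if missing:
        raise TriomicsError(f"node attributes missing for: {missing[:5]}")
    g = nx.Graph()
    for node in ids:
        attrs = {
            k: v
            for k, v in node_attrs.loc[node].items()
            if v is not None and not (isinstance(v, float) and np.isnan(v))
        }
        g.add_node(node, **attrs)
    R = pcm.matrix.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(R[i, j]) > threshold:
                g.add_edge(ids[i], ids[j], R=float(R[i, j]))
    return IntegrationNetwork(graph=g, contrast=contrast, threshold=threshold)
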