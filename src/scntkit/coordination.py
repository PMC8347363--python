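"""Coordinated expression of key target genes.

Pairwise Pearson correlation (PCC) of log2(FPKM+1) across a group's
samples quantifies how tightly a set of key downstream genes — epigenetic
modifiers and pluripotency factors — moves together.  Pairs above a PCC
cut (default 0.55) form an undirected co-expression network, over which
directed TF -> target regulon edges are overlaid.  Normally developing
embryos show a dense, coordinated block; arrested nuclear-transfer embryos
lose much of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, RegulonSet, SampleSheet, group_mean, log2p1

__all__ = ["CorrelationMatrix", "pcc_matrix", "coordination_network"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric PCC matrix with a validity mask for zero-variance genes."""

    gene_ids: tuple[str, ...]
    values: pd.DataFrame  # genes x genes, NaN where undefined
    valid: pd.Series  # per gene: had non-zero variance

    def defined_pairs(self) -> list[tuple[str, str, float]]:
        """Upper-triangle (i < j) pairs with a defined correlation."""
        out = []
        ids = self.gene_ids
        arr = self.values.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if np.isfinite(arr[i, j]):
                    out.append((ids[i], ids[j], float(arr[i, j])))
        return out


def pcc_matrix(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    group: str,
    genes,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation over a group's samples.

    Computed on log2(FPKM+1) across individual samples (cells), not group
    means.  Requires >= 3 samples; genes with zero variance within the
    group yield masked (NaN) rows/columns and a warning.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for a correlation matrix")
    samples = [s for s in sheet.samples_in_group(group) if s in expr.data.columns]
    if len(samples) < 3:
        raise ValueError(
            f"group {group!r} has {len(samples)} sample(s); >= 3 required for PCC"
        )
    sub = expr.subset_genes(genes)
    logvals = log2p1(sub.data[samples].to_numpy())
    sd = logvals.std(axis=1)
    valid = sd > 0
    if (~valid).any():
        bad = [g for g, v in zip(sub.gene_ids, valid) if not v]
        warnings.warn(f"zero-variance gene(s) in group {group!r} masked: {bad[:5]}")

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logvals)
    corr = np.asarray(corr, dtype=float)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    corr = np.clip(corr, -1.0, 1.0)

    ids = tuple(sub.gene_ids)
    return CorrelationMatrix(
        gene_ids=ids,
        values=pd.DataFrame(corr, index=list(ids), columns=list(ids)),
        valid=pd.Series(valid, index=list(ids)),
    )


def coordination_network(
    corr: CorrelationMatrix,
    regulons: RegulonSet | None,
    condition: str | None,
    core_tfs=(),
    *,
    threshold: float = 0.55,
    expr: ExpressionMatrix | None = None,
    sheet: SampleSheet | None = None,
    expression_group: str | None = None,
) -> nx.MultiDiGraph:
    """Thresholded co-expression network with a regulatory overlay.

    Undirected PCC edges (stored as reciprocal directed pairs tagged
    ``kind="coexpression"``) connect gene pairs with defined PCC >=
    ``threshold``; directed ``kind="regulation"`` edges are taken from the
    given condition's regulons restricted to the node set (key genes plus
    core TFs).  Node attribute ``mean_log_expr`` holds the group-mean
    log2(FPKM+1) when expression is supplied.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    nodes = list(corr.gene_ids) + [tf for tf in core_tfs if tf not in corr.gene_ids]
    if not nodes:
        raise ValueError("empty node set")

    g = nx.MultiDiGraph()
    for n in nodes:
        g.add_node(n, role="core_tf" if n in set(core_tfs) else "key_gene")

    for a, b, r in corr.defined_pairs():
        if r >= threshold:
            g.add_edge(a, b, kind="coexpression", pcc=r)
            g.add_edge(b, a, kind="coexpression", pcc=r)

    if regulons is not None and condition is not None:
        edges = regulons.for_condition(condition)
        node_set = set(nodes)
        sel = edges.loc[edges["tf"].isin(node_set) & edges["target"].isin(node_set)]
        for _, row in sel.iterrows():
            g.add_edge(row["tf"], row["target"], kind="regulation",
                       weight=float(row["weight"]))

    if expr is not None and sheet is not None and expression_group is not None:
        means = group_mean(expr, sheet, expression_group)
        for n in g.nodes:
            if n in means.index:
                g.nodes[n]["mean_log_expr"] = float(log2p1(means.loc[n]))
    return g


def coexpression_edge_count(graph: nx.MultiDiGraph) -> int:
    """Number of undirected co-expression edges in a coordination network."""
    return sum(1 for _, _, d in graph.edges(data=True)
               if d.get("kind") == "coexpression") // 2
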