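"""Regulon target-universe comparison, dysregulation filters, core-TF
selection and condition-specific subnetwork extraction.

The regulatory picture is taken as given: each condition carries a set of
TF -> target edges (e.g. exported from a SCENIC-style inference run).  The
operations here compare the target universes regulated by pathway TFs
between conditions, flag targets whose expression differs more than a fold
threshold, rank TFs by regulon size to pick the core factors of each
pathway, and cut out the subnetwork of edges present in one condition but
absent in a contrast condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, RegulonSet, SampleSheet, group_mean

__all__ = [
    "VennPartition",
    "CoreTFSelection",
    "target_union",
    "venn_partition",
    "fold_change_filter",
    "select_core_tfs",
    "extract_subnetwork",
    "subnetwork_to_graph",
]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint decomposition of two conditions' target universes."""

    condition_a: str
    condition_b: str
    shared: frozenset[str]
    a_specific: frozenset[str]
    b_specific: frozenset[str]

    def __post_init__(self) -> None:
        assert not self.shared & self.a_specific
        assert not self.shared & self.b_specific
        assert not self.a_specific & self.b_specific

    @property
    def targets_a(self) -> frozenset[str]:
        return self.shared | self.a_specific

    @property
    def targets_b(self) -> frozenset[str]:
        return self.shared | self.b_specific

    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            f"{self.condition_a}_specific": len(self.a_specific),
            f"{self.condition_b}_specific": len(self.b_specific),
        }


def target_union(
    regulons: RegulonSet,
    condition: str,
    tfs: set[str] | list[str] | None = None,
) -> set[str]:
    """Union of target genes over a condition's (optionally filtered) TFs."""
    edges = regulons.for_condition(condition)
    if tfs is not None:
        edges = edges.loc[edges["tf"].isin(set(tfs))]
        if edges.empty:
            warnings.warn(
                f"no regulon edges for condition {condition!r} after TF filter"
            )
            return set()
    return set(edges["target"])


def venn_partition(
    regulons: RegulonSet,
    condition_a: str,
    condition_b: str,
    tf_filter: set[str] | list[str] | None = None,
) -> VennPartition:
    """Shared / A-specific / B-specific target genes of two conditions."""
    ta = target_union(regulons, condition_a, tf_filter)
    tb = target_union(regulons, condition_b, tf_filter)
    return VennPartition(
        condition_a,
        condition_b,
        shared=frozenset(ta & tb),
        a_specific=frozenset(ta - tb),
        b_specific=frozenset(tb - ta),
    )


def fold_change_filter(
    genes,
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    *,
    ratio_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify genes by pseudocounted group-mean FPKM ratio.

    ``ratio = (mean_a + pseudocount) / (mean_b + pseudocount)``; class is
    ``A_over_B`` when ratio > threshold, ``B_over_A`` when 1/ratio >
    threshold, ``neither`` otherwise.  Genes absent from the matrix are
    dropped with a warning.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    present = [g for g in genes if g in expr.data.index]
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} gene(s) absent from matrix dropped")
    if not present:
        raise ValueError("no requested genes present in the expression matrix")
    mean_a = group_mean(expr, sheet, group_a).loc[present]
    mean_b = group_mean(expr, sheet, group_b).loc[present]
    ratio = (mean_a + pseudocount) / (mean_b + pseudocount)
    cls = np.where(
        ratio > ratio_threshold,
        "A_over_B",
        np.where(1.0 / ratio > ratio_threshold, "B_over_A", "neither"),
    )
    return pd.DataFrame(
        {"gene_id": present, "ratio": ratio.to_numpy(), "class": cls}
    )


@dataclass(frozen=True)
class CoreTFSelection:
    """Ranked regulon sizes and the selected core TFs of one pathway."""

    pathway: str
    rankings: dict[str, list[tuple[str, int]]]  # condition -> [(tf, n_targets)]
    selected: tuple[str, ...]


def select_core_tfs(
    regulons: RegulonSet,
    geneset: GeneSet,
    conditions: list[str] | tuple[str, ...],
    k: int = 2,
) -> CoreTFSelection:
    """Core TFs of a pathway: within top ``k`` by regulon size in *every*
    listed condition.

    Ranking is by descending target count, ties broken lexicographically by
    gene id.  Only pathway members with at least one regulon edge are
    ranked.
    """
    members = set(geneset.genes)
    rankings: dict[str, list[tuple[str, int]]] = {}
    top_sets: list[set[str]] = []
    for condition in conditions:
        edges = regulons.for_condition(condition)
        edges = edges.loc[edges["tf"].isin(members)]
        counts = edges.groupby("tf")["target"].nunique()
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rankings[condition] = [(tf, int(n)) for tf, n in ranked]
        top_sets.append({tf for tf, _ in ranked[:k]})
    if any(not r for r in rankings.values()):
        warnings.warn(f"pathway {geneset.name!r} has no regulon-bearing TF in some condition")
        return CoreTFSelection(geneset.name, rankings, ())
    selected = set.intersection(*top_sets) if top_sets else set()
    if not selected:
        warnings.warn(
            f"pathway {geneset.name!r}: no TF ranks within top {k} in every condition"
        )
    return CoreTFSelection(geneset.name, rankings, tuple(sorted(selected)))


def select_core_tfs_all(
    regulons: RegulonSet,
    genesets: GeneSetCollection,
    conditions: list[str] | tuple[str, ...],
    k_per_pathway: dict[str, int] | int = None,
) -> dict[str, CoreTFSelection]:
    """Run the core-TF screen for every pathway.

    ``k_per_pathway`` may be one integer for all pathways or a mapping; the
    default screens the top 2 per pathway except the largest pathway (top 1),
    reproducing the shape of a five-factor core screen over three pathways.
    """
    if k_per_pathway is None:
        sizes = {s.name: len(s.genes) for s in genesets}
        biggest = max(sizes, key=lambda n: sizes[n])
        k_per_pathway = {name: (1 if name == biggest else 2) for name in sizes}
    if isinstance(k_per_pathway, int):
        k_per_pathway = {s.name: k_per_pathway for s in genesets}
    return {
        s.name: select_core_tfs(regulons, s, conditions, k_per_pathway[s.name])
        for s in genesets
    }


def extract_subnetwork(
    regulons: RegulonSet,
    condition: str,
    core_tfs,
    *,
    contrast_condition: str | None = None,
    key_genes=None,
    expr: ExpressionMatrix | None = None,
    sheet: SampleSheet | None = None,
    expression_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Edges of the core-TF regulatory network specific to one condition.

    Takes the focal condition's edges whose TF is in ``core_tfs``; when a
    contrast condition is given, any (tf, target) pair also present there is
    removed (edge-level set difference).  ``key_genes`` restricts targets.
    Returns an edge table (tf, target, condition); node expression can be
    annotated afterwards via :func:`subnetwork_to_graph`.
    """
    core_tfs = list(core_tfs)
    if not core_tfs:
        raise ValueError("core_tfs must be non-empty")
    edges = regulons.for_condition(condition)
    known_tfs = set(edges["tf"])
    missing = [tf for tf in core_tfs if tf not in known_tfs]
    if missing:
        warnings.warn(
            f"core TF(s) {missing} have no edges in condition {condition!r}; "
            "kept as isolated nodes"
        )
    focal = edges.loc[edges["tf"].isin(core_tfs), ["tf", "target"]]
    if contrast_condition is not None:
        contrast = regulons.for_condition(contrast_condition)[["tf", "target"]]
        contrast_pairs = set(map(tuple, contrast.to_numpy()))
        keep = [tuple(row) not in contrast_pairs for row in focal.to_numpy()]
        focal = focal.loc[keep]
    if key_genes is not None:
        focal = focal.loc[focal["target"].isin(set(key_genes))]
    out = focal.copy()
    out["condition"] = condition
    return out.reset_index(drop=True)


def subnetwork_to_graph(
    edge_table: pd.DataFrame,
    core_tfs,
    *,
    expr: ExpressionMatrix | None = None,
    sheet: SampleSheet | None = None,
    expression_groups: list[str] | None = None,
) -> nx.DiGraph:
    """Directed graph of a subnetwork edge table, with node roles and
    optional per-group mean-expression annotations."""
    g = nx.DiGraph()
    core = set(core_tfs)
    for tf in core:
        g.add_node(tf, role="core_tf")
    for _, row in edge_table.iterrows():
        if row["target"] not in g:
            g.add_node(row["target"], role="target")
        g.add_edge(row["tf"], row["target"], condition=row.get("condition", ""))
    if expr is not None and sheet is not None and expression_groups:
        for grp in expression_groups:
            means = group_mean(expr, sheet, grp)
            for node in g.nodes:
                if node in means.index:
                    g.nodes[node][f"mean_fpkm_{grp}"] = float(means.loc[node])
    return g
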