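"""End-to-end orchestration: activation -> DEG -> rescue -> GRN ->
coordination -> enrichment, with a reproducible report directory.

Each stage writes its own TSVs so any of them can be re-run or replaced
in isolation (e.g. an externally produced DEG table); ``summary.tsv``
collects the headline statistics and every number in it is re-derivable
from the stage outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import activation_profile, compare_activation
from .coordination import coexpression_edge_count, coordination_network, pcc_matrix
from .enrichment import hypergeometric_ora
from .grn import (
    extract_subnetwork,
    fold_change_filter,
    select_core_tfs_all,
    subnetwork_to_graph,
    venn_partition,
)
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    RegulonSet,
    SampleSheet,
    read_expression,
    read_gmt,
    read_regulons,
    read_sample_sheet,
)
from .rescue import call_degs, classify_rescue_table, summarize_rescue
from .simulate import STAGES

logger = logging.getLogger("scntkit")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Inputs, group labels and thresholds for one pipeline run."""

    expression: str
    samples: str
    genesets: str
    regulons: str
    out_dir: str
    deg_table_2cell: str | None = None
    deg_table_4cell: str | None = None
    key_genes: str | None = None  # path to one-gene-per-line list

    wt2: str = "WT2"
    nta2: str = "NTA2"
    ntb2: str = "NTB2"
    wt4: str = "WT4"
    nta4: str = "NTA4"
    ntb4: str = "NTB4"
    coord_wt: str = "WT2_sc"
    coord_nta: str = "NTA2_sc"
    stage_order: tuple[str, ...] = tuple(STAGES)
    series_types: tuple[str, str] = ("WT", "SCNT")

    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    fold_ratio: float = 2.0
    pcc_threshold: float = 0.55
    k_per_pathway: dict | int | None = None
    denominator_mode: str = "abnormal_genes"
    literal_rescue: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stage_order, list):
            cfg.stage_order = tuple(cfg.stage_order)
        if isinstance(cfg.series_types, list):
            cfg.series_types = tuple(cfg.series_types)
        return cfg

    def validate(self) -> None:
        for name in ("expression", "samples", "genesets", "regulons"):
            path = getattr(self, name)
            if path is None:
                raise ValueError(f"config field {name!r} is required")
            if not Path(path).exists():
                raise ValueError(f"config field {name!r}: path does not exist: {path}")
        for name in ("deg_table_2cell", "deg_table_4cell", "key_genes"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"config field {name!r}: path does not exist: {path}")
        for name in ("fdr_threshold", "pcc_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.fold_ratio <= 1:
            raise ValueError("fold_ratio must exceed 1")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")


def _read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write a report directory; returns its path.

    Aborts on the first failing stage with :class:`PipelineError` naming
    the stage; partial outputs are kept next to a ``FAILED`` marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}
    current_stage = "load_inputs"

    def tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(out / name, sep="\t", index=index)

    try:
        expr = read_expression(config.expression)
        sheet = read_sample_sheet(config.samples)
        genesets = read_gmt(config.genesets)
        regulons = read_regulons(config.regulons)
        pathway_genes = sorted(genesets.all_genes())
        key_genes = (_read_gene_list(config.key_genes) if config.key_genes
                     else None)

        # --- activation -------------------------------------------------
        current_stage = "activation"
        profile_rows, comparison_rows = [], []
        for s in genesets:
            for etype in config.series_types:
                prof = activation_profile(expr, sheet, s, config.stage_order,
                                          embryo_type=etype)
                for stage, score in prof.scores.items():
                    profile_rows.append({"pathway": s.name, "series": etype,
                                         "stage": stage, "score": score})
            for ga, gb in ((config.nta2, config.wt2), (config.nta4, config.wt4),
                           (config.nta2, config.ntb2), (config.nta4, config.ntb4)):
                t, p, _ = compare_activation(expr, sheet, s, ga, gb)
                comparison_rows.append({"pathway": s.name, "group_a": ga,
                                        "group_b": gb, "t": t, "p_value": p})
        tsv(pd.DataFrame(profile_rows), "activation_profiles.tsv")
        tsv(pd.DataFrame(comparison_rows), "activation_comparisons.tsv")

        # --- differential expression -----------------------------------
        current_stage = "differential_expression"
        if config.deg_table_2cell:
            degs2 = pd.read_csv(config.deg_table_2cell, sep="\t")
        else:
            degs2 = call_degs(expr, sheet, config.nta2, config.wt2,
                              fdr_threshold=config.fdr_threshold,
                              lfc_threshold=config.lfc_threshold)
        if config.deg_table_4cell:
            degs4 = pd.read_csv(config.deg_table_4cell, sep="\t")
        else:
            degs4 = call_degs(expr, sheet, config.nta4, config.wt4,
                              fdr_threshold=config.fdr_threshold,
                              lfc_threshold=config.lfc_threshold)
        tsv(degs2, "degs_2cell.tsv")
        tsv(degs4, "degs_4cell.tsv")
        summary["n_degs_2cell"] = int(degs2["is_deg"].sum())
        summary["n_degs_4cell"] = int(degs4["is_deg"].sum())

        # --- rescue classification --------------------------------------
        current_stage = "rescue"
        for label, degs, wt, nta, ntb in (
            ("2cell", degs2, config.wt2, config.nta2, config.ntb2),
            ("4cell", degs4, config.wt4, config.nta4, config.ntb4),
        ):
            calls = classify_rescue_table(degs, expr, sheet, wt, nta, ntb,
                                          literal=config.literal_rescue)
            rescue_summary = summarize_rescue(calls, genesets,
                                              denominator_mode=config.denominator_mode)
            tsv(calls, f"rescue_calls_{label}.tsv")
            tsv(rescue_summary.table, f"rescue_summary_{label}.tsv")
            overall = rescue_summary.table.set_index("pathway").loc["ALL_CLASSIFIED"]
            for cat in ("highly", "partially", "unrescued"):
                summary[f"frac_{cat}_{label}"] = float(overall[f"frac_{cat}"])

        # --- GRN comparison ---------------------------------------------
        current_stage = "grn"
        venn_rows = []
        for label, ca, cb in (("2cell", config.wt2, config.nta2),
                              ("4cell", config.wt4, config.nta4)):
            part = venn_partition(regulons, ca, cb, tf_filter=pathway_genes)
            venn_rows.append({"comparison": label, **part.counts()})
            summary[f"venn_shared_{label}"] = len(part.shared)
            summary[f"venn_{ca}_specific"] = len(part.a_specific)

            fc = fold_change_filter(sorted(part.a_specific), expr, sheet, ca, cb,
                                    ratio_threshold=config.fold_ratio)
            tsv(fc, f"wt_specific_fold_change_{label}.tsv")
            n_dys = int((fc["class"] == "A_over_B").sum())
            summary[f"n_dysregulated_{label}"] = n_dys
        tsv(pd.DataFrame(venn_rows), "venn_counts.tsv")

        current_stage = "core_tfs"
        selections = select_core_tfs_all(
            regulons, genesets, (config.wt2, config.wt4),
            k_per_pathway=config.k_per_pathway,
        )
        core_rows, core_tfs = [], []
        for name, sel in selections.items():
            core_tfs.extend(sel.selected)
            for condition, ranking in sel.rankings.items():
                for rank, (tf, n) in enumerate(ranking, start=1):
                    core_rows.append({"pathway": name, "condition": condition,
                                      "tf": tf, "n_targets": n, "rank": rank,
                                      "selected": tf in sel.selected})
        core_tfs = sorted(set(core_tfs))
        tsv(pd.DataFrame(core_rows), "core_tf_rankings.tsv")
        summary["n_core_tfs"] = len(core_tfs)
        summary["core_tfs"] = ",".join(core_tfs)

        current_stage = "subnetwork"
        sub_edges = extract_subnetwork(regulons, config.wt2, core_tfs,
                                       contrast_condition=config.nta2)
        tsv(sub_edges, "subnetwork_edges_2cell.tsv")
        graph = subnetwork_to_graph(sub_edges, core_tfs, expr=expr, sheet=sheet,
                                    expression_groups=[config.wt2, config.nta2])
        nx.write_graphml(graph, out / "subnetwork_2cell.graphml")
        summary["n_subnetwork_targets"] = int(
            sum(1 for _, d in graph.nodes(data=True) if d["role"] == "target")
        )

        # --- coordination ------------------------------------------------
        current_stage = "coordination"
        if key_genes is None:
            # default: targets of the core TFs present in both coordination
            # groups' expression, capped for readability
            targeted = sorted(
                set(extract_subnetwork(regulons, config.wt2, core_tfs)["target"])
                & set(expr.gene_ids)
            )[:32]
            key_genes = targeted
        if len(key_genes) < 2:
            raise ValueError("need >= 2 key genes for coordination analysis")
        edge_counts = {}
        for label, grp, cond in (("wt", config.coord_wt, config.wt2),
                                 ("nta", config.coord_nta, config.nta2)):
            corr = pcc_matrix(expr, sheet, grp, key_genes)
            corr_out = corr.values.copy()
            corr_out.index.name = "gene_id"
            tsv(corr_out, f"correlation_{label}.tsv", index=True)
            net = coordination_network(corr, regulons, cond, core_tfs,
                                       threshold=config.pcc_threshold,
                                       expr=expr, sheet=sheet, expression_group=grp)
            rows = [{"source": u, "target": v, "kind": d["kind"],
                     "value": d.get("pcc", d.get("weight", ""))}
                    for u, v, d in net.edges(data=True)]
            tsv(pd.DataFrame(rows), f"coordination_edges_{label}.tsv")
            edge_counts[label] = coexpression_edge_count(net)
        summary["coord_edges_wt"] = edge_counts["wt"]
        summary["coord_edges_nta"] = edge_counts["nta"]

        # --- enrichment ---------------------------------------------------
        current_stage = "enrichment"
        fc2 = pd.read_csv(out / "wt_specific_fold_change_2cell.tsv", sep="\t")
        dys_genes = list(fc2.loc[fc2["class"] == "A_over_B", "gene_id"])
        if dys_genes:
            ora = hypergeometric_ora(dys_genes, genesets, expr.gene_ids)
            tsv(ora, "enrichment_dysregulated_2cell.tsv")
            summary["n_enriched_sets"] = int((ora["p_value"] < 0.05).sum())
        else:
            summary["n_enriched_sets"] = 0

        # --- report -------------------------------------------------------
        current_stage = "report"
        srows = [{"statistic": k, "value": v} for k, v in summary.items()]
        tsv(pd.DataFrame(srows), "summary.tsv")
        log_lines = [
            f"scntkit {__version__}",
            f"python {sys.version.split()[0]}",
            f"seed {config.seed}",
            "config " + json.dumps(asdict(config), default=str, sort_keys=True),
        ]
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current_stage}\ncause: {exc}\n")
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    return out
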