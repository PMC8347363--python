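"""Abnormal-gene calling and rescue classification in NT-to-blastocyst embryos.

A gene abnormally expressed in arrested nuclear-transfer (NTA) embryos is
*rescued* in embryos that reached blastocyst (NTB) when its NTB expression
moves back toward the in vivo fertilized (WT) level.  On the
log2(FPKM + 1) scale, with ``mid`` the midpoint of the WT and NTA values,
a gene down-regulated in NTA is

* **highly rescued**   when  ``ntb > mid``
* **partially rescued** when ``nta < ntb < mid``
* **unrescued**        otherwise (boundary values included)

For genes up-regulated in NTA the inequalities are mirrored (NTB must come
back *down* toward WT); a ``literal`` mode applies the down-form
inequalities regardless of direction.

The abnormal-gene caller provided here is a per-gene Welch t-test on
log2(FPKM+1) with Benjamini–Hochberg FDR control — a documented stand-in
for a negative-binomial count model.  Externally produced tables with the
same columns are accepted interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, SampleSheet, group_mean, log2p1

__all__ = [
    "benjamini_hochberg",
    "call_degs",
    "classify_rescue",
    "classify_rescue_table",
    "summarize_rescue",
    "RescueCall",
    "RescueSummary",
    "DOWN",
    "UP",
    "CATEGORIES",
]

DOWN = "down_in_NTA"
UP = "up_in_NTA"
CATEGORIES = ("highly", "partially", "unrescued")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR), input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    *,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential-expression calls for ``group_a`` (NT) vs ``group_b`` (WT).

    Per-gene two-sided Welch t-test on log2(FPKM+1) across samples;
    ``log2fc = log2((mean_a + 1) / (mean_b + 1))`` on group-mean FPKM.
    A gene is flagged when ``fdr < fdr_threshold`` and
    ``|log2fc| > lfc_threshold``.  Genes with zero variance in both groups
    get ``p = 1`` when the means agree (including all-zero rows) and
    ``p = 0`` when they differ — the noiseless limit of the t-test.

    Returns a table with columns gene_id, log2fc, p_value, fdr, direction,
    is_deg.
    """
    sa = [s for s in sheet.samples_in_group(group_a) if s in expr.data.columns]
    sb = [s for s in sheet.samples_in_group(group_b) if s in expr.data.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(sa)} in {group_a!r} "
            f"and {len(sb)} in {group_b!r}"
        )
    log_a = log2p1(expr.data[sa].to_numpy())
    log_b = log2p1(expr.data[sb].to_numpy())

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) rows are patched below by convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        mean_la = log_a.mean(axis=1)
        mean_lb = log_b.mean(axis=1)
        degenerate = (log_a.var(axis=1) == 0) & (log_b.var(axis=1) == 0)
        same = np.isclose(mean_la, mean_lb)
        p = np.where(degenerate & same, 1.0, p)
        t = np.where(degenerate & same, 0.0, t)
        p = np.where(degenerate & ~same, 0.0, p)
        t = np.where(degenerate & ~same, np.sign(mean_la - mean_lb) * np.inf, t)

    fdr = benjamini_hochberg(p)
    mean_a = expr.data[sa].mean(axis=1).to_numpy()
    mean_b = expr.data[sb].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    direction = np.where(log2fc < 0, DOWN, UP)
    is_deg = (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)

    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "is_deg": is_deg,
        }
    )


@dataclass(frozen=True)
class RescueCall:
    """One gene's rescue classification and the log values that drove it."""

    gene_id: str
    wt_log: float
    nta_log: float
    ntb_log: float
    direction: str
    category: str

    @property
    def midpoint(self) -> float:
        return (self.wt_log + self.nta_log) / 2.0


def classify_rescue(
    wt_fpkm: float,
    nta_fpkm: float,
    ntb_fpkm: float,
    direction: str = DOWN,
    *,
    gene_id: str = "",
    literal: bool = False,
) -> RescueCall:
    """Classify one abnormal gene as highly / partially / unrescued.

    Inputs are group-mean FPKM values (non-negative).  All inequalities are
    strict; values landing exactly on a boundary fall to ``unrescued``.
    """
    if min(wt_fpkm, nta_fpkm, ntb_fpkm) < 0:
        raise ValueError("FPKM inputs must be non-negative")
    if direction not in (DOWN, UP):
        raise ValueError(f"direction must be {DOWN!r} or {UP!r}")
    wt = log2p1(wt_fpkm)
    nta = log2p1(nta_fpkm)
    ntb = log2p1(ntb_fpkm)
    mid = (wt + nta) / 2.0

    if literal or direction == DOWN:
        if ntb > mid:
            category = "highly"
        elif nta < ntb < mid:
            category = "partially"
        else:
            category = "unrescued"
    else:  # up_in_NTA: rescue means coming back down toward WT
        if ntb < mid:
            category = "highly"
        elif mid < ntb < nta:
            category = "partially"
        else:
            category = "unrescued"

    return RescueCall(gene_id, wt, nta, ntb, direction, category)


def classify_rescue_table(
    deg_table: pd.DataFrame,
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    wt_group: str,
    nta_group: str,
    ntb_group: str,
    *,
    literal: bool = False,
) -> pd.DataFrame:
    """Classify every flagged gene in a DEG table.

    Returns a table with columns gene_id, direction, wt_log, nta_log,
    ntb_log, midpoint, category.
    """
    flagged = deg_table.loc[deg_table["is_deg"]]
    if flagged.empty:
        raise ValueError("no abnormal genes to classify (is_deg all False)")
    wt = group_mean(expr, sheet, wt_group)
    nta = group_mean(expr, sheet, nta_group)
    ntb = group_mean(expr, sheet, ntb_group)

    rows = []
    for gene, direction in zip(flagged["gene_id"], flagged["direction"]):
        if gene not in wt.index:
            warnings.warn(f"gene {gene!r} absent from expression matrix; skipped")
            continue
        call = classify_rescue(
            wt.loc[gene], nta.loc[gene], ntb.loc[gene], direction,
            gene_id=gene, literal=literal,
        )
        rows.append(
            {
                "gene_id": gene,
                "direction": direction,
                "wt_log": call.wt_log,
                "nta_log": call.nta_log,
                "ntb_log": call.ntb_log,
                "midpoint": call.midpoint,
                "category": call.category,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RescueSummary:
    """Per-pathway and overall rescue-category counts and fractions."""

    table: pd.DataFrame
    denominator_mode: str


def summarize_rescue(
    calls: pd.DataFrame,
    genesets: GeneSetCollection,
    *,
    denominator_mode: str = "abnormal_genes",
) -> RescueSummary:
    """Summarize rescue calls per pathway and overall.

    ``denominator_mode="abnormal_genes"`` divides category counts by the
    number of classified genes in each pathway; ``"all_pathway_genes"``
    divides by the full pathway size.  Genes belonging to several pathways
    are counted in each (with a warning).
    """
    if calls.empty:
        raise ValueError("empty rescue-call set")
    if denominator_mode not in ("abnormal_genes", "all_pathway_genes"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")

    membership: dict[str, set[str]] = {s.name: set(s.genes) for s in genesets}
    gene_pathways = {
        g: [n for n, members in membership.items() if g in members]
        for g in calls["gene_id"]
    }
    multi = [g for g, ps in gene_pathways.items() if len(ps) > 1]
    if multi:
        warnings.warn(f"{len(multi)} gene(s) belong to several pathways; counted in each")

    rows = []

    def one_row(name: str, sub: pd.DataFrame, denom: int) -> dict:
        counts = sub["category"].value_counts()
        row = {"pathway": name, "denominator": denom, "n_classified": len(sub)}
        for c in CATEGORIES:
            n = int(counts.get(c, 0))
            row[f"n_{c}"] = n
            row[f"frac_{c}"] = n / denom if denom else float("nan")
        return row

    for s in genesets:
        sub = calls.loc[calls["gene_id"].isin(membership[s.name])]
        denom = len(sub) if denominator_mode == "abnormal_genes" else len(s.genes)
        rows.append(one_row(s.name, sub, denom))

    all_members = genesets.all_genes()
    overall = calls.loc[calls["gene_id"].isin(all_members)]
    denom = len(overall) if denominator_mode == "abnormal_genes" else len(all_members)
    rows.append(one_row("ALL_PATHWAYS", overall, denom))
    rows.append(one_row("ALL_CLASSIFIED", calls,
                        len(calls) if denominator_mode == "abnormal_genes"
                        else len(calls)))

    return RescueSummary(pd.DataFrame(rows), denominator_mode)
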