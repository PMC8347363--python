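"""Stage-wise pathway-activation profiles and group comparisons.

The activation score of a gene set at a developmental stage is the mean of
log2(FPKM+1) over the set's genes and the stage's samples.  In normal
(in vivo fertilized) embryos the three transcription pathways — basal
transcription factors, RNA polymerase and spliceosome — mount a major
activation wave at the 2-cell to 4-cell transition, coincident with
zygotic genome activation; nuclear-transfer embryos activate them only
partially.  Group differences are tested with a two-sided Welch t-test
over per-gene group-mean values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, SampleSheet, group_mean, log2p1

__all__ = ["ActivationProfile", "activation_profile", "compare_activation"]


@dataclass(frozen=True)
class ActivationProfile:
    """Per-stage activation of one gene set."""

    pathway: str
    stages: tuple[str, ...]
    scores: pd.Series  # index = stages, mean log2(FPKM+1)
    trajectories: pd.DataFrame  # genes x stages, per-gene min-max normalized

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.stages):
            raise ValueError("score count must equal stage count")

    def max_increase_transition(self) -> tuple[str, str]:
        """The stage pair with the largest score increase."""
        diffs = np.diff(self.scores.to_numpy())
        i = int(np.argmax(diffs))
        return self.stages[i], self.stages[i + 1]


def _stage_samples(sheet: SampleSheet, stage: str, group_prefix: str | None) -> list[str]:
    if group_prefix is not None:
        return sheet.samples_in_group(f"{group_prefix}_{stage}")
    return sheet.samples_in_stage(stage)


def activation_profile(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    geneset: GeneSet,
    stage_order: tuple[str, ...] | list[str],
    *,
    embryo_type: str | None = None,
) -> ActivationProfile:
    """Activation score of ``geneset`` at each stage in ``stage_order``.

    ``embryo_type`` restricts samples to one series (e.g. ``"WT"`` or
    ``"SCNT"``) when the sheet annotates several.  Scores are means of
    log2(FPKM+1) over pathway genes and stage samples; the trajectory view
    min-max-normalizes each gene across stages (genes flat across stages
    are reported as all-zero with a warning).
    """
    present = [g for g in geneset.genes if g in expr.data.index]
    missing = [g for g in geneset.genes if g not in expr.data.index]
    if not present:
        raise ValueError(
            f"no genes of set {geneset.name!r} found in the matrix; missing {missing[:10]}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) of set {geneset.name!r} absent from matrix"
        )
    logvals = expr.subset_genes(present).log_values()

    per_gene = {}
    scores = {}
    for stage in stage_order:
        samples = sheet.samples_in_stage(stage, embryo_type=embryo_type)
        samples = [s for s in samples if s in logvals.columns]
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples"
                             + (f" of embryo type {embryo_type!r}" if embryo_type else ""))
        stage_mean = logvals[samples].mean(axis=1)
        per_gene[stage] = stage_mean
        scores[stage] = float(stage_mean.mean())

    traj = pd.DataFrame(per_gene)
    lo = traj.min(axis=1)
    hi = traj.max(axis=1)
    span = hi - lo
    flat = span <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} gene(s) constant across stages; normalized "
            "trajectory reported as flat 0"
        )
    span = span.where(~flat, 1.0)
    normalized = traj.sub(lo, axis=0).div(span, axis=0)
    normalized.loc[flat] = 0.0

    return ActivationProfile(
        pathway=geneset.name,
        stages=tuple(stage_order),
        scores=pd.Series(scores).reindex(list(stage_order)),
        trajectories=normalized,
    )


def compare_activation(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    geneset: GeneSet,
    group_a: str,
    group_b: str,
    *,
    unit: str = "genes",
    equal_var: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Two-sided t-test of pathway activation between two groups.

    With ``unit="genes"`` (default) the observations are per-gene
    log2(group-mean FPKM + 1) values, pathway genes as the sample; with
    ``unit="cells"`` they are per-sample means of log2(FPKM+1) over
    pathway genes.  Welch (unequal variance) by default.

    Returns ``(t, p, per_gene_means)`` where the DataFrame holds the
    gene-level values for both groups.
    """
    present = [g for g in geneset.genes if g in expr.data.index]
    if len(present) < 2:
        raise ValueError(f"need >=2 pathway genes in matrix, found {len(present)}")
    sub = expr.subset_genes(present)

    if unit == "genes":
        a = log2p1(group_mean(sub, sheet, group_a).to_numpy())
        b = log2p1(group_mean(sub, sheet, group_b).to_numpy())
    elif unit == "cells":
        logvals = sub.log_values()
        sa = [s for s in sheet.samples_in_group(group_a) if s in logvals.columns]
        sb = [s for s in sheet.samples_in_group(group_b) if s in logvals.columns]
        if not sa or not sb:
            raise ValueError("both groups need >=1 sample in the matrix")
        a = logvals[sa].mean(axis=0).to_numpy()
        b = logvals[sb].mean(axis=0).to_numpy()
    else:
        raise ValueError(f"unit must be 'genes' or 'cells', got {unit!r}")

    table = pd.DataFrame(
        {"group": [group_a] * len(a) + [group_b] * len(b),
         "value": np.concatenate([a, b]),
         "unit_id": (present * 2 if unit == "genes"
                     else list(range(len(a))) + list(range(len(b))))}
    )
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        if np.isclose(a[0], b[0]):
            # identical constants: no evidence of difference by convention
            return 0.0, 1.0, table
        raise ValueError("zero variance in both groups; t statistic undefined")

    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), table
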