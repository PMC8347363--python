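"""Synthetic expression data with the structure the analysis assumes.

The generator emulates two kinds of mouse pre-implantation datasets:

* a six-stage developmental series (zygote -> blastocyst) for in vivo
  fertilized (WT) and nuclear-transfer (SCNT) embryos, carrying a
  transcription-pathway activation wave at the 2-cell -> 4-cell transition
  that is attenuated in SCNT;
* six embryo groups (WT2, WT4, NTA2, NTA4, NTB2, NTB4) with planted
  abnormally expressed genes whose rescue category in NT-to-blastocyst
  (NTB) embryos is known, plus two single-cell sample sets at the 2-cell
  stage (``WT2_sc`` / ``NTA2_sc``) carrying a latent-factor-driven block of
  co-regulated key genes for correlation analyses.

Planted regulons wire a handful of core pathway transcription factors to
background and key-gene targets in WT conditions; NTA conditions retain
only a configured subset of those edges.  Every planted signal is returned
as ground truth so recovery can be scored exactly.

All planted means live on the log2(FPKM+1) scale; observed values add
Gaussian noise on that scale and are back-transformed to FPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RegulonSet,
    SampleSheet,
    write_expression,
    write_gmt,
    write_regulons,
    write_sample_sheet,
)

__all__ = ["SimConfig", "SimGroundTruth", "simulate_dataset", "write_fixture",
           "largest_remainder_counts", "STAGES", "EMBRYO_GROUPS"]

STAGES = ("zygote", "2cell", "4cell", "8cell", "morula", "blastocyst")
EMBRYO_GROUPS = ("WT2", "WT4", "NTA2", "NTA4", "NTB2", "NTB4")
PATHWAY_NAMES = ("basal_TFs", "RNA_polymerase", "spliceosome")
RESCUE_CATEGORIES = ("highly", "partially", "unrescued")

#: planted distance kept between an NTB mean and every category boundary
#: on the log2 scale, so classification is not boundary-flaky at low noise
CATEGORY_MARGIN = 0.5


class ConfigError(ValueError):
    """A SimConfig field combination is invalid or infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real study's shape: three KEGG transcription
    pathways of 44, 31 and 136 members, three replicates per embryo group,
    a four-fold WT activation wave at the 2-cell -> 4-cell transition that
    SCNT embryos fail to mount, and a 16-gene co-regulated key-gene block.
    """

    seed: int = 0
    n_background_genes: int = 2000
    pathway_sizes: tuple[int, int, int] = (44, 31, 136)
    replicates_per_group: int = 3
    cells_per_group: int = 20
    noise_sd: float = 0.1
    deg_effect: float = 2.0
    n_planted_degs: int = 300
    pathway_deg_count: int = 150
    rescue_fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    down_fraction: float = 0.8
    wave_fold: float = 4.0
    scnt_attenuation: float = 0.25
    n_regulon_targets: int = 100
    regulon_retention: float = 0.3
    key_gene_count: int = 16
    key_factor_sd: float = 0.4

    def __post_init__(self) -> None:
        if abs(sum(self.rescue_fractions) - 1.0) > 1e-9:
            raise ConfigError("rescue_fractions must sum to 1")
        for name in ("n_background_genes", "replicates_per_group", "cells_per_group",
                     "n_planted_degs", "pathway_deg_count", "n_regulon_targets",
                     "key_gene_count"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(s <= 0 for s in self.pathway_sizes):
            raise ConfigError("pathway_sizes must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0 < self.scnt_attenuation <= 1):
            raise ConfigError("scnt_attenuation must lie in (0, 1]")
        if not (0 <= self.down_fraction <= 1):
            raise ConfigError("down_fraction must lie in [0, 1]")
        if not (0 <= self.regulon_retention <= 1):
            raise ConfigError("regulon_retention must lie in [0, 1]")
        # the partially-rescued interval has half-width deg_effect/4; the
        # planted margin must fit inside it
        if self.deg_effect / 4.0 < CATEGORY_MARGIN:
            raise ConfigError(
                f"deg_effect={self.deg_effect} leaves no room for the "
                f"{CATEGORY_MARGIN} log2 category margin (needs >= {4 * CATEGORY_MARGIN})"
            )
        if self.pathway_deg_count > sum(self.pathway_sizes):
            raise ConfigError("pathway_deg_count exceeds the pathway universe")
        if self.n_planted_degs - self.pathway_deg_count > self.n_background_genes:
            raise ConfigError("not enough background genes for planted DEGs")


@dataclass(frozen=True)
class SimGroundTruth:
    """Everything the generator planted, for exact recovery scoring."""

    planted_log_means: pd.DataFrame  # genes x group labels, log2(FPKM+1)
    deg_table: pd.DataFrame  # gene, direction, rescue_category
    core_tfs: tuple[str, ...]
    key_genes: tuple[str, ...]
    regulons: RegulonSet  # the planted edges, identical to the emitted set
    config: SimConfig

    @property
    def deg_genes(self) -> list[str]:
        return list(self.deg_table["gene"])

    def category_counts(self) -> dict[str, int]:
        vc = self.deg_table["rescue_category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in RESCUE_CATEGORIES}


def largest_remainder_counts(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of ``total`` by fractions, largest remainder first.

    Ties in the fractional remainders are broken by position (earlier
    category wins), so (highly, partially, unrescued) order is the
    tie-break.
    """
    raw = [f * total for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = total - sum(counts)
    remainders = [(r - np.floor(r), -i) for i, r in enumerate(raw)]
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - np.floor(raw[i])), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _gene_universe(config: SimConfig) -> tuple[list[str], GeneSetCollection, list[str], list[str]]:
    prefixes = ("BTF", "POL", "SPL")
    sets = []
    pathway_genes: list[str] = []
    for name, prefix, size in zip(PATHWAY_NAMES, prefixes, config.pathway_sizes):
        genes = tuple(f"{prefix}_{i:03d}" for i in range(1, size + 1))
        sets.append(GeneSet(name, f"synthetic {name} pathway", genes))
        pathway_genes.extend(genes)
    key_genes = [f"KEY_{i:02d}" for i in range(1, config.key_gene_count + 1)]
    background = [f"G{i:05d}" for i in range(1, config.n_background_genes + 1)]
    all_genes = pathway_genes + key_genes + background
    return all_genes, GeneSetCollection(tuple(sets)), key_genes, background


def _plant_ntb(wt: np.ndarray, nta: np.ndarray, category: np.ndarray,
               down: np.ndarray, effect: float) -> np.ndarray:
    """NTB log-means placed >= CATEGORY_MARGIN away from every boundary."""
    mid = (wt + nta) / 2.0
    ntb = np.empty_like(wt)
    # highly: beyond the midpoint on the WT side -- plant full recovery
    hi = category == "highly"
    ntb[hi] = wt[hi]
    # partially: centre of the open (nta, mid) interval
    pa = category == "partially"
    ntb[pa] = (nta[pa] + mid[pa]) / 2.0
    # unrescued: outside the nta boundary, away from it by the margin
    un = category == "unrescued"
    ntb[un] = np.where(down[un], nta[un] - CATEGORY_MARGIN, nta[un] + CATEGORY_MARGIN)
    return ntb


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleSheet, GeneSetCollection, RegulonSet, SimGroundTruth]:
    """Generate one synthetic dataset, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    genes, genesets, key_genes, background = _gene_universe(config)
    pathway_genes = [g for s in genesets for g in s.genes]
    gene_index = pd.Index(genes, name="gene_id")
    n_genes = len(genes)

    # --- baseline log2(FPKM+1) means ------------------------------------
    # high enough that a deg_effect drop plus the unrescued margin stays >= 0
    floor = config.deg_effect + CATEGORY_MARGIN + 0.2
    base = pd.Series(rng.uniform(1.0, 5.0, n_genes), index=gene_index)
    base.loc[pathway_genes] = rng.uniform(floor, floor + 1.5, len(pathway_genes))
    base.loc[key_genes] = rng.uniform(floor, floor + 1.8, len(key_genes))

    # --- planted DEGs and rescue categories -----------------------------
    n_bg_degs = config.n_planted_degs - config.pathway_deg_count
    deg_pathway = list(rng.choice(pathway_genes, config.pathway_deg_count, replace=False))
    deg_background = list(rng.choice(background, n_bg_degs, replace=False))
    deg_genes = deg_pathway + deg_background
    # background DEG baselines also need headroom for the down shift
    base.loc[deg_background] = rng.uniform(floor, floor + 1.5, len(deg_background))

    # pathway DEGs are uniformly down in NTA (the incomplete-activation
    # phenotype); the up-regulated abnormal genes live in the background
    n_bg_down = int(round(config.down_fraction * len(deg_background)))
    bg_directions = np.array(
        ["down_in_NTA"] * n_bg_down
        + ["up_in_NTA"] * (len(deg_background) - n_bg_down)
    )
    rng.shuffle(bg_directions)
    directions = np.concatenate(
        [np.array(["down_in_NTA"] * len(deg_pathway)), bg_directions]
    )

    counts = largest_remainder_counts(len(deg_genes), config.rescue_fractions)
    categories = np.repeat(RESCUE_CATEGORIES, counts)
    rng.shuffle(categories)

    deg_table = pd.DataFrame(
        {"gene": deg_genes, "direction": directions, "rescue_category": categories}
    )

    # --- per-group planted log-means ------------------------------------
    wave_gain = np.log2(
        config.wave_fold * (2.0 ** base.loc[pathway_genes].to_numpy() - 1.0) + 1.0
    ) - base.loc[pathway_genes].to_numpy()
    scnt_gain = np.log2(
        config.wave_fold * config.scnt_attenuation
        * (2.0 ** base.loc[pathway_genes].to_numpy() - 1.0) + 1.0
    ) - base.loc[pathway_genes].to_numpy()

    group_means: dict[str, pd.Series] = {}

    # six-stage series: wave mounts at 2cell -> 4cell and persists
    for etype, gain in (("WT", wave_gain), ("SCNT", scnt_gain)):
        for si, stage in enumerate(STAGES):
            mu = base.copy()
            if si >= 2:  # 4cell onward
                mu.loc[pathway_genes] = base.loc[pathway_genes].to_numpy() + gain
            group_means[f"{etype}_{stage}"] = mu

    # embryo groups: WT2 at pre-wave baseline, WT4 post-wave
    wt2 = base.copy()
    wt4 = base.copy()
    wt4.loc[pathway_genes] = base.loc[pathway_genes].to_numpy() + wave_gain

    down = directions == "down_in_NTA"
    shift = np.where(down, -config.deg_effect, config.deg_effect)
    nta2 = wt2.copy()
    nta2.loc[deg_genes] = wt2.loc[deg_genes].to_numpy() + shift
    nta4 = wt4.copy()
    nta4.loc[deg_genes] = wt4.loc[deg_genes].to_numpy() + shift
    # key genes fail to come up in arrested embryos
    nta2.loc[key_genes] = np.maximum(wt2.loc[key_genes].to_numpy() - config.deg_effect, 0.0)
    nta4.loc[key_genes] = np.maximum(wt4.loc[key_genes].to_numpy() - config.deg_effect, 0.0)

    ntb2 = wt2.copy()
    ntb2.loc[deg_genes] = _plant_ntb(
        wt2.loc[deg_genes].to_numpy(), nta2.loc[deg_genes].to_numpy(), categories, down,
        config.deg_effect,
    )
    ntb4 = wt4.copy()
    ntb4.loc[deg_genes] = _plant_ntb(
        wt4.loc[deg_genes].to_numpy(), nta4.loc[deg_genes].to_numpy(), categories, down,
        config.deg_effect,
    )

    group_means.update(
        WT2=wt2, WT4=wt4, NTA2=nta2, NTA4=nta4, NTB2=ntb2, NTB4=ntb4,
        WT2_sc=wt2.copy(), NTA2_sc=nta2.copy(),
    )
    if (pd.concat(group_means.values(), axis=1).to_numpy() < 0).any():
        raise ConfigError("planted log-means fell below zero; raise baselines or "
                          "lower deg_effect")

    # --- draw samples ----------------------------------------------------
    columns: list[str] = []
    sheet_rows: list[dict] = []
    blocks: list[np.ndarray] = []

    def draw(group: str, n: int, stage: str, etype: str, latent_scale: float | None) -> None:
        mu = group_means[group].to_numpy()
        noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n))
        logvals = mu[:, None] + noise
        if latent_scale is not None:
            factor = rng.normal(0.0, config.key_factor_sd * latent_scale, size=n)
            ki = [genes.index(k) for k in key_genes]
            logvals[ki, :] += factor[None, :]
        blocks.append(np.maximum(2.0 ** logvals - 1.0, 0.0))
        for r in range(1, n + 1):
            sid = f"{group}_r{r}"
            columns.append(sid)
            sheet_rows.append(
                {"sample_id": sid, "group": group, "stage": stage,
                 "embryo_type": etype, "replicate": r}
            )

    for etype in ("WT", "SCNT"):
        for stage in STAGES:
            draw(f"{etype}_{stage}", config.replicates_per_group, stage, etype, None)
    stage_of = {"WT2": "2cell", "WT4": "4cell", "NTA2": "2cell", "NTA4": "4cell",
                "NTB2": "2cell", "NTB4": "4cell"}
    etype_of = {"WT2": "WT", "WT4": "WT", "NTA2": "NT-arrest", "NTA4": "NT-arrest",
                "NTB2": "NT-blastocyst", "NTB4": "NT-blastocyst"}
    for group in EMBRYO_GROUPS:
        draw(group, config.replicates_per_group, stage_of[group], etype_of[group], None)
    draw("WT2_sc", config.cells_per_group, "2cell", "WT", 1.0)
    draw("NTA2_sc", config.cells_per_group, "2cell", "NT-arrest", config.scnt_attenuation)

    expr = ExpressionMatrix(
        pd.DataFrame(np.hstack(blocks), index=gene_index, columns=columns)
    )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    # --- planted regulons -------------------------------------------------
    core_tfs = ("BTF_001", "BTF_002", "POL_001", "POL_002", "SPL_001")
    edge_rows: list[dict] = []

    def add_edges(condition: str, tf: str, targets: list[str]) -> None:
        for t in targets:
            edge_rows.append({"condition": condition, "tf": tf, "target": t, "weight": 1.0})

    # key genes split across the cores so each is targeted in WT conditions
    key_assignment: dict[str, list[str]] = {tf: [] for tf in core_tfs}
    for i, kg in enumerate(key_genes):
        key_assignment[core_tfs[i % len(core_tfs)]].append(kg)

    # secondary pathway TFs carry small regulons so core ranking is non-trivial
    secondary = ["BTF_003", "BTF_004", "POL_003", "POL_004", "SPL_002", "SPL_003"]
    target_pool = deg_background + [g for g in background if g not in set(deg_background)]

    wt_targets: dict[str, list[str]] = {}
    for ti, tf in enumerate(core_tfs):
        n_deg = min(len(deg_background), config.n_regulon_targets // 3)
        picked_deg = list(rng.choice(deg_background, n_deg, replace=False))
        rest_pool = [g for g in background if g not in set(picked_deg)]
        picked_bg = list(
            rng.choice(rest_pool, config.n_regulon_targets - n_deg, replace=False)
        )
        wt_targets[tf] = sorted(set(picked_deg + picked_bg)) + key_assignment[tf]
    for ti, tf in enumerate(secondary):
        size = 5 + 3 * ti
        wt_targets[tf] = sorted(rng.choice(background, size, replace=False))

    for condition in ("WT2", "WT4"):
        for tf, targets in wt_targets.items():
            add_edges(condition, tf, targets)

    for condition in ("NTA2", "NTA4"):
        for tf, targets in wt_targets.items():
            keep = max(1, int(round(config.regulon_retention * len(targets))))
            retained = sorted(rng.choice(targets, keep, replace=False))
            novel = sorted(
                rng.choice([g for g in background if g not in set(targets)],
                           max(1, keep // 5), replace=False)
            )
            add_edges(condition, tf, retained + novel)

    regulons = RegulonSet(pd.DataFrame(edge_rows))

    truth = SimGroundTruth(
        planted_log_means=pd.DataFrame(group_means),
        deg_table=deg_table,
        core_tfs=core_tfs,
        key_genes=tuple(key_genes),
        regulons=regulons,
        config=config,
    )
    return expr, sheet, genesets, regulons, truth


FIXTURE_FILES = {
    "expression": "expression.tsv",
    "samples": "samples.csv",
    "genesets": "pathways.gmt",
    "regulons": "regulons.tsv",
    "planted_means": "ground_truth_means.tsv",
    "deg_table": "ground_truth_degs.tsv",
}


def write_fixture(bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated bundle to ``out_dir`` in the pipeline's file formats.

    Returns the mapping of component name to written path.  Re-reading the
    files reproduces the in-memory bundle.
    """
    expr, sheet, genesets, regulons, truth = bundle
    out_dir = Path(out_dir)
    if out_dir.exists() and not out_dir.is_dir():
        raise OSError(f"{out_dir} exists and is not a directory")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in FIXTURE_FILES.items()}
    write_expression(expr, paths["expression"])
    write_sample_sheet(sheet, paths["samples"])
    write_gmt(genesets, paths["genesets"])
    write_regulons(regulons, paths["regulons"])
    means = truth.planted_log_means.copy()
    means.index.name = "gene_id"
    means.to_csv(paths["planted_means"], sep="\t")
    truth.deg_table.to_csv(paths["deg_table"], sep="\t", index=False)
    return paths
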