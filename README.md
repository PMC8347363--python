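# scntkit

Analysis toolkit for the transcription-pathway failure of somatic cell
nuclear transfer (SCNT) embryos.

Most cloned mouse embryos arrest at the 2- or 4-cell stage, around zygotic
genome activation (ZGA). One molecular signature of this arrest is the
incomplete activation of the three KEGG transcription pathways — basal
transcription factors (mmu03022, 44 genes), RNA polymerase (mmu03020, 31
genes) and spliceosome (mmu03040, 136 genes) — and the downstream collapse
of the gene-regulatory networks (GRNs) they drive. `scntkit` implements
the downstream analysis of that phenotype as a reusable, tested pipeline
for anyone working with FPKM expression matrices of in vivo fertilized
(WT), NT-arrested (NTA) and NT-to-blastocyst (NTB) embryo groups, plus
condition-specific regulon tables (TF → target edges, e.g. from a
SCENIC-style run).

## What it computes

All statistics operate on log-transformed expression
`x = log2(FPKM + 1)`.

**Pathway activation** — the activation score of a gene set at a
developmental stage is the mean of `x` over the set's genes and the
stage's samples; group differences are tested with a two-sided Welch
t-test over per-gene group means.

**Rescue classification** — for a gene abnormally expressed in NTA
embryos (called at BH-FDR < 0.05 and |log2 fold change| > 1), write
`x_WT`, `x_NTA`, `x_NTB` for the group-mean log values and
`m = (x_WT + x_NTA)/2`. A gene down-regulated in NTA is

- *highly rescued* iff `x_NTB > m`
- *partially rescued* iff `x_NTA < x_NTB < m`
- *unrescued* otherwise (boundary values included).

For up-regulated genes the inequalities are mirrored (a `--literal` mode
applies the down-form verbatim).

**Regulon dysregulation** — the target universes regulated by pathway TFs
in two conditions are partitioned into shared and condition-specific
sets; condition-specific targets with group-mean ratio
`(mean_A + 1)/(mean_B + 1) > 2` are flagged as dysregulated. Core TFs are
the factors ranking in the top *k* by regulon size in every screened
condition (default top 2 per pathway, top 1 for the spliceosome), and the
condition-specific subnetwork is the edge-level set difference between
the focal and contrast condition.

**Coordination** — pairwise Pearson correlation (PCC) of key downstream
genes across a group's cells; pairs with PCC ≥ 0.55 form the undirected
co-expression network, overlaid with directed regulon edges.

A synthetic-data generator (`scntkit.simulate`) produces expression
matrices, sample sheets, pathway GMTs and regulon tables with all of
these signals planted and returns the ground truth, so every stage of
the pipeline can be validated end to end.

## Worked example

```python
from scntkit import (SimConfig, simulate_dataset, activation_profile,
                     compare_activation, call_degs, classify_rescue_table,
                     summarize_rescue)
from scntkit.simulate import STAGES

expr, sheet, pathways, regulons, truth = simulate_dataset(SimConfig(seed=42))

prof = activation_profile(expr, sheet, pathways["basal_TFs"], STAGES,
                          embryo_type="WT")
print("WT activation scores:", prof.scores.round(2).to_dict())
print("largest increase at:", "->".join(prof.max_increase_transition()))

t, p, _ = compare_activation(expr, sheet, pathways["basal_TFs"], "NTA2", "WT2")
print(f"NTA2 vs WT2 (basal TFs): t = {t:.2f}, p = {p:.2e}")

degs = call_degs(expr, sheet, "NTA2", "WT2")
print("abnormal genes called:", int(degs["is_deg"].sum()))
calls = classify_rescue_table(degs, expr, sheet, "WT2", "NTA2", "NTB2")
row = summarize_rescue(calls, pathways).table.set_index("pathway").loc["ALL_CLASSIFIED"]
print(f"highly rescued: {row['frac_highly']:.1%}, "
      f"partially: {row['frac_partially']:.1%}, "
      f"unrescued: {row['frac_unrescued']:.1%}")
```

prints

```
WT activation scores: {'zygote': 3.42, '2cell': 3.43, '4cell': 5.31, '8cell': 5.33, 'morula': 5.31, 'blastocyst': 5.31}
largest increase at: 2cell->4cell
NTA2 vs WT2 (basal TFs): t = -8.46, p = 1.18e-11
abnormal genes called: 316
highly rescued: 24.1%, partially: 28.5%, unrescued: 47.5%
```

The WT series mounts its activation wave at the 2-cell → 4-cell
transition (scores jump from 3.4 to 5.3), NTA2 pathway expression is
significantly below WT2, and the rescue fractions recover the planted
20 / 30 / 50 split (the extra "highly" calls are the co-regulated key
genes, which are planted as fully recovered in NTB embryos).

The same analyses are available from the shell:

```sh
scntkit simulate --out fixture --seed 42
scntkit all --config pipeline.yaml          # activation → DEG → rescue → GRN → coordination → enrichment
scntkit rescue --expr fixture/expression.tsv --samples fixture/samples.csv \
    --genesets fixture/pathways.gmt --wt WT2 --nta NTA2 --ntb NTB2 --out rescue_out
```

`scntkit all` writes per-stage TSVs, a `summary.tsv` of headline
statistics (every number in it re-derives from the stage files), and a
run log with the seed and thresholds used.

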