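# Methods

This note records the modelling conventions, generator design and
numerical choices behind `scntkit`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and transforms

Expression is consumed as FPKM matrices (genes × samples) with a sample
sheet mapping samples to embryo group (WT2, WT4, NTA2, NTA4, NTB2, NTB4,
or free labels), developmental stage (zygote → blastocyst) and embryo
type. All statistics operate on `log2(FPKM + 1)`; the pseudocount keeps
zeros at zero and every fold-change and rescue inequality uses the same
`+1` convention.

**Replicate aggregation order.** Group-level values are arithmetic means
of replicate FPKMs, log-transformed afterwards. The rescue inequalities
are written on a single FPKM value per condition, which this order
provides; averaging `log2(FPKM+1)` across replicates first and
back-transforming is available via `group_mean(..., log_first=True)` for
workflows that prefer post-log aggregation. The two differ by a Jensen
term that is ≈ 0.004 log2 units at the default within-group noise
(σ = 0.1) — far inside the 0.5-unit category margins the generator
plants.

Identifiers are case-sensitive exact strings; no symbol aliasing is
attempted. Genes present in a gene set but absent from the matrix are
dropped from that analysis with a logged count, since annotation-build
mismatches are routine.

## Pathway activation

The activation score of a gene set at a stage is the mean of
`log2(FPKM+1)` over (set genes × stage samples). The per-gene min–max
normalisation across stages is used only for the trajectory (plotting)
view, never for statistics; genes flat across stages are reported as
all-zero trajectories with a warning.

Group comparisons default to a two-sided Welch (unequal-variance) t-test
with per-gene group-mean log values as the observations — the gene is
the experimental unit, matching claims phrased as "expression levels of
pathway genes are lower". A `unit="cells"` alternative treats per-sample
pathway means as the observations, and a pooled-variance flag is
provided. Welch is the default because the R `t.test` default is the
unequal-variance form.

## Abnormal-gene calling and rescue classification

The built-in caller is a per-gene Welch t-test on `log2(FPKM+1)` across
samples with Benjamini–Hochberg step-up FDR control across all tested
genes; a gene is abnormal when FDR < 0.05 and |log2FC| > 1, with
`log2FC = log2((mean_NTA + 1)/(mean_WT + 1))` on group-mean FPKM. This
is a deliberate stand-in for a negative-binomial count model: it is
exact in the simulated Gaussian-on-log world the generator produces,
and externally produced DEG tables (e.g. from DESeq2) with the same
columns are accepted interchangeably, so the rescue classifier is
agnostic to the caller. Zero-variance rows are patched by convention
(p = 1 when means agree, p = 0 when they differ) so the noiseless limit
behaves sensibly.

Rescue categories use strict inequalities; values landing exactly on the
NTA boundary or on the WT/NTA midpoint fall to *unrescued* (the
"remaining genes" rule). The printed inequalities only make sense for
genes whose NTA expression is below WT; for up-regulated abnormal genes
the defaults mirror them (highly iff `x_NTB < m`; partially iff
`m < x_NTB < x_NTA`), since rescue there means coming back *down*
toward the WT level. A `literal` flag applies the down-form verbatim for
users who want the unmirrored behaviour. Note the classification is not
scale-equivariant: multiplying all three FPKM inputs by a constant can
change the category, which is inherent to the pseudocounted log scale.

Summary fractions are reported under two denominators, because both are
defensible and give different pictures: `abnormal_genes` (the classified
genes, default) and `all_pathway_genes` (the full pathway size). Genes
belonging to several pathways are counted in each, with a warning.

## Regulon comparison and core TFs

Regulons are consumed as condition-labelled TF → target edge tables;
no network inference is performed here. Target universes are unions
over (optionally pathway-filtered) TFs; the Venn partition is plain set
algebra and its conservation identities are fuzz-tested. Self-edges
(TF targeting itself) are retained but flagged.

Dysregulation of condition-specific targets uses the pseudocounted
group-mean ratio with threshold 2 ("more than twice"), consistent with
the `+1` convention elsewhere; both threshold and pseudocount are
configurable.

Core TFs are pathway members ranking within the top *k* by distinct
target count in *every* screened condition, ties broken
lexicographically so the screen is deterministic. The default per-pathway
*k* is 2, except 1 for the largest pathway — the shape of a five-factor
screen over the three transcription pathways. Condition-specific
subnetworks are edge-level set differences (an edge is specific when the
same (TF, target) pair is absent from the contrast condition); edge
weights are deliberately not compared.

## Coordination networks

Pearson correlations are computed across individual samples/cells within
one group (never across group means, which would be degenerate with two
points) and require ≥ 3 samples; zero-variance genes are masked rather
than dropped so matrix shape is preserved. The co-expression edge rule is
PCC ≥ 0.55 — the boundary is included, a choice documented here because
the verbal form "more than 0.55" does not settle it and planted effects
never sit at the boundary. Regulon edges restricted to the node set are
overlaid as directed edges. The key-gene list is a user input; by
default the pipeline falls back to the core TFs' targets.

## Enrichment

A generic over-representation statistic: upper-tail hypergeometric
probability of the observed overlap between a gene list and each
annotation set, both intersected with a configurable universe
(default: all genes in the expression matrix, since no better background
is known to the tool), BH-adjusted across sets. Raw p-values are
reported alongside FDR because enrichment summaries are conventionally
thresholded on raw p < 0.05. No ontology structure is handled.

## Synthetic-data generator

The generator emulates the structure of the two study designs the
pipeline targets — a six-stage WT/SCNT developmental series and the six
embryo groups with a separate single-cell set — without attempting
read-level realism, library-size artefacts or dropout.

Defaults (one place, `SimConfig`): pathway sizes (44, 31, 136); 2,000
background genes; 3 replicates per group; 20 cells per single-cell
group; noise σ = 0.1 on the log2 scale; planted effect 2.0 log2 units;
300 planted abnormal genes at fractions (0.2, 0.3, 0.5) for
(highly, partially, unrescued); wave fold 4; SCNT attenuation 0.25;
16 key genes; 100 targets per core TF with 30% edge retention in NTA
conditions.

Design choices worth recording:

- **Noise model.** Gaussian on `log2(FPKM+1)`, back-transformed —
  log-normal-like on the FPKM scale, the standard minimal model for
  FPKM-scale simulation; it keeps the rescue margins directly
  interpretable in log2 units.
- **Placement of abnormal genes.** 150 of the 300 planted abnormal genes
  lie inside the three pathways (the 211-member pathway universe cannot
  hold 300) and 150 in the background. Pathway-member abnormal genes are
  all down-regulated in NTA — the incomplete-activation phenotype; the
  20% up-regulated abnormal genes are placed in the background, so
  mirrored-direction classification is still exercised without erasing
  the pathway-level deficit.
- **Category margins.** NTB means are planted ≥ 0.5 log2 units from
  every category boundary (full recovery for *highly*, interval centre
  for *partially*, 0.5 beyond the NTA boundary for *unrescued*), so
  desk-scale tests are not boundary-flaky; with effect 2.0 the
  *partially* interval half-width is exactly 0.5, and smaller effects
  are rejected as infeasible at config time.
- **Category counts** are fixed by largest-remainder rounding of the
  fractions, ties broken in (highly, partially, unrescued) order, so
  planted counts are exact, not expected values.
- **Activation wave.** Pathway-gene FPKM means rise `wave_fold`-fold at
  the 2-cell → 4-cell transition of the WT series and by
  `wave_fold × scnt_attenuation` (= 1, i.e. flat, at defaults) in the
  SCNT series; all other transitions are flat, so the wave location is
  unambiguous.
- **Single-cell groups.** Correlation across 3 bulk replicates is
  meaningless, so the generator emits dedicated 20-cell sample sets
  (`WT2_sc`, `NTA2_sc`) for the coordination analysis — mirroring the
  use of a separate single-cell dataset for that figure-level analysis —
  while the six embryo groups keep 3 replicates for the DEG/rescue path.
- **Key-gene block.** A per-cell latent factor with σ = 0.4 log2 units
  loads on all 16 key genes in WT cells; with noise σ = 0.1 the implied
  within-block population correlation is 0.16/0.17 ≈ 0.94. In NTA cells
  the factor is scaled by the SCNT attenuation (0.25), giving
  ρ ≈ 0.5 — below the 0.55 edge cut in expectation — which produces the
  planted coordination defect (strictly fewer NTA edges) without making
  NTA correlations vanish entirely.
- **Regulons.** Five designated core TFs (two per small pathway, one for
  the spliceosome) receive 100-target regulons in WT conditions — a
  third of targets drawn from the background abnormal genes so the
  dysregulation filter has signal — plus the key genes, split across
  cores. Secondary pathway TFs carry small regulons so the core ranking
  is non-trivial. NTA conditions retain 30% of each WT regulon plus a
  few novel targets, so both Venn specific sets are non-empty and the
  WT-specific subnetwork equals the planted WT-only edge set exactly
  (edge space carries no noise).

What passing tests on this generator do **not** show: robustness to
count overdispersion, dropout, batch effects, library-size variation or
annotation mismatch — real-data behaviour of the DEG stand-in in
particular will differ from a count model's.

## Problem sizes and determinism

The default simulated study is 2,227 genes × 94 samples, small enough
that the full suite (including ten-replicate recovery checks) runs in
well under a minute; recovery criteria are averaged over ten seeds to
damp seed-to-seed variation. Everything downstream of `SimConfig.seed`
is driven by one `numpy` Generator, so a seed fixes the entire bundle
byte-for-byte, and the pipeline itself is deterministic given its
inputs. `scripts/acceptance.py --seed N` derives its ten replicate seeds
as `N .. N+9` (mod 2³¹−1).

## Known limitations

- The DEG stand-in assumes approximately Gaussian log-expression within
  groups; at n = 3 replicates its p-values are exact only under that
  assumption.
- Rescue classification depends on the FPKM scale through the
  pseudocount (documented above).
- The enrichment universe default (all matrix genes) is a convention,
  not a recommendation; expressed-gene universes are usually more
  appropriate.
- Regulon "specificity" is presence/absence of edges; differential edge
  weights are out of scope.
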