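# micropair

Matched-pair case-control analysis of gut microbiome taxonomic
profiles — from species-level relative-abundance tables to matched
case-control pairs, paired differential abundance, dispersion
diagnostics, design power analysis, and host-biomarker association.

## The problem

Gut microbiomes vary enormously from donor to donor, and in many
chronic inflammatory conditions (psoriasis among them) the disease
effect on the stool community is small — Cohen's *d* ≈ 0.37 for a
group-level contrast. A two-sided two-sample t-test at α = 0.05 then
needs well over 200 donors for 80% power, so a ~100-donor cohort
cannot support an unpaired case-control comparison. The remedy is a
matched-pair design: pair each case with the control whose overall
microbiome is most similar, so that the shared inter-individual
background cancels within pairs and a paired test isolates
disease-associated shifts.

`micropair` implements that pipeline for MetaPhlAn-style profiles:

1. **I/O & validation** — merged profile TSV (pipe-delimited lineages,
   percent or proportion) and metadata TSV with case/control labels
   and a biomarker panel including fecal calprotectin (µg/g).
2. **Preprocessing** — rare-taxon filter (discard taxa seen in ≤ 3
   donors AND never above 1e-4), multiplicative zero replacement, and
   the centered log-ratio transform
   clr(x)_j = ln x_j − (1/K) Σ_k ln x_k.
3. **Diversity & ordination** — Shannon *H* = −Σ p ln p and
   Bray-Curtis Σ|x−y|/Σ(x+y) on the unfiltered table with two-sample
   KS group comparisons (exact p for small tie-free samples); PCA of
   CLR data with component selection at 70% cumulative variance.
4. **Matching & paired DA** — greedy nearest-neighbor matching without
   replacement in PC space; per-taxon Wilcoxon signed-rank tests on
   within-pair differences (exact p for ≤ 25 tie-free pairs) with
   Benjamini-Hochberg FDR.
5. **Group-wise diagnostic** — Dirichlet-resampled CLR comparison of
   median between-group differences against within-group dispersion.
6. **Power** — Cohen's *d*, noncentral-*t* power curves, minimum-N
   solver.
7. **Biomarkers** — calprotectin > 35 µg/g classification, MaAsLin-style
   linear models at 10% FDR, Kendall tau-b, and calprotectin-constrained
   redundancy analysis (RDA) taxon ranking.
8. **Synthetic cohorts** — a seeded generator that plants all of the
   above structure (spiked species, pair-level clusters, coupled
   calprotectin) and returns the ground truth, so every stage is
   testable against known answers.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_diversity_and_ordination.py
python analysis/03_matched_pairs_da.py
python analysis/04_groupwise_dispersion.py
python analysis/05_power_analysis.py
python analysis/06_biomarker_association.py
```

Output of the run (seed 11):

```
cohort: 100 donors x 424 taxa (53 cases / 47 controls)
calprotectin > 35 µg/g: 15/53 cases, 1/47 controls
...
alpha diversity: KS D=0.136, p=0.678 (no group difference expected)
filter: 424 -> 249 taxa (175 rare/low-abundance removed)
PCA: PC1+PC2 explain 7.7% of CLR variance; 28 components reach 70.0% (target 70%)
...
matching: 47 case-control pairs over 28 PCs (6 cases unmatched)
paired DA: 18 taxa at p <= 0.05 (10 case-enriched, 8 control-enriched)
ground truth: 14/14 planted species occupy the 14 smallest p-values
...
dispersion diagnostic over 249 taxa (16 Dirichlet instances):
  taxa whose between-group difference exceeds within-group dispersion: 0
...
power at N=100 (50/group), d=0.37: 0.45 — underpowered
minimum total N for 80% power at d=0.37: 232 donors (> 200)
...
linear models: 4 of 14 candidate taxa significantly associated with calprotectin at 10% FDR
  truth check: 4/4 coupled case-enriched taxa recovered as positive associations (s__Species_0023, ...)
RDA: constrained axis explains 1.6% of CLR variance; top-5 species contain 5/6 truly coupled taxa
```

Reading it: no diversity difference between groups and no taxon whose
group-level difference exceeds within-group dispersion — yet the
paired analysis pulls all 14 planted species to the top of the
ranking, and the biomarker stage correctly singles out exactly the
calprotectin-coupled subset. That is the matched-pair design doing
what the power analysis says an unpaired test cannot.

The same pipeline is available as a CLI (`micropair simulate`,
`micropair run --profile ... --metadata ...`, plus per-stage
subcommands `filter`, `clr`, `pca`, `match`, `da-paired`,
`da-groupwise`, `power`, `biomarker`) and as a library
(`micropair.run_pipeline(PipelineConfig(...))`), both fully seeded and
byte-reproducible.

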