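# Methods

`micropair` implements a matched-pair case-control analysis of gut
microbiome taxonomic profiles, together with a synthetic-cohort
generator that provides ground truth for every stage. This note
records the statistical model, the parameter choices that matter, and
the limits of what the synthetic experiments demonstrate.

## The analysis model

Species-level relative abundances are compositional: a profile carries
only ratio information, so all Euclidean geometry (PCA, matching
distances) is done in centered log-ratio (CLR) coordinates,

    clr(x)_j = ln x_j − (1/K) Σ_k ln x_k ,

after deterministic multiplicative zero replacement (zeros → δ,
nonzeros scaled by 1 − z·δ per sample; δ = 0.65 × the smallest nonzero
proportion in the table when `delta="auto"`). This replacement is
order-preserving within samples and makes the CLR scale-invariant to
the percent/proportion convention of the input. A Bayesian posterior
replacement would differ in the third decimal of δ-scale entries and
is deliberately not used: determinism makes the whole pipeline
byte-reproducible.

**Rare-taxon filter.** A taxon is discarded iff it is observed in at
most `max_prevalence` donors (default 3) AND its maximum relative
abundance is below `min_abundance` (default 1e-4). The conjunction is
the conservative reading of "rare and low-abundance"; both thresholds
are configurable and the filter report logs which clause fired per
taxon. Diversity (Shannon, Bray-Curtis) is computed on the
*unfiltered* table — rare taxa legitimately contribute to diversity —
while every later stage uses the filtered one. This wiring is enforced
in `run_pipeline`, not inside the operations.

**Matching.** PCA scores are truncated at the smallest k whose
cumulative explained variance reaches `target_cum_evr` (default 0.70,
k capped at n−1). Greedy nearest-neighbor matching without replacement
then forms pairs tightest-first: at each step the globally closest
remaining (case, control) pair is fixed and the control retired, with
ties broken by case ID then control ID. Greedy is not globally optimal
(that would be Hungarian matching, out of scope) but is deterministic,
transparent, and recovers a planted bijection essentially perfectly
when between-pair variation dominates. With 53 cases and 47 usable
controls the pairing always has 47 pairs and 6 unmatched cases.

**Paired differential abundance.** Per taxon, within-pair differences
of relative abundances (CLR differences behind a flag) are tested with
the Wilcoxon signed-rank test: zero differences dropped, exact
two-sided p by full sign-pattern enumeration when ≤ 25 tie-free
differences remain, otherwise normal approximation with tie and
continuity corrections. Benjamini-Hochberg q-values are computed
across all non-degenerate taxa; taxa whose differences are all zero
are flagged degenerate and excluded from the FDR family rather than
being given p = 1. The report threshold is p ≤ 0.05 with q alongside
(both configurable) — deliberately permissive, since the design treats
the paired test as a discovery tool.

**Group-wise dispersion diagnostic.** Because profiles are proportions,
the Dirichlet uncertainty layer of count-based effect analysis is
approximated by reconstructing pseudo-counts at a configurable depth
(default 1e5), drawing `n_mc` Dirichlet(counts + 0.5) instances, and
CLR-transforming each. Per taxon, `diff_btw` is the median over
instances of (median case CLR − median control CLR) and `disp_win` the
median over instances of the larger of the two within-group IQRs;
a taxon "exceeds dispersion" iff |diff_btw| > disp_win. The module
deliberately makes no significance calls — its role is the negative
result (group differences buried in dispersion) that motivates
matching. It is an approximation in the spirit of ALDEx2-style
analysis, not a reimplementation of any tool.

**Power analysis.** Two-sided two-sample t-test power uses the
noncentral-t distribution with noncentrality d·√(n/2) (normal
approximation available, and used automatically if the noncentral
density underflows at extreme df). The minimum-N solver scans n upward,
so it agrees with a brute-force grid search by construction. At
d = 0.37, α = 0.05 the smallest total N reaching 80% power is 232 —
the quantitative reason a ~100-donor cohort cannot support an unpaired
group comparison and a matched design is needed.

**Biomarker association.** Fecal calprotectin above 35 µg/g (strict
inequality) is operationally "elevated". Candidate taxa are related to
biomarkers by ordinary least squares of log-transformed abundance
(half-minimum pseudocount per taxon) on the standardized biomarker with
group as a covariate — the minimal faithful core of a MaAsLin-style
model. Strictly positive right-skewed markers (calprotectin) are
log-transformed before standardization; this matches both convention
and the generator's log-linear coupling. One BH family spans all
(taxon, biomarker) tests of an invocation; significance is q ≤ 0.10.
Kendall tau-b handles ties and missing values pairwise. The RDA
ranking regresses centered CLR data on the centered covariate; the
rank-1 fitted matrix has a single constrained axis whose loading
magnitudes (∝ |per-taxon slope|) rank taxa, and the constrained
variance fraction is ‖Ŷ‖²/‖Y‖². Ranking and fraction are invariant to
affine rescaling of the covariate.

**Exact small-sample KS.** The two-sample KS p-value is exact for
tie-free samples with m·n ≤ 1e4, computed by integer lattice-path
counting of the permutation distribution (the statistic is
max |i·n − j·m|/(mn) along the pooled order, so the criterion is
integral and the count uses big integers); larger or tied samples use
the asymptotic distribution. The beta-diversity group comparison — KS
on within-case vs within-control Bray-Curtis values — is our
operationalization of a "distribution-level" comparison; pairwise
dissimilarities are not independent observations, so that p-value is
descriptive, not calibrated.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not any particular real dataset:

* **Baseline**: a power-law rank profile (log-abundance −1.5·ln rank)
  over 249 "abundant" taxa, giving realistic dominance decay.
* **Inter-individual variability**: each designed case-control pair
  shares a latent cluster effect (per-taxon SD `pair_cluster_sd`,
  default 0.9 natural-log units); each donor adds residual noise
  (`subject_sd`, default 0.3). The 3:1 ratio makes donor identity,
  not diagnosis, the dominant axis of variation — total
  inter-individual log-SD ≈ 0.95, larger than the strongest planted
  disease effect (ln 2 ≈ 0.69). These two SDs were set jointly so that
  all stated design conditions hold at once: between-pair variation
  dominates (matching is informative and the paired test beats the
  unpaired one), no taxon's group difference exceeds within-group
  dispersion at fold ≤ 2, the paired null stays calibrated, and the
  0.5-per-SD calprotectin coupling is recoverable by RDA and the
  linear models at cohort size 100.
* **Disease signal**: 7 case- and 7 control-enriched species at
  multiplicative fold 2.0, drawn from mid-abundance ranks (20–150).
  Spiking dominant taxa instead would propagate to every other taxon
  through compositional closure and turn a 14-species signal into a
  table-wide artifact.
* **Calprotectin**: exactly 15/53 cases and 1/47 controls are pushed
  above 35 µg/g by construction (elevated: 35·exp|N(0, 0.45)|;
  non-elevated: below threshold on a log scale spanning ~3–32 µg/g).
  Four of the case-enriched species plus two unspiked taxa are coupled
  log-linearly to standardized log calprotectin (slope 0.5 per SD).
* **Rare block**: 175 taxa constructed to satisfy *both* filter
  clauses exactly (1–3 donors, values < 1e-4), so the default filter
  reproducibly takes 424 → 249 taxa.

All randomness flows from a single integer seed through one named
generator; identical seeds give byte-identical tables.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: phylogenetic correlation among
taxa, strain-level structure, sequencing noise (unless multinomial
resampling is enabled, which breaks the exact 424→249 construction),
covariate confounding by age/BMI/diet, and a bulk shift of
calprotectin between groups. On the last point: only the elevated
fraction differs by design, so a whole-distribution rank test of
calprotectin between synthetic groups is marginal (p ≈ 0.1), whereas
real cohorts typically also shift the bulk. Similarly, the planted
"cluster" is a stylized stand-in for shared enterotype-like backgrounds;
real matched pairs are never this clean.

## Problem sizes and numerical choices

Simulation-heavy checks run on reduced cohorts chosen to exercise the
same structure at interactive scale: calibration and power-gain
experiments use 60–80 abundant taxa without the rare block (the rare
block is inert in those questions), structure-recovery experiments use
80–120 taxa, and replicate counts are 50–200 per experiment. The
full-scale 424-taxon cohort is used wherever the 424→249 filter split,
the 47-pair matching, or end-to-end reports are the point.

Numerical conventions: natural logarithms throughout; PCA signs fixed
by making each component's largest-magnitude loading positive; CLR
rows re-centered to machine zero so downstream zero-sum assertions
hold at 1e-9; Wilcoxon W reported as the sum of positive ranks;
all-zero difference vectors reported as missing rather than p = 1;
file floats written with 10 significant digits, which makes
read → write → read the identity on files the package wrote.

## Known limitations

* Greedy matching can be beaten by optimal matching when clusters are
  weak; the package reports formation order and distances so users can
  audit pair quality.
* The dispersion diagnostic's pseudo-count bridge understates
  uncertainty for very low-depth real data; it is a desk-scale
  approximation.
* The RDA uses a single numeric constraint; multi-covariate RDA and
  permutation tests of the constrained fraction are out of scope.
* Associations are OLS on log abundances; zero-inflated or
  count-level models are not provided.
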