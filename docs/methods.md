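# Methods

`esterodeg` re-implements, as a tested offline pipeline, the computational
analysis of a two-strain wine-yeast RNA-seq deletion experiment together
with the genetics and phenotyping statistics that surround it. This note
documents the models, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
conventions.

## Differential expression

Gene-level read counts (genes × samples, two strains with ≥ 2 biological
replicates each) are normalized to RPKM,

    rpkm[g, s] = counts[g, s] · 10⁹ / (length_bp[g] · total_counts[s]),

which removes library-size and gene-length effects but, like any
total-count normalization, is sensitive to composition: a strongly
asymmetric set of regulated genes shifts all other genes' values in the
opposite direction. No TPM or median-of-ratios alternative is offered
because the pipeline reproduces an RPKM-based procedure by design.

Each gene is tested for a strain effect by a variance-gated switch: a
Brown–Forsythe test (Levene with median centering) at α = 0.05 decides
between one-way ANOVA (homoscedastic genes) and Kruskal–Wallis
(heteroscedastic genes). The gate's α and the median centering are this
package's choices; at 3 vs 3 replicates the Brown–Forsythe test is very
conservative, so nearly all genes take the ANOVA route — which is also the
regime the original analysis describes. Raw p-values are
Benjamini–Hochberg-adjusted across all tested genes (Holm–Bonferroni is
available as an option because the source analysis names both corrections
in different places; the discrepancy is surfaced, not resolved). A gene is
a DEG only under the dual criterion p_adj < 0.05 AND |log2 fold change| ≥ 1.

Numerical conventions:

* Fold change is log2((mean_mut + ε)/(mean_wt + ε)) with pseudo-count
  ε = 0.1 RPKM, so knocked-out genes get a large finite negative value.
* Genes with zero counts in every sample, or zero variance in both groups
  with equal means, are excluded before testing (class `untested`) and do
  not enter the BH family.
* Kruskal–Wallis uses the standard tie correction; an all-tied gene is
  degenerate and handled by the rule above.
* The group tests run on raw RPKM by default; `log_values=True` switches to
  log2(RPKM + ε). Which scale the original analysis used is unstated, so
  both are exposed.
* All per-gene statistics are computed vectorized across genes; unit tests
  verify every branch per-gene against `scipy.stats.levene`, `f_oneway`
  and `kruskal`.

At 3 vs 3 replicates a Kruskal–Wallis p-value has a finite attainable
minimum (≈ 0.0495 for perfect separation), so any gene routed to the rank
branch can never survive FDR correction at genome scale. This is a property
of the procedure itself at this design size, not of the implementation.

## Overlapping-ORF correction

When two same-strand genes overlap, a position-based read counter assigns
the shared-region reads to both, double-counting them. Given region-level
counts (A-unique, B-unique, shared) per sample, `subtract_overlap` replaces
each partner's naive total by its unique-region count. The corrected count
never exceeds the naive one. This is the operation that unmasks a deleted
gene whose naive total is dominated by reads from a strongly expressed
overlapping neighbour.

## GO enrichment

Annotation is a flat gene → term table restricted to the universe of
quantified genes (no ontology-graph propagation; the source analysis used
a flat association file). For each term, exact hypergeometric tails
p_over = P(X ≥ k) and p_under = P(X ≤ k) are computed; the smaller tail is
the per-term p, adjusted across terms (BH default, Holm optional), and a
direction (enriched/depleted) is assigned when the adjusted value clears
α. Queries are run separately for up, down and combined DEG sets.

## PPI clustering

The pairwise confidence-score matrix of DEGs (scores in [0, 1]; the
0–1000 integer evidence scale is rescaled automatically; missing pairs
score 0) is transformed to distance d = 1 − score — the minimal monotone
transform for a [0, 1] similarity — and clustered agglomeratively with
complete linkage. The original clusters were "defined visually"; for
reproducibility the tree is instead cut at an explicit height (default
0.95). Each flat cluster is scored by the mean of all within-cluster
pairwise similarities and retained when it has more than 10 members and a
mean score above 0.4. Ties in the agglomeration follow SciPy's
deterministic lowest-index order, which makes the output invariant under
input permutation up to cluster labels.

## Histone-modification enrichment

Each gene carries ratios for 8 modifications (3 acetylations: H3K9ac,
H3K14ac, H4ac; 5 methylations: H3K4me1/2/3, H3K36me3 and a fifth
methylation column whose name is configurable). Up- and downregulated
gene classes are compared to non-significant genes per modification with a
two-group Kruskal–Wallis test (identical to the rank-sum test for two
groups, kept as KW for fidelity to the source procedure), BH-adjusted
across all 16 class × modification tests — the family is this package's
choice, as the source names the correction but not the family. Fold
enrichment is the ratio of class mean to reference mean; missing ratios
are dropped per modification, not per gene.

## Meiotic segregation

A diploid is described per locus as wt/wt, wt/del or del/del; loci are
modeled unlinked (the study's stated premise — the deleted genes lie on
different chromosomes), with no recombination-fraction parameter. The
probability that a spore carries a required deletion set is the product of
per-locus factors 0, ½ or 1 — giving 1/32 for a quintuple heterozygote and
1/8 once two loci are fixed homozygous-deleted — and per-pair
double-deletion carrier frequencies follow the same product rule (¼, ½
or 1).

`simulate_spores` draws 4·n_tetrads spores either with exact 2:2
segregation of each heterozygous locus within a tetrad (`tetrad` mode) or
independently per spore (`random_spore`); both modes have identical
marginals for unlinked loci. Viability is an ordered list of
first-match-wins rules (haplotype predicate → survival probability,
default 1) applied per spore after the genotype draw: germination is
modeled at the spore level. A separate zygote-level survival hook (default
off) can remove whole tetrads, representing prezygotic incompatibility.

Carrier deficits are tested per locus pair with a 1-df carrier/non-carrier
chi-square goodness-of-fit against the expected frequency — the framing of
the original test is unstated, so this contingency construction is a
documented interpretation. Degenerate expectations (0 or 1) with occupied
opposite cells fall back to an exact binomial and are flagged.

## Metabolite and sensory statistics

* `normalize_by_control` divides each compound's values by the control
  strain's mean (control relative mean ≡ 1); idempotent on normalized data.
* `kw_lsd` is the `agricolae`-style procedure: omnibus Kruskal–Wallis,
  then rank-based Fisher-LSD comparisons of each group against the control
  with BH correction (default α = 0.01). Two constant, equal groups return
  an omnibus p of 1 by convention. At 3 replicates per group and few
  groups, the rank LSD cannot reach α = 0.01 — significance at that level
  needs the larger designs the original study used (up to 6 replicates,
  many strains).
* `anova2_hsd` fits value ~ strain + must + strain:must by OLS with
  type-II sums of squares (identical to the classical decomposition for
  balanced designs, verified against an explicit arithmetic oracle) and
  runs Tukey HSD on significant main effects. All-constant responses are
  reported untestable.
* `triangular_test` is the one-sided exact binomial tail with chance level
  1/3 — one-sided because forced-choice discrimination only ever tests for
  above-chance performance.
* `descriptor_wilcoxon` compares two wines per descriptor; paired
  signed-rank over judges by default (each judge rated both wines), with
  zero differences dropped (identical vectors → p = 1, not significant)
  and exact p-values at small n; an unpaired rank-sum mode is exposed as a
  flag because the original pairing is unstated.

## Synthetic-data generators

All generators derive their streams from a single `SeedSequence` with
fixed per-generator spawn keys, so one integer seed reproduces every input
byte-identically.

**Counts.** Negative-binomial counts (mean µ drawn loguniform from
10–2000 per gene; variance µ + µ²/dispersion) for 6000 genes × 2 strains ×
3 replicates by default. The default planted differential set is strongly
up-biased (1100 up, 22 down at log2FC 2), four genes (ATF1, ATF2, EEB1,
EHT1) are knocked out in the mutant with Poisson(0.5) residual counts
(matching "very few reads", not hard zeros), and one overlap pair
(ATF2–YGR176W) is emitted as region-level counts (A-unique, B-unique,
shared) plus naive per-gene totals that double-count the shared region.
The neighbour gene is set strongly expressed and the overlapped gene's own
transcription to a small fraction of the shared signal, so that the shared
reads mask the knockout until the subtraction — the situation the
correction exists for. The default NB dispersion (size 10) is moderate
overdispersion typical of biological triplicates; the calibration runs use
size 100 ("low dispersion") where the procedure's power is limited mainly
by replicate number.

**GO annotation.** Random term memberships with optional planted terms
packed with a stated excess of query genes, enriched by construction.

**PPI.** Symmetric block matrices: within-block scores drawn strictly
above the background range, so planted blocks are recoverable by any cut
inside the gap.

**Histone.** Baseline ratios Normal(1, 1) per modification; up-genes
shifted by +1 on the first 7 of 8 modifications and down-genes by −0.75 on
the first 5, emulating the concentration of chromatin-mark changes in
overexpressed genes.

What the generators do **not** emulate: read-level sequencing error and
mapping ambiguity, GC/length biases, correlated gene modules, a realistic
GO DAG, STRING's evidence-channel structure, or inter-replicate library
effects beyond NB noise. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under its own model
assumptions, not that the pipeline is robust to every artifact of real
sequencing data.

## Problem sizes and calibration

The test suite and the acceptance script run desk-scale versions of each
study: null calibration uses 50 simulations of 2000 genes (raw false-
positive rate ≈ 0.049, median DEG count 0); planted-effect recall is
measured on 2000 genes with 110 planted fourfold effects at NB size 100
(recall ≈ 0.89–0.93 depending on seed, direction accuracy 1.0 — the
residual misses are planted genes drawn at the low end of the expression
range, where 3-replicate power runs out); spore simulation uses 25 000
tetrads (10⁵ spores), where all haplotype frequencies sit within 3
binomial SE of the product-rule expectations; the end-to-end scenario uses
2000 genes, a 60-protein score matrix with planted blocks of 15, 18 and 10
members, and 7-of-8 shifted histone modifications. The original
dataset-level results (6287 quantified genes, 1124 DEGs, 23 GO terms,
13 PPI clusters) depend on deposited reads and live STRING/GO resources
and are represented by these recovery properties rather than reproduced
numerically.

## Known limitations

* RPKM's compositional sensitivity biases fold changes of unregulated
  genes when the planted set is strongly asymmetric (visible in the
  scenario as a small negative shift of null genes' log2FC).
* The Brown–Forsythe gate has essentially no power at 3 vs 3; the
  Kruskal–Wallis branch exists for fidelity but rarely fires at that
  design size.
* BH across 16 histone tests occasionally drags a null modification below
  the FDR cutoff when the other 15 are extreme (~5% of seeds in the
  scenario conditions).
* The chi-square pair-deficit test uses the large-sample approximation;
  at the study's scale (~100–300 spores) expected cell counts are large
  enough, but tiny dissections should rely on the flagged exact fallback.
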