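# Methods

## Problem setting

Low rDNA copy number (CN) in *Drosophila* males triggers germline rDNA
magnification: CN expansion by unequal sister chromatid exchange, restricted
to germline stem cells (GSCs). Finding the genes GSCs regulate in response
to low CN requires (i) isolating a rare cell type from testis single-cell
data cleanly enough for differential expression, and (ii) guarding the
resulting gene list against two systematic artifacts of droplet single-cell
assays — ambient RNA shared across all droplets, and GSC:cyst doublets —
plus a biological specificity requirement (the change should be absent in
the differentiating spermatogonia, SG). The package implements this
discovery cascade together with the two quantitative assays used around it:
ddPCR copy-number estimation and magnification-cross scoring.

## Discovery pipeline

**QC.** Cells are kept when total counts lie in [5,500, 250,000] and
detected genes in [200, 9,000]. Bounds are read as inclusive ("between … and"
as a closed interval): conservative and boundary-testable. QC is idempotent.

**Normalization.** Each cell is scaled to a common target (the median
library size unless configured) and log1p-transformed. Zeros map to zeros.
The method is the common library-size default of single-cell toolkits; it is
configurable because the choice is a convention, not a result.

**Embedding.** The 2,000 most variable genes (variance of normalized
expression) are standardized per gene and projected onto 14 principal
components (randomized SVD, seeded, deterministic). The 14 dimensions are
the analysis setting of the study design this pipeline follows; a 2-D
nonlinear layout is considered visualization and is not computed.

**Clustering.** Leiden community detection (RBConfiguration = modularity
with a resolution parameter, resolution 0.5) on an undirected k=20
nearest-neighbour graph of the embedding. Cluster ids are relabelled
contiguously by first occurrence, so partitions are deterministic given the
seed and stable up to relabeling under cell permutation.

**Annotation.** Panel score of a cluster = mean over the panel's markers of
the fraction of cells with raw count ≥ 1. Panels: GSC&SG {vas, nos, ovo},
Cyst {dlg1, CadN, tj, zfh1}, spermatocyte {fzo, CycB}, spermatid {CG32106,
m-cup}. A cluster takes the best label when its score reaches the
predominance fraction (0.5; "predominantly" is not quantified upstream, so
this is a package decision) and otherwise falls back to the strongest score.
Clusters predominant for both GSC&SG and Cyst are flagged mixed (suspected
doublets) and excluded from downstream selection. Ties break to the
lexicographically smallest label.

**GSC selection, cluster-based.** Cells of GSC&SG-labelled clusters plus the
largest Cyst cluster (outgroup) are re-normalized, re-embedded and
re-clustered with the same parameters. Subcluster calls: GSC when the mean
nos/ovo positive fraction is ≥ 0.5; SG when vas-positive (fraction ≥ 0.5)
but nos/ovo-depleted (mean positive fraction < 0.5); mixed (excluded) when a
germline call coincides with a predominant Cyst score; Cyst otherwise when
the Cyst panel is predominant. The depletion-based SG rule mirrors the
wording "vas positive, but mostly devoid of nos and ovo" and avoids a
tie-break between two panels that both contain vas. The SG cell set feeds
the specificity filter.

**GSC selection, expression-based.** Cells from any cluster with raw count
≥ 1 for each of vas, nos and ovo and exactly 0 for tj and zfh1. "Positive" =
count ≥ 1 and "negative" = count 0 is the simplest defensible reading and is
configurable. This method is independent of clustering by construction and
is the more stringent of the two (marker dropout excludes many true GSCs),
so the two selections differ in size by design.

**Differential expression.** Two-sided Wilcoxon rank-sum on log-normalized
expression (ranks are invariant to the monotone transform), low-rDNA cells
over normal-rDNA cells. Exact enumeration when min(n) ≤ 10 with no ties;
otherwise normal approximation with midranks, tie correction and continuity
correction. Effect size log₂((x̄_A + 1)/(x̄_B + 1)) on de-logged normalized
means (pseudocount 1, configurable). Genes detected in neither group are
skipped and excluded from the Bonferroni factor G; p_adj = min(1, p·G).
Significant ⇔ p_adj < 0.05 and |log₂FC| > 0.25. No minimum-detection
prefilter is applied (none is specified upstream).

**Candidate cascade.** (1) Intersection: genes significant in both
selections with the same direction; the reported effect is the
smaller-magnitude fold change and the larger adjusted p (conservative).
(2) Ambient filter: up-candidates also significantly up in the somatic
(Cyst-labelled) cells are removed — soup from lysed cells adds counts to
every droplet, so a shared somatic/germline increase is suspect;
down-candidates cannot be soup artifacts and are never removed. The filter
runs after the intersection (the upstream ordering is ambiguous; flags
record both states). (3) SG specificity: candidates significant in SG in the
same direction are flagged non-specific; "no expression change" is
operationalized as not significant at the same thresholds. Filters only
shrink the set: final ⊆ intersection ⊆ each method's significant set.

## Synthetic-data generator

The generator emulates one 10x run per rDNA condition over five testis cell
types. Counts are negative binomial (variance μ + μ²/θ, θ = 10 shared across
genes) around per-type expected profiles, scaled by a lognormal library
factor (σ = 0.3 around a ~12,000-count library, chosen to sit inside the QC
window the pipeline uses).

* **Gene means.** Background genes draw lognormal relative abundances
  (σ = 1.2) with mean 6 counts/cell. Marker/program genes sit at 0.25
  off-type and fold × 0.25 on-type (named markers fold 40 → ~10 counts;
  15 anonymous program genes per type at fold 12 give each type a
  separable identity beyond the canonical markers, as real cell types
  have). vas is a shared germline program (GSC and SG) — per-type programs
  themselves are disjoint and validated as such.
* **Planted effects.** Genes carrying condition effects sit at base mean
  4.0 (high enough that a |log₂FC| = 1 effect clears the 0.25 fold-change
  threshold after the pseudocount). Defaults: 30 GSC-down, 20 GSC-up,
  10 + 10 shared GSC+SG, 10 ambient artifacts, all |log₂FC| = 1 in the low
  condition.
* **Ambient contamination.** Each condition has its own soup — the
  library-weighted average of that condition's expected profiles — and a
  fraction ρ = 0.05 of every cell's expected counts is replaced by it, at
  the expected-value level (counts stay integral and expected library size
  is exactly preserved). Per-condition pooling is what makes
  condition-dependent soup artifacts possible at all, which is the failure
  mode the ambient filter exists for. Artifact bait genes are
  spermatocyte-specific at fold 256 (~64 counts): only highly expressed
  genes move the soup composition enough to shift other types' means past
  the significance thresholds — which is also why real ambient artifacts
  are dominated by highly expressed transcripts.
* **Doublets.** A fraction δ = 0.05 of output barcodes (0.10 in the
  stress test) are sums of one fresh GSC-program cell and one cyst-program
  cell, so a doublet's counts are exactly the sum of its two sources.
  ρ and δ defaults are placeholders — the upstream study does not
  characterize its soup or doublet levels.
* **QC outliers.** 2% of singlets have their expected library forced
  outside the QC window (half low, half high).

Cell numbers per type per condition (GSC 600, SG 400, spermatocyte 300,
spermatid 300, cyst 400; ~4,200 barcodes total) were fixed by an up-front
power analysis so that the weakest planted signal — the ambient artifact
leak into the ~300-cell expression-based GSC groups — clears Bonferroni
significance with margin. This is a desk-scale stand-in: the real study
sequenced 20,138 cells, and the generator makes no attempt at UMI
saturation, sequencing error, batch effects, or realistic gene-gene
correlation beyond the type programs.

What passing tests show, and what they do not: recovery of planted truth
demonstrates the cascade's logic (selection, testing, filtering) is correct
under the generative model the filters assume; it does not certify
performance on real data, where ambient profiles, doublet composition and
within-type heterogeneity are messier.

## Assay statistics

**ddPCR.** λ = −ln(1 − k/n) copies/droplet (Poisson occupancy; the
instrument software's standard correction, reconstructed here since the
formula is not printed upstream). Saturated wells (k = n) are rejected. The
λ CI transforms a Wilson binomial interval (stable at k = 0) through the
same map. Copy number: replicate-averaged λ per gene; reference genes
combined by geometric mean (ratio-of-ratios robustness; arithmetic mean via
config); cn = λ_target/g × ref copies per genome-equivalent — reported per
genome-equivalent with the reference copy number configurable, since
absolute calibration (droplet volume) cancels in the ratio. The cn CI
propagates the binomial variance of ln λ through the ratio on the log
scale. Group comparison: Welch's t by default ("Student's t-test" upstream
names no variance assumption; pooled is available), with per-group t-based
95% CIs of the mean.

**Magnification crosses.** Frequency = wild-type / (wild-type + bobbed);
Bar-marked offspring never enter the denominator. Proportion CIs use the
textbook Wald formula p̂ ± z√(p̂(1−p̂)/n) truncated to [0,1] — degenerate at
k = 0 or k = n, a documented limitation; Wilson is available via config.
2×2 comparisons use Pearson chi-squared without continuity correction (no
correction is named upstream, and the uncorrected statistic has a clean
closed-form oracle); Yates is available via config. Families of comparisons
are Bonferroni-corrected with the number of comparisons reported explicitly.

**Enrichment.** fold = (|query ∩ annotated|/|query|)/(|annotated|/background)
with the chi-squared test on the induced 2×2 table.

## Numerical and testing choices

* One `numpy.random.default_rng` seed drives each stochastic operation;
  Leiden receives a derived non-negative 31-bit seed. Fixed seed ⇒
  byte-identical pipeline outputs.
* PCA uses seeded randomized SVD; deterministic up to scikit-learn's sign
  convention. Degenerate inputs (rank-deficient data) leave trailing
  components at zero variance rather than erroring.
* Cluster-recovery is asserted two ways: raw-partition ARI ≥ 0.9 against
  planted types on an experiment without planted condition effects (type
  programs are then the only structure), and ARI ≥ 0.9 of annotated
  per-cell labels against truth at marker-panel resolution on the default
  experiment. On the default experiment the 70 planted GSC effects are
  themselves genuine cluster structure — Leiden correctly refines GSCs
  into low/normal sub-populations, which raw ARI against the 5 types would
  misread as error.
* The chi-squared oracle test draws the test's actual null (two binomials
  at the pooled rate) at a moderately sized table: at tiny tables
  (n = 20 per row) the discrete conditional null sits ~0.03 above the
  asymptotic p, so closer agreement is only meaningful at moderate counts.
* Doublet-exclusion performance is measured against GSCs present in the
  QC-passed matrix — the input of the selection step being scored.

## Known limitations

* The Wald interval under-covers for small n or extreme p (use Wilson).
* Marker positivity thresholds of 1 count make the expression-based
  selection sensitive to ambient marker leakage; the tj/zfh1 = 0 rule
  excludes roughly half of true GSCs at realistic soup levels (by design —
  it trades recall for purity, as the size gap between the two selection
  methods reflects).
* The generator's shared NB dispersion and independent genes understate
  real overdispersion structure; calibration results (type-I error,
  coverage) hold under the generative model, not as guarantees on data
  with correlated genes.
* No batch integration, no covariate adjustment in DE, no alternative FDR
  procedures: single-factor two-condition designs only.
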