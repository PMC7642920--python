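# Methods

## The statistical pipeline

`seedqtl` implements a staged genetical-genomics analysis for biparental
recombinant-inbred-line (RIL) populations: gene-level log2 expression of
disjoint subpopulations (one per developmental stage, here the four seed
germination stages PD, AR, IM, RP) is scanned marker-by-marker for
expression QTL, significant eQTLs are classified as local or distant,
genomic bins enriched in distant eQTLs are flagged as hotspots, and an
ensemble co-expression network over each hotspot's genes prioritizes its
candidate master regulators.

### Single-marker scan

For gene *i* and marker *x* the model is the simple linear regression

    y_ij ~ x_j + e_j

with homozygous genotypes coded −1 (allele A) / +1 (allele B).  The reported
score is −log10 of the two-sided p-value of the genotype slope, which for a
balanced binary regressor is identical to a pooled-variance two-sample
t-test.  Implementation notes:

* scores come from the Pearson correlation *r* between y and the coding via
  t = |r|·sqrt(df/(1−r²)), df = n−2, with `scipy.stats.t.logsf` so that
  extreme associations keep precision; exact fits are capped at a
  configurable score of 300;
* monomorphic markers and constant genes score 0 (cells kept, not dropped);
* missing genotype calls are excluded pairwise per marker (a marker needs
  ≥ 3 informative lines);
* the variance explained per cell is r², and the allelic effect sign is
  sign(r) (positive = B allele higher).

### Permutation threshold

Genome-wide significance per stage uses per-gene permutations: each gene's
expression values are shuffled over the lines independently, the scan is
repeated, and the per-gene genome-wide maximum score is recorded; 100 rounds
by default.  On a candidate grid T = 0, 0.1, …, 20 the procedure accepts the
smallest T with RDS(T) > 0 and

    FDS(T) / RDS(T) ≤ (m0/m) · q · log(m),     m0 = m − RDS(T)

where RDS counts genes whose real maximum reaches T, FDS is the mean such
count over permutation rounds, m is the number of genes and q = 0.05.  The
log is natural by default (`threshold_log_base="10"` switches it); the
discovery unit is the gene (its genome-wide maximum), matching the per-gene
permutation scheme.  If no grid point qualifies a `NoThresholdError` carrying
the full FDS/RDS table is raised — on a pure-noise matrix this simply means
nothing is separable from the permuted scans.

When no genotypes are missing the residual df is constant across markers, so
permutation rounds only convert each gene's maximum |r|, keeping 100-round
scans of thousands of genes to a few seconds.

### Peaks, intervals, classification

Per gene, at most one peak per chromosome is called: the maximum-score
marker at or above the threshold, leftmost on ties.  The confidence interval
extends over the contiguous run of markers within a 1.5 drop of −log10(p)
from the peak, stopping at the first marker below the cutoff (interior
valleys are not skipped).  An eQTL is **local** when the gene lies on the
peak chromosome and its annotated start is within 1 Mb (inclusive) of the
span [min(ci_start, peak), max(ci_end, peak)]; otherwise **distant**;
unannotated genes are labeled **unknown** and excluded from hotspot counts.
The gene "location" is its start coordinate.

### Hotspots

The genome is tiled with half-open 2 Mb bins anchored at 0 per chromosome
(partial terminal bins kept).  With λ = (total distant eQTLs)/(total bins),
a bin with observed count k is a hotspot when the Poisson upper tail
P(X ≥ k) < 1e-4.  Assignment uses the peak position, not the CI.  Adjacent
significant bins are reported separately by default (`merge_adjacent=True`
joins them under one id).  The same scan/threshold machinery runs on
phenotype or metabolite trait matrices (no local/distant labels) to count
collocating trait QTL per bin.

### Ensemble network and prioritization

Genes with a local eQTL peaking inside a hotspot bin are candidate
regulators; genes with a distant eQTL there are targets (a gene with both
stays a candidate).  Five methods score the candidate∪target expression
submatrix:

* **|Spearman|** — absolute rank correlation (symmetric);
* **CLR** — each gene's mutual-information profile is z-scored against its
  own background (negatives clipped), edge score sqrt(z_i² + z_j²);
* **ARACNE** — the MI matrix after data-processing-inequality pruning: in
  every triangle the strictly weakest edge is removed (tolerance 0);
* **GENIE3** — per target, a 1,000-tree random-forest regression on all
  other genes (sqrt feature sampling); directed importances normalized to
  sum 1 per target;
* **TIGRESS** — per target, LARS stability selection: 500 rounds of
  half-sampling with Uniform(0.2, 1) predictor reweighting, scoring the
  selection frequency within the first 5 LARS steps.

Mutual information uses a plug-in estimator on 10 equal-frequency bins —
standard CLR practice and robust at ~40 samples; the plug-in bias is
positive but cancels in CLR's background standardization and is shared by
all edges in ARACNE's triangle comparisons.

GENIE3 fixes the orientation of every gene pair first (the direction with
the larger importance survives; ties prefer candidate → target, then the
lexicographically smaller source), then all methods are integrated by
averaging their per-edge ranks over the kept directions (rank 1 = strongest,
midrank on ties).  The reported network is the shortest prefix of the
ascending average-rank edge list in which every candidate and target is an
endpoint; the threshold is the average rank of the last admitted edge.
Candidates are ranked by outdegree, ties by closeness centrality — here the
number of reachable nodes divided by the summed directed shortest-path
lengths to them (0 when nothing is reachable) — then gene id.  Orienting
before aggregation yields exactly one rank list per pair; the alternative
order (aggregate, then orient) is not exposed.

### Transcriptome overview

PCA runs on gene-centered, unscaled log intensities with samples as
observations; variance fractions are of total variance.  The stage filter
keeps genes with |Δ mean log2| ≥ log2(2) between at least one consecutive
stage pair (PD→AR, AR→IM, IM→RP), on stage means over all samples of a
stage.  Filtered genes are clustered by Ward linkage (ward.D2 convention via
scipy on condensed distances) on the distance 1 − |Pearson r|, cut into 8
clusters; zero-variance profiles get distance 1 to everything.

### Normalization

`quantile_normalize` maps every sample column onto the vector of per-rank
column means; tied values receive the mean of their tied ranks' normalized
values (the limma `normalizeQuantiles` convention), making the operation
idempotent.  Whether to normalize within stages or across all samples is the
caller's choice; the pipeline default is one matrix, all samples.  The
package ingests gene-level matrices; probe handling and array QC are
upstream and out of scope.

## Synthetic data generator

The generator emulates the study design, not microarray physics:

* **Genotypes** — per chromosome, a two-state Markov chain over the ordered
  markers.  Inter-marker distance in Morgans (from `cm_per_mb`, default
  4 cM/Mb) enters the Haldane map function r = (1 − e^(−2d))/2 — no
  crossover interference — expanded for selfed RILs to R = 2r/(1 + 2r).
  Chromosomes segregate independently; allele frequency is 0.5; lines are
  fully homozygous (A/B).  Defaults: 1,059 markers over five chromosomes of
  30.4/19.7/23.5/18.6/26.9 Mb; 40 lines per stage, four stages drawn as
  independent subpopulations sharing the same planted truth.
* **Expression** — additive Gaussian model y = baseline + Σβ·g + ε with
  ε ~ N(0, noise_sd²), noise_sd = 1 log2 unit and per-gene baselines
  N(8, 1) shared across stages.  A `local_fraction` of genes receives a
  local eQTL: the gene start is placed within 1 Mb of its causal marker and
  β = noise_sd·sqrt(r²/(1−r²)) so the genotype explains `local_r2` of the
  variance (Var(g) = 1 under ±1 coding).  Hotspot specs plant a master
  regulator (a gene with a strong local eQTL, default r² = 0.6, at a chosen
  locus) and n targets placed away from that locus, driven either by the
  regulator's standardized expression (`expression_mediated`, default) or
  directly by its genotype (`genotype_direct`).
* **Stage structure** — 5% of genes get per-stage offsets of SD 2 log2
  units (shared across lines within a stage), giving the fold-change filter
  and the PCA something real to find; roughly matching the small fraction
  of stage-responsive genes seen in staged germination transcriptomes.
* **Network fixture** — `simulate_network_scenario` builds a star topology:
  one hub among decoy candidates linearly driving all targets.

What the generator deliberately omits: probe-level intensity effects,
epistasis, crossover interference (Haldane, not Kosambi), segregation
distortion, correlated residual structure (batch effects), and
dormancy-specific biology.  Tests passing on these fixtures demonstrate the
statistical machinery — exactness of the scan, FDR behavior of the
threshold, calibration of the Poisson test, hub recovery of the ensemble —
not performance on real microarray data.

## Problem sizes and numerical choices

The test and benchmark runs use desk-scale versions of the study design:
2,000-gene null/signal matrices with 200 markers for FDR behavior, 1,000
genes × 1,059 markers for recovery, 1,000 replicates for hotspot
calibration, and 20 seeds of a 10-candidate/30-target star for network
recovery (GENIE3 at 100 trees and TIGRESS at 50 resamples there; the
estimator defaults remain 1,000/500).  Degenerate inputs are handled
explicitly: monomorphic markers score 0; constant genes correlate 0;
sd = 0 rows in CLR give z = 0; two-gene ARACNE inputs have no triangles;
single-marker chromosomes give point confidence intervals.  All randomness
flows from explicit seeds; pipeline child seeds derive from the master seed
via `numpy.random.SeedSequence([master, index])`.

## Known limitations

* **Recovery power at weak effects.** With 40 lines per subpopulation,
  planted local eQTLs at R² = 0.3 sit near the detection limit: the causal
  t statistic is noncentral-t with ncp = sqrt(40·0.3/0.7) ≈ 4.1 while the
  permutation threshold lands around 3.5–3.7 score units, so only ~50–65%
  of such eQTLs are recovered.  This mirrors the low per-gene power of
  40-line single-marker designs generally; recovery rises steeply with
  `local_r2` or `n_lines`.
* The scan fits one marker at a time — no covariates, kinship correction,
  interval mapping or epistasis.
* ARACNE pruning enumerates triangles (O(p³)); fine for hotspot-sized gene
  sets (~100–200 genes), not for genome-wide networks.
* Closeness follows the reachable-set convention above; scores are not
  comparable across networks with different reachability structure.
* GO-term enrichment of clusters and hotspot gene sets requires an external
  annotation database and is out of scope; cluster and candidate tables are
  exported for external tools.
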