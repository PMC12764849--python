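# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
benchmarks do and do not establish.

## Data model and containers

The pipeline operates on a sparse cell × gene matrix (raw counts or
log-normalized values), a per-cell metadata table (patient, integer cycle ≥ 1,
biopsy site, cell type, ploidy ∈ {diploid, aneuploid, not.defined,
unassigned}, detected-feature count, mitochondrial percentage), and named
gene-set collections. Counts are exchanged as matrix-market coordinate
files (genes × cells, 1-based) with row-aligned annotation files; gene sets
as GMT; everything else as TSV. Duplicate gene symbols are collapsed by
summation on read (symbols are the gene identity; collisions are logged).

## Quality control and normalization

Cells are retained when `min_features < n_features < max_features` and
`pct_mt < max_pct_mt`, all strict, with defaults 300 / 8000 / 5% — the
standard droplet single-nuclei thresholds for this tissue type. A 4%
assumed doublet rate is carried as provenance only; doublet removal is
upstream of this package. The pre-scoring transform is log1p of
counts-per-10k. A more elaborate count-model normalization would be
defensible, but the scoring statistic depends only on within-cell ranks,
which any strictly monotone per-cell transform preserves; the choice is
recorded in each score matrix's config snapshot so runs are auditable.

## ssGSEA scoring

Per cell, the descending-rank statistic assigns r = N to the most expressed
gene and r = 1 to the least, ties (including the zero block of sparse data)
receiving average ranks. The enrichment score for set S is the full running
sum ES(S) = Σᵢ [P_in(i) − P_out(i)] (not the maximum deviation), with in-set
steps weighted by r^α, α = 0.25. Summing the walk analytically gives

    ES(S) = Σ_{g∈S} r_g^{α+1} / Σ_{g∈S} r_g^α  −  Σ_{g∉S} r_g / (N − |S|),

which is computed for the whole cell × set matrix with two matrix products.
For untied data this is *identical* to the positional walk; for tied data it
equals the walk's expectation over tie-consistent orderings, which makes
scores independent of input gene order — a property a literal positional
walk does not have. Optional normalization divides the whole matrix by its
global max − min (range width 1, ordering preserved); both behaviors are
supported since score consumers differ on this. Sets are size-filtered on
their overlap with the panel (default 2–1000); sets covering the entire
panel are dropped because the out-of-set ECDF is undefined.

## Temporal linear modeling

Each feature is fit per patient by OLS of the response on the numeric cycle,
cells as independent observations, biopsy sites pooled — a deliberately
simple single-term model matching one-estimate-per-patient-per-feature
reporting. No random effects are used; with cells correlated within biopsies
the standard errors are anti-conservative for inference beyond the sampled
tumors, and this is a known limitation. By default fits use aneuploid
(malignant) cells only, with a flag to include all cells. Zero-variance
responses report estimate 0 with missing p/FDR; groups with one distinct
cycle are skipped with a warning. BH adjustment is step-up with enforced
monotonicity, applied across features within each (patient, feature-family)
batch; missing p-values pass through and do not count toward m. Volcano
classes use strict inequalities (fdr < 0.05 and |estimate| > cutoff); a
feature at exactly the cutoff is non-significant.

## Archetype discovery

Pathway-score columns are mean-centered (not scaled) before SVD; the
smallest leading component set reaching 90% cumulative variance is kept.
Scaling to unit variance happens only inside the batch-distance computation,
preserving the order of the two operations: batch detection picks the
component with the largest absolute between-group mean difference of the
scaled components (maximum pairwise difference if more than two groups,
ties to the lowest index) and removes exactly that one. Removal is skipped
in single-patient runs. If the best distance is below 0.1 (unit-variance
scale) a warning notes the batch effect may be negligible; removal still
occurs unless disabled, since the operation is defined unconditionally.

K selection: for each k in 2..10, 100 k-means runs (Euclidean, one random
initialization each — run-to-run variability is the quantity measured) on
fresh 80% subsamples accumulate co-clustering and co-sampling counts;
consensus(i,j) is their ratio, pairs never co-sampled are excluded rather
than imputed (at 100 × 80% a pair is co-sampled ~64 times, so exclusion is
rare); PAC is the fraction of off-diagonal consensus values strictly inside
(0.1, 0.9); the selected k maximizes 1 − PAC with ties to the smallest k.
Seeds for subsampling and k-means derive from one SeedSequence per k, so
results are reproducible and k-blocks are independent.

Clustering to the selected K uses a 20-nearest-neighbor graph in the
embedding, shared-nearest-neighbor Jaccard edge weights pruned below 1/15,
and Louvain modularity clustering; the resolution bridging K to modularity
is found by geometric bisection on [0.01, 5] (≤ 30 steps), returning the
nearest achievable cluster count with a warning when K is unreachable.
Communities smaller than 10 cells (stray SNN components) are folded into
the nearest cluster by centroid distance before counting, as graph
clusterings of noisy embeddings conventionally handle singletons. Archetype
profiles are the top 20 positively enriched pathways per archetype by
two-sided Wilcoxon rank-sum versus all other cells, BH-adjusted within
archetype, ranked by FDR then effect (difference of means); archetypes with
fewer than 3 cells are excluded. Proportions are per-(patient, cycle) label
fractions. Copy-number subclones use Euclidean K-means (K = 2 by default,
10 restarts, fixed seed).

## Malignancy rescue classifier

The classifier is the rank-correlation core of reference-profile
annotation: per-label mean log-normalized profiles over the top-2000
dispersion (variance/mean) genes, each cell assigned the label whose profile
its expression Spearman-correlates with best. The iterative fine-tuning
step of full reference annotation is omitted — with two labels there is no
label subset to iterate over. Model quality is the unweighted mean of
one-vs-rest AUCs of the correlation margin (own minus best competing label)
over stratified held-out folds (5, reduced with a warning if a class is
smaller). Predictions are accepted only when this AUC strictly exceeds 0.7;
a rejected model leaves the metadata untouched. Rescued cells are flagged in
a provenance column; confident labels are never altered.

## Pipeline orchestration

`run_all` executes input/simulation → QC → scoring → temporal →
classification → archetype discovery from one config. Classification runs
before archetype discovery so that rescued aneuploid cells join the
malignant set that archetype discovery consumes. All randomness flows from
one seed through named per-stage SeedSequence substreams; every output file
is SHA-256 hashed into a manifest, and a failed stage writes a partial
manifest naming itself.

## Synthetic cohort generator

Gene log-means compose additively: lognormal baselines (σ = 1 across genes,
scaled to a 6000-count mean library); +1.0 log-fold archetype programs on
disjoint 50-gene sets for aneuploid cells, drawn per cycle from the
configured mixing schedule; per-pathway trends slope·(cycle−1) on dedicated
50-gene sets; a per-patient batch offset N(0, 0.5²) per gene; log-dosage on
four contiguous 50-gene CNA blocks (1.5×/0.5×) for aneuploid cells. Counts
are NB(mean = L·μ, size r = 2) with lognormal library factors (σ = 0.35).
Defaults mirror the modeled study design: two patients with 6 and 2 cycles,
1000 cells per biopsy (5–12k per patient), mixing schedules following the
reported per-cycle archetype proportions (50/50 drifting to ~69.5/30.5 by
cycle 4 and reversing to ~34/66 by cycle 6 for the first patient; stable
~69/31 then ~64/36 for the second), 80% aneuploid cells, 10% ploidy labels
masked to not.defined, and small low-quality (2%, ~3% library) and
high-mitochondrial (2%, ~15% MT share) fractions so QC filtering is
exercised. A 2000-gene panel stands in for the transcriptome — large enough
for realistic per-gene depths at single-nuclei library sizes, small enough
for fast benchmarks.

**Induced trend slopes.** The temporal stage fits mean log1p-CPM over a
pathway's genes, but trends are planted on gene log-means; log1p curvature
at single-cell depths attenuates the slope (≈30% at these settings), and
unbalanced trends additionally shift CPM denominators (the default ±
symmetric slopes cancel this). Because OLS is linear in the response, the
fitted slope is exactly unbiased for the OLS slope of the per-cycle
*expected* response; the generator computes that expectation
semi-analytically (exact NB pmf summation, 21-node Gauss–Hermite integration
over the library factor, total counts approximated by their conditional
mean — an approximation worth ~2×10⁻⁴ in slope, a sixth of a typical
standard error) and records the induced slope per pathway and patient.
Recovery benchmarks compare CIs against these induced values; comparing
against the raw planted log-mean slopes would conflate estimator quality
with transform curvature.

**What the generator does not emulate:** transcriptome-wide gene-gene
correlation beyond programs, ambient RNA, doublets, zero inflation beyond
NB sampling, genome positions (CNA blocks are index-contiguous stand-ins),
and patient-level biological heterogeneity beyond the batch shift. Passing
benchmarks therefore demonstrate that the estimators recover the structure
they assume, at realistic depths and sample sizes — not that real tissue
meets those assumptions.

## Benchmark problem sizes

The test-suite and acceptance-script benchmarks use: 20 seeded cohorts of
500 cells/cycle × 6 cycles × 2000 genes for slope-CI coverage and null FDR;
20 seeds × 600 cells for consensus K recovery on 2- and 3-archetype cohorts
(programs at 1.0 log-fold, the full k = 2..10 × 100-iteration consensus);
20 seeds × 600 cells for batch-component alignment (60 scored sets — with
only ~17 score dimensions the planted shift is not generically orthogonal
to the archetype axis and no removal method could align with it); one
3000-cell cohort for proportion tracking against a 6-cycle schedule; and a
1200-cell cohort with strong CNA dosage (3×/0.2×) for the classifier gate,
where separability is the point of the construction. The acceptance script
runs trimmed replicate counts (8–10 seeds per arm) to keep a full run in a
few minutes.

## Known limitations

Cells are treated as independent within patients (no biopsy-level random
effects); ssGSEA normalization is global-range rather than per-set;
consensus clustering cost grows with the square of cell count (dense
consensus accumulators); Louvain on SNN graphs may not admit every target K
at any resolution — the bisection warns and returns the nearest count; the
classifier presumes the variable-gene panel captures the dosage signal, and
an AUC gate on held-out folds does not guard against covariate shift in the
not.defined population.
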