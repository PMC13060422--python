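# Methods

## The regional motif diversity score

Plasma cell-free DNA (cfDNA) is fragmented non-randomly: nucleases cut
preferentially in sequence contexts that depend on chromatin state, so the
k-mer of reference sequence at a fragment's 5′ terminus (its *end motif*)
carries epigenetic information about the contributing cells. The motif
diversity score (MDS) summarizes this as the normalized Shannon entropy of
end-motif frequencies over a whole genome; the **regional** MDS (rMDS)
computed here resolves it per genomic bin.

For bin *j* with counts *c₍ᵢⱼ₎* over the 4ᵏ possible k-mers (k = 4 by
default, 256 motifs), with *P₍ᵢⱼ₎ = c₍ᵢⱼ₎ / Σᵢ c₍ᵢⱼ₎*:

    rMDS_j = Σᵢ −P_ij · log P_ij / log 4^k ,   0·log 0 := 0

so rMDS ∈ [0, 1]: 0 when one motif carries every end, 1 when all motifs
are equally used. No pseudocounts are added — zero-count motifs contribute
nothing, matching the definition literally. Natural log is used
internally; the value is base-invariant because the normalization cancels
the base (asserted to 1e-12 in tests). Per sample, scores are z-transformed
across defined bins, Z_j = (rMDS_j − μ)/σ, with the *population* standard
deviation; bins with fewer than `min_ends` ends (default 100) stay
undefined and are excluded from μ and σ. Z_rMDS is the quantity used by
every downstream stage.

### End-motif conventions

Each fragment contributes two ends. For the informative `five_prime` side,
the upstream motif is the reference k-mer `[start, start+k)` and the
downstream motif is the reverse complement of `[end−k, end)` — the 5′ end
of the bottom strand, the double-strand convention of the end-motif
literature. The `three_prime` side is defined as the reverse complements
of the corresponding 5′ motifs; because cleavage information lives at 5′
termini under standard library chemistry, the 3′ score is a
composition-matched negative control. Each end is tallied into the bin
containing its own terminal base (`start`, or `end−1`), not the fragment
midpoint: the score measures end diversity *at a locus*. Ends whose window
leaves the chromosome are skipped ("edge-skipped"), windows containing
non-ACGT bases are discarded, and ends in masked bins are dropped — all
three are tallied so that counts + tallies = 2 × fragments (a tested
conservation law).

### Fragment QC and binning

Fragments are BED-style 0-based half-open intervals. QC keeps records with
mapping quality ≥ 30 (a missing mapq passes and is flagged, since
fragment files are typically pre-filtered upstream), length 50–350 bp
inclusive on both ends, chromosome in the layout, and no blacklist
overlap; every rejection is counted by rule. The genome is tiled into
non-overlapping bins (500 kb at production scale; the test suite uses
100 kb bins on toy genomes). A bin is masked when blacklist intervals
cover more than half of it or its mean mappability falls below 0.9; both
thresholds are configurable because published practice does not pin them
down. A locus-level track is also available: windows every 10 kb scored
from all ends within ±250 kb of the window center, reported as raw rMDS
(cross-sample normalization happens downstream).

## Batch correction with a preserved covariate

Multi-site longitudinal plasma collections carry technical structure from
collection site, cfDNA isolation date and library date. Per bin, Z_rMDS is
modeled by OLS on sum-to-zero contrasts of the batch factors *plus* the
response label as a preserved biological covariate; only the batch terms
are subtracted. Because the response term absorbs the group difference
during fitting, subtracting the batch terms cannot remove it — the
preservation guarantee is tested by simulation (planted institute offsets
removed to |residual| < 0.05 over 20 seeds while the response silhouette
is retained within 10%). Coefficients are learned once on a designated
fit set and applied frozen elsewhere; under sum contrasts a factor level
unseen at fit time encodes to the zero vector, so such samples receive
the grand-mean correction only (with a warning). Corrected matrices are
standardized per bin (zero-variance bins dropped with a log message) and
reduced by truncated SVD (default 6 components, matching the production
configuration); components are sign-canonicalized so the largest-magnitude
loading is positive, making embeddings reproducible. Group separation is
quantified by the silhouette score (b−a)/max(a,b) on the corrected
feature matrix with Euclidean distances; singleton clusters and identical
points score 0 by convention.

## Differential testing

Three timepoints per patient are repeated measures. Rather than per-bin
mixed models, the package uses the duplicate-correlation strategy: a
consensus intra-patient correlation ρ̂ is estimated by a one-way
random-intercept ANOVA decomposition of per-bin OLS residuals, the
per-bin intraclass correlations clipped to (−0.99, 0.99) and averaged on
the Fisher-z scale. Every bin is then fitted by GLS under
block-equicorrelated errors (correlation ρ̂ within a patient), via the
closed-form blockwise whitening
Σ^(−1/2) y = (y − ȳ1)/√(1−ρ) + ȳ1/√(1+(m−1)ρ); ρ̂ = 0 reduces exactly to
OLS (tested to 1e-10). The design contains an intercept, the response
contrast (coded ±½ so the coefficient is the responder-minus-non-responder
difference) and clinical covariates: numeric covariates centered,
categorical ones one-hot with first-level reference and levels carried by
fewer than two samples collapsed to "other". Timepoint is available as an
optional covariate but excluded by default, since the production analysis
tests a global response effect.

Residual variances are moderated by the standard empirical-Bayes squeeze:
a scaled inverse-χ² prior (d₀, s₀²) is fitted by matching moments of
log s² (digamma/trigamma inversion), posterior variances
s̃² = (d₀s₀² + d·s²)/(d₀+d), and the moderated t has d₀+d degrees of
freedom. The implementation is cross-checked in the test suite against an
independent reference implementation of this scheme (limma's `eBayes`,
run through R) on simulated data — agreement on d₀, s₀² and every t
statistic. Multiple testing uses q-values: Storey's π₀ from a λ-grid with
a cubic smoother by default (falling back to π₀ = 1, i.e.
Benjamini–Hochberg, below 100 tests where the grid is unstable), with
`method="bh"` available explicitly. Bins at q < 0.1 are called
differential.

## Clustering and telomere enrichment

Significant bins are clustered on their value patterns across all samples
(ordered by response group, patient, timepoint) with Ward linkage cut to
exactly 3 clusters; labels are renumbered by descending cluster size
because dendrogram order is not portable across library versions. Cluster
trajectories are summarized as patient-level means per (cluster, group,
timepoint) with 95% t-intervals across patients.

Telomere proximity of a bin is the distance from its midpoint to the
nearest chromosome end. Enrichment is tested against a null of 100,000
bins of the same width placed uniformly on the genome (chromosome chosen
proportional to length; null bins may overlap each other or real bins —
the stated procedure gives no exclusion rule), with (i) a one-sided
Mann–Whitney U test for stochastically smaller distances and (ii) a
permutation test drawing |cluster|-sized sets from the null pool and
comparing mean distance, with the add-one correction
p ≥ 1/(n_perm + 1). The permutation statistic is the mean (chosen for
power against location shifts; median available). One subtlety is noted:
grid-bin midpoints cannot exceed distance L/2 − bin_size/2 while uniformly
placed bins reach L/2, so even random *grid* clusters sit very slightly
closer to ends than the continuous null; calibration is therefore checked
with observed sets drawn from the null process itself, where rejection at
α = 0.05 is exact.

## Response classification

Features are the corrected, standardized matrix reduced to 6 SVD
components; the default classifier is ridge-regularized logistic
regression (deterministic, dependency-light), behind a fit/predict_proba
interface any plug-in classifier can implement. Three patient-level
validation schemes are provided: repeated stratified k-fold
cross-validation, leave-one-institute-out, and repeated random patient
holdout. Splits are always by patient; with the `refit` correction
policy, batch correction, standardization and SVD are learned on the
training samples of each split and applied frozen to the test samples
(the holdout-honest setting), while `global` uses a pre-corrected matrix
(the analysis-set setting). Patient predictions use the sample from the
most recent available timepoint (Screen < Day0 < AdjWk1; unknown
timepoints sort least recent; a Screen-only patient uses Screen as a last
resort and is flagged); probability ≥ 0.5 predicts responder. Metrics:
ROC AUC, accuracy, F1, precision, recall, balanced accuracy, confusion
counts, and sensitivity at 95% specificity (the maximum TPR over
thresholds with FPR ≤ 5%, 0 if none), aggregated as mean ± SD over
splits, at both sample level (stratified by timepoint) and patient level.

## The synthetic cohort generator

The simulator emulates the structure of a longitudinal multi-institute
cfDNA study: two response groups, three timepoints per patient, six
institutes, per-patient technical batches (all timepoints of a patient
share an isolation/library batch, as in practice), and a planted regional
entropy difference. Per sample and bin, the motif distribution p is drawn
from a symmetric Dirichlet with per-motif concentration 2.0 — giving
baseline rMDS ≈ 0.96 with realistic bin-to-bin variability — and counts
follow a Dirichlet-multinomial. The response effect multiplies the
concentration by `effect_delta` (default 0.2) for non-responders at
designated effect bins: concentration controls draw dispersion, so a
smaller value lowers expected entropy without moving mean motif
composition. Trajectory archetypes modulate the effect by timepoint:
`cluster1` applies it at Screen and the post-surgery timepoint but not at
surgery day, `cluster2` applies it constantly, `cluster3` applies the
inverse constantly.

Two batch knobs exist. `batch_tilt_sd` perturbs the motif axis per
(institute, library-date) batch as element-wise exp(N(0, sd)) on the
concentration vector; because it shifts the expected entropy of every bin
equally, the per-sample z-transform removes most of it. `batch_bin_sd`
multiplies the concentration by a per-(batch, bin) lognormal factor,
creating bin-level batch structure that survives z-scoring — the kind of
structure the correction stage exists to remove — and is used in the
correction-benefit evaluations.

Crucially, fragments are *written against the reference*: the upstream 5′
end is placed at a position inside the bin whose forward k-mer equals the
motif sampled from p (uniform over matches; uniform-position fallback if
a motif is absent from the bin, rare at ≥100 kb bins). The downstream end
is placed at the reference position matching its sampled motif nearest to
the length-sampled endpoint (lengths ~ N(166, 40) truncated to 50–350 bp)
within the legal length window, falling back to the length-sampled
position when no match exists (~e⁻¹·² of fragments at k = 4). The
counting stage therefore has to read sequence — it cannot inherit the
answer from the simulator — at the price of a small background admixture
on downstream ends; the calibration test confirms total-variation
distance to the planted distributions still falls monotonically with
coverage. The generator does not model nucleosome-positioned coverage,
GC bias or sequencing error, so passing tests demonstrate correctness of
the pipeline's algebra and statistics on data with the planted structure,
not performance on real plasma.

## Problem sizes and numerical choices

The test and example simulations run on toy genomes (2 chromosomes of
1–5 Mb, 100 kb bins, 256-motif space preserved; 8–20 patients per group;
300–3,000 fragments per bin), sizes chosen so the full suite runs on a
laptop while keeping every distributional property testable. Calibration
checks use reduced resampling sizes (e.g. 10,000 null bins and 1,000–10,000
permutations) with thresholds that account for the implied Monte Carlo
error. Production defaults remain 500 kb bins, k = 4, min_ends = 100,
q < 0.1, 6 SVD components, and 100,000 null bins/permutations.

Known limitations: the correction model is linear (no ComBat-style
shrinkage or nonlinear correction); per-sample quality weights are
accepted in the GLS but not estimated; q-value π₀ estimation falls back
to BH for small test counts; the simulator's fallback placements slightly
dilute the planted downstream-end signal; and silhouette is computed on
the corrected feature matrix (an optional 2-D embedding export exists,
but separation statistics on nonlinear embeddings are not part of the
tested contract).
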