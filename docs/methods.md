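# Methods

`cityprints` reimplements, as a tested library, a complete analysis pipeline
for asking whether urban microbial communities carry a *city-specific
fingerprint*: given a taxonomy-annotated OTU count table from swab samples
collected in three cities, can the city of origin be recovered from the
abundance profile of the taxa all cities share?  This note records the
models, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Input model and preprocessing

The pipeline starts from a QIIME-classic OTU table (OTU × sample integer
counts, greengenes lineage strings) and a metadata table assigning each
sample a city and a sequencing platform (WGS or Amplicon).  Samples present
on only one side of the count/metadata join are dropped with a warning; a
configurable minimum-total-count filter (`min_sample_total`, default 1)
stands in for the per-sample QC that surveys of this kind apply, since no
portable rule exists for it.

**Rank aggregation.** OTU counts are summed into named taxa at each of three
ranks — order, family, genus.  An OTU whose lineage lacks the rank (an empty
`o__` token) is *excluded* at that rank and its count mass reported, rather
than pooled into an "unclassified" level: all cross-city analyses run on
named taxa only.  Aggregation therefore conserves mass exactly
(assigned + excluded = original), which the tests assert.

**Common levels.** A taxon is *present* in a city when its summed count
there is nonzero; the analyses are restricted to the intersection of the
per-city supports (the centre of the three-city Venn diagram).  Presence
has no abundance threshold — the simplest reading, flagged as a choice.

**Normalization.** Counts are transformed to log2 counts-per-million with a
half-count offset and a one-read library offset:

    y_gi = log2( (r_gi + 0.5) / (N·R_i + 1) · 1e6 )

where `r_gi` is the count of level g in sample i, `N` the number of levels,
and `R_i` the mean per-level count of sample i, so `N·R_i` is sample i's
total over the included levels.  The offsets bound the inner ratio strictly
inside (0, 1), so every value is finite and below log2(1e6) ≈ 19.93; a zero
count in a sample of total 999,999 maps to exactly −1.  Whether the totals
are taken before or after restriction to common levels is not determined by
the transform's provenance; the pipeline normalizes each city's
common-restricted table separately (`normalize_per_city=True`), with pooled
normalization available as a sensitivity switch.  (On a common-restricted
table the two agree, because the formula depends only on each sample's own
total; they differ only when per-city tables carry different level sets.)
Samples with zero total at a rank cannot represent a library and are
rejected.

**Platform check.** Because WGS and Amplicon samples are merged, a
two-sided two-sample Kolmogorov–Smirnov test per level compares the two
platforms' normalized values; the check is skipped with a notice unless
both platforms have ≥ 2 samples.  Min and max p across levels are reported.

## Ordination

PCA runs on the correlation matrix of the levels (levels standardized to
unit variance), so the variance proportions are invariant to affine
rescaling of any level.  Constant levels are dropped with a warning.
Eigenvalues come from a symmetric eigendecomposition; the sign of each
component is fixed by making its largest-magnitude loading positive.  The
tests check the proportions against an independent SVD of the standardized
data and the reconstruction identity Z = scores · loadingsᵀ.

## Provenance classifiers

**Random forest.** Bootstrap-aggregated CART trees (default 1000) with a
random predictor subset at each split, `vars_per_split = min(10, p)` since
the genus rank can have as few as 10 predictors.  The implementation bags
`DecisionTreeClassifier`s through `BaggingClassifier` so each tree's in-bag
index set is public, which makes two things exact rather than approximate:
the OOB error (each sample voted on only by trees that never saw it) and
the importance, measured as the mean decrease in OOB accuracy when one
predictor column is permuted within each tree's OOB set.  Tests assert that
a pure-noise predictor's importance is within 2 standard errors of zero and
that label permutation drives the OOB error to the majority-class baseline.

**Pairwise ensemble.** For each city pair, repeated stratified 2-fold
cross-validation (default 100 iterations).  Within each training fold the
component roster — LDA, k-nearest-neighbour, a single CART tree, linear
SVM, a small random forest, and L2-penalized logistic regression — is
assessed by an internal stratified 2-fold CV on accuracy, sensitivity,
specificity and AUC; components are ranked per metric, mean ranks (Borda,
ties averaged) are mapped to non-negative weights summing to one, the
components are refit on the whole training fold, and their weighted vote
scores the held-out fold.  The positive class is the first label of the
pair; the AUC uses the vote score (total weight voting positive); metrics
are averaged over the two folds of an iteration and reported per iteration.
Mean-rank aggregation is a deliberate simplification of weighted
rank-aggregation schemes, and the roster is configurable because no
canonical component list exists.  With a single component the ensemble
provably reduces to plain repeated CV of that component (tested).

## Balanced-subsample differential abundance

City sample sizes are strongly unbalanced (the survey scale is 134/777/18),
so each replicate draws `n = 18` samples per city without replacement
(cities already at n pass through whole), runs a one-way fixed-effects
ANOVA per common level on the normalized values, applies Benjamini–Hochberg
across the rank's levels *within the replicate* at FDR 1% (the only reading
compatible with per-replicate Tukey follow-up), and runs Tukey's HSD
all-pairs test at α = 0.01 on the selected levels only.  Balance makes the
studentized-range critical value with the pooled mean-square error exact.
Pairwise outcomes are encoded as compact letters over the declared city
order: the first city gets 'a'; each later city reuses the letter of the
earliest city it is not significantly different from, else takes the next
unused letter; the three significance bits map exhaustively onto
{a-a-a, a-a-b, a-b-a, a-b-b, a-b-c, other}, with the three non-transitive
bit combinations in "other".  Over replicates the summary counts, per level
and pattern, the occurrences and the min/mean/max of the ANOVA p-values of
the counted occurrences; a level contributes only when it survives BH, so
pattern counts per level sum to at most the replicate count.  Degenerate
levels (zero within-group variance) get p = 0 when the group means differ
and are skipped with a log message when they do not.  The summary tallies
ANOVA p-values; Tukey-adjusted pairwise p-values are available from
`anova_tukey_replicate(adjusted_p=True)` for single replicates, where their
per-call cost is negligible.

## Diversity of order q and its permutation test

The mean species diversity of order q over sampling units j and species i,

    α = ( Σ_j Σ_i p_ij · p_{i|j}^(q−1) ) ^ (−1/(q−1)),

uses `p_ij` = share of the grand total and `p_{i|j}` = share within unit j.
The two coincide when each city is a single pooled unit, which is the
default (`unit="city"`); a per-sample-unit mode exists because the double
sum admits both readings.  The grand-total convention is the one under
which a uniform single-unit community of S species gives α = S exactly
(tested for S = 2…50 at q ∈ {0.5, 2}).  Zero cells contribute nothing (the
0^(q−1) convention for q > 1; dropped terms for q < 1).  q = 1 is rejected
rather than taking the Shannon limit — the analysis uses q ∈ {0.5, 2} only,
where q < 1 up-weights rare species and q = 2 the abundant ones.

The cross-city test runs on *raw counts over all discovered levels* (not
the common restriction): per-city α values give the statistic
θ = Σ_t (α_t − ᾱ)², and city labels are reassigned uniformly at random with
group sizes fixed (the source literature calls this a bootstrap; it is a
label permutation and the code says so, while report headers keep the
"bootstrap replications" phrasing).  The p-value is the fraction of
permuted θ* *strictly* greater than θ, as defined — no +1 correction, so
p = 0 is attainable.  Tests verify the Monte-Carlo p against exhaustive
enumeration of all 90 labelings of a 6-sample toy and the empirical level
of the test on exchangeable nulls (rejection rate at α = 0.05 within
[0.03, 0.07] over 800 null datasets of 12 samples per city at 500
permutations each).

## Co-abundance networks

Per city, the Pearson correlation matrix of the common levels (≥ 3 samples
required; constant levels excluded; the matrix is symmetrized to kill
one-ulp asymmetries from the underlying routine).  Edges keep pairs with
|r| strictly above a threshold; isolated levels drop from the node list, so
edge sets are nested along any threshold sweep (tested).  Because the
original procedure tuned thresholds by hand to equalize node counts across
cities, `calibrate_threshold` automates that criterion: it searches the
sorted unique |r| values (node count is a non-increasing step function of
the threshold) for the largest threshold within ±tolerance (default 10% of
target) of the target node count, falling back to the closest-achieving
threshold with a warning when a step jump skips the band entirely.  Hubs
are the top-k degree nodes (ties lexicographic); shared hubs are the
intersection of per-city hub sets.  Networks serialize as edge-list TSV and
GraphML.

## Synthetic data generator

The generator emulates the structure of the three-city survey rather than
its sequences: a taxon catalogue of shared taxa (lognormal baseline
abundances, σ = 1) plus small city-specific sets; unbalanced city sizes
defaulting to 134/777/18; heterogeneous library sizes drawn uniformly per
sample (default 20,000–100,000); a platform covariate (default: 75%
Amplicon in the first city, WGS elsewhere) with *no* distributional effect
unless a `platform_shift` is planted to exercise the KS check; and compound
Dirichlet-multinomial counts — per-sample proportions drawn from a
Dirichlet centred on the city profile with concentration `p/overdispersion`
(default overdispersion 0.02, i.e. total concentration 50, mid-range for
16S surveys), then a multinomial at the sample's library size.  Zero
overdispersion degenerates to exact multinomial sampling, checked against
the analytic multinomial variance.

City effects are planted on mid-ranked shared taxa with centred multipliers
`effect_size^(k − (K−1)/2)` per city k.  Centring matters: abundance
vectors are compositions, and multiplying *dominant* taxa by 1, e, e²
mostly rescales the whole vector on renormalization, leaving realized
cross-city log-ratios far below nominal.  With centred multipliers on
mid-abundance taxa the realized log-fold changes stay near log2(effect_size).
`effect_size = 1` with no city-specific taxa yields exactly identical city
profiles — the exchangeable null used for calibration tests.

**What the generator does not emulate:** sequence-level noise (OTU-picking,
chimeras), realistic phylogenetic correlation between taxa, platform-
specific taxonomic bias, or per-city variance structure beyond what the
Dirichlet-multinomial induces.  One induced property deserves note: with
concentration proportional to abundance, taxa below ~2% relative abundance
have Dirichlet parameters below 1 and hence very heavy-tailed log-scale
noise.  A city whose planted multiplier pushes a taxon into that regime
acquires a much larger within-city variance than the others, and a
pooled-MSE Tukey test then reads the configuration as a-b-b rather than
a-b-c even when the three means are far apart.  The generator-based
recovery property is therefore stated as the planted taxa *surviving FDR
selection* (≥ 95% of replicates at effect 4, n = 18/city), while the
letter-pattern recovery of a three-distinct-means configuration is tested
on a fixture planted directly on the normalized scale with homoscedastic
spread.  Passing tests show the machinery recovers what was planted under
this noise model; they do not certify performance on real surveys, whose
confounders (uneven protocols, depth, geography) the generator does not
contain.

## Reproducibility and problem sizes

One root seed drives everything; each stage derives an independent
substream keyed by a stable hash of the stage name, so changing one stage's
replicate count never perturbs another stage's draws, and a single-stage
rerun reproduces its slice of a full-pipeline run (tested byte-for-byte on
the report files).  Every output table carries the seed and a configuration
hash in a header comment.

Defaults follow the survey protocol (5000 ANOVA replicates, 2000
permutations, 1000 trees, 100 ensemble iterations).  The test-suite and the
acceptance script run scaled-down sizes chosen to keep the full suite in a
few CPU-minutes while leaving every Monte-Carlo margin comfortable: 300–500
ANOVA replicates, 500 permutations, 200–300 trees, 10–25 ensemble
iterations, 800 calibration datasets.  All scaled sizes are recorded in the
outputs they produce.

## Known limitations

- q = 1 (Shannon) diversity is deliberately unsupported.
- The strict-inequality permutation p-value can be exactly 0; consumers
  wanting a positive lower bound should apply their own (B+1) correction.
- Tukey letters are defined for the three-city case in the summary tally;
  `letter_pattern` itself handles any k, but patterns beyond three groups
  are reported as raw letter strings, not tallied classes.
- The KS platform check compares marginal distributions per level; it has
  no power against platform effects that only reorder samples jointly
  across levels.
- With platform confounded with city (one city carrying all Amplicon
  samples), the KS check picks up city effects; interpret it within a city
  or on effect-free data.
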