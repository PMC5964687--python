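# cityprints

**City-of-origin microbiome fingerprints from taxonomy-annotated OTU count
tables.**

Urban surfaces carry microbial communities that differ measurably between
cities. Given 16S-derived OTU counts from swab samples collected in several
cities — with wildly unbalanced sample sizes and a mix of whole-genome
shotgun (WGS) and amplicon sequencing — `cityprints` asks and answers the
fingerprint question end to end: *do the taxa all cities share separate the
cities, and can a sample's city of origin be predicted from its profile?*

It is written for microbiome researchers and data analysts who start from a
QIIME-classic OTU table (the TSV export of a biom table, with greengenes
lineage strings) plus a sample metadata table, and want a tested, seeded,
reusable implementation of the whole analysis rather than a pile of
one-off scripts.

## What it computes

Counts are aggregated to a taxonomic rank (order, family or genus),
restricted to the *common levels* — taxa with nonzero counts in every
city — and normalized to bounded log2 counts-per-million:

    y_gi = log2( (r_gi + 0.5) / (N·R_i + 1) · 1e6 )

where `r_gi` is the count of level *g* in sample *i* and `N·R_i` is sample
*i*'s total count. On these profiles the pipeline runs:

- **Platform check** — per-level two-sample Kolmogorov–Smirnov comparison
  of WGS vs Amplicon samples, so merging the platforms is justified (or
  flagged) rather than assumed.
- **Ordination** — PCA on the correlation structure of the levels, with
  variance-explained reporting for the first components.
- **Provenance classifiers** — a random forest scored by out-of-bag (OOB)
  error with permutation importance, and a pairwise *ensemble classifier*:
  component classifiers are ranked on a training fold, rank-aggregated into
  voting weights, and the weighted vote predicts the held-out fold over
  repeated stratified 2-fold cross-validation.
- **Balanced-subsample differential abundance** — because city sizes are
  unbalanced (e.g. 134/777/18), each replicate draws 18 samples per city,
  runs per-level one-way ANOVA with Benjamini–Hochberg FDR control at 1%,
  and encodes Tukey HSD all-pairs outcomes as compact letters
  (`a-b-c` = all three city means differ, `a-a-b` = only the third city
  differs, …), tallied over thousands of replicates.
- **Diversity permutation test** — mean species diversity of order *q*,
  α = (Σ_j Σ_i p_ij · p_{i|j}^(q−1))^(−1/(q−1)), per city on raw counts;
  the statistic θ = Σ_t (α_t − ᾱ)² is referred to its label-permutation
  null, p = (1/N) Σ I(θ*_n > θ).
- **Co-abundance networks** — per-city Pearson correlation networks with
  |r|-thresholding, per-city threshold calibration to a common node count,
  and hub comparison across cities.

A synthetic three-city generator (compound Dirichlet-multinomial counts,
shared + city-specific taxa, planted effect sizes, unbalanced sizes,
platform covariate) provides ground truth for every stage; the full model
and all numerical choices are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
import cityprints as cp

spec = cp.make_spec(effect_size=4.0, n_per_city=(30, 40, 18), seed=7)
dataset = cp.simulate_dataset(spec)
table = cp.aggregate_to_rank(dataset, "order")
common, venn = cp.common_levels(cp.split_by_city(table))
print(f"common order-level taxa: {len(common)}")

norm = cp.normalize_log_cpm(cp.restrict_to_common(table, common))
pca = cp.run_pca(norm)
print(f"variance in PC1-3: {100 * cp.variance_explained(pca, 3):.1f}%")

rf = cp.rf_city_classifier(norm, trees=300, seed=7)
print(f"RF out-of-bag error: {100 * rf.oob_error:.2f}%")

summary = cp.replicate_summary(norm, replicates=300, n=18, seed=7)
print("Tukey pattern totals:",
      summary.table["count"].groupby("pattern").sum().to_dict())

result = cp.permutation_test(table, q=0.5, n_permutations=500, seed=7)
print(f"diversity test (q=0.5): theta={result.theta:.3f} p={result.p_value:.3f}")
```

prints

```
common order-level taxa: 15
variance in PC1-3: 47.3%
RF out-of-bag error: 15.91%
Tukey pattern totals: {'a-a-b': 1313, 'a-b-a': 0, 'a-b-b': 486, 'a-b-c': 888, 'other': 610}
diversity test (q=0.5): theta=1.241 p=0.016
```

Reading the numbers: the three simulated cities share 15 order-level taxa;
the first three principal components carry about half the correlation
structure of this small fixture; a 300-tree forest mislabels ~16% of
samples out-of-bag (three cities, only 88 samples); across 300 balanced
ANOVA replicates the planted city effects surface mostly as `a-a-b` and
`a-b-c` letter patterns; and the order-0.5 diversity (which up-weights rare
taxa, here the city-specific ones) differs significantly across cities
(p = 0.016 against the permutation null).

The same stages are available from a shell:

```bash
cityprints simulate --seed 7 --outdir data/
cityprints all --counts data/otu_table.tsv --metadata data/metadata.tsv \
    --seed 7 --outdir run/
```

`run/` then holds, per rank, the normalized table, PCA / random-forest /
ensemble reports, the Tukey replicate summary, the diversity test results,
per-city networks (edge-list TSV + GraphML) and a manifest echoing seed and
configuration.

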