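# Methods

## The activity index

For taxon bin *t* in sample *s*, the activity index is
`%RP = 100 · rp_reads / total_reads`, the share of the bin's annotated
transcriptome devoted to ribosomal proteins. The index is a *within-taxon*
quantity: it is invariant to the bin's recruitment depth, so temporal
profiles of %RP can be compared across taxa whose abundances differ by
orders of magnitude. Cells with `total_reads = 0` are explicitly missing
(NaN), never 0 — a measured 0 %RP (reads present, none ribosomal) is a
meaningful low-activity observation, whereas an empty bin carries no
information. The index assumes that ribosome synthesis tracks activity
similarly *within* a taxon over time; cross-taxon comparisons of absolute
%RP levels are not part of any test in this package.

### Bootstrap confidence intervals

The resampling unit is the read. Redrawing a bin-sample cell's
`total` reads with replacement, each ribosomal with probability
`rp/total`, is exactly a `Binomial(total, rp/total)` draw, so the CI is the
percentile interval of `100 · rp*/total` over `n_boot` (default 1000)
binomial replicates. Percentile intervals (rather than BCa) are used; at
the read depths involved the difference is far below the interval width.
The interval is clipped to bracket the point estimate, which quantile
interpolation on a discrete resampling distribution can otherwise violate
by a fraction of one count. Cells resampling a zero count have a lower
bound of exactly 0.

### Absolute transcript concentrations

A known quantity of artificial mRNA (default `4.7e10` copies, the
standard's load per sample) is spiked into each sample before extraction.
Recovered standard reads estimate the sample's capture ratio, so

```
rp_per_L(t, s) = rp_reads(t, s) · copies_added(s) / standard_reads(s) / volume_L(s)
```

converts any read count to transcripts per litre. The statistic is
invariant to sequencing-depth changes that scale taxon and standard reads
together — the defining property of spike-in normalization, asserted
exactly in the tests. Samples recovering zero standard reads cannot be
normalized; their column is NaN with a logged warning.

## Temporal permutation tests

Both tests operate per taxon on a per-sample statistic (either %RP or
`rp_per_L`), after technical replicates are averaged.

**Day–night.** The observed statistic is the mean day−night difference
over complete pairs (pairs with an undefined member are dropped; fewer
than two usable pairs marks the taxon untestable rather than raising).
Under the null the 2m participating values are pooled and randomly
re-paired, one member of each pair designated "day". Choosing a uniformly
random perfect matching and then a uniformly random orientation makes
every m-subset of the pooled values equally likely to be the day set
(each subset is consistent with `m!` matchings out of `(2m)!/(2^m m!)`,
giving probability `1/C(2m, m)`), so the null is sampled by a simple
permutation. The test is two-sided on |mean difference| by default because
day- and night-enriched calls should be symmetric; `tail="greater"` gives
the literal one-sided rule. A `null="signflip"` variant keeps the original
pairs and randomizes only the orientation.

**Seasonal.** The observed statistic is the between-season sum of squares
`Σ_g n_g (x̄_g − x̄)²` over the five seasonal groupings; the null permutes
sample-to-season labels with group sizes fixed. Seasons left with no
defined values are dropped with a warning; at least two populated seasons
are required.

**p-values.** Both tests use `p = (b + 1)/(n_iter + 1)` where `b` counts
null draws at least as extreme as the observed statistic. Ties count as
exceedances (conservative; also the only choice that avoids `p = 0` for a
perfect separation), and tie detection allows a `1e-9` relative slack so a
permutation that reconstructs the observed partition is counted as a tie
despite float summation-order jitter. `add_one=False` restores the raw
proportion. Significance calls use raw p-values at α = 0.05; a
Benjamini–Hochberg column can be added downstream but is not used for
calls, keeping one well-defined decision rule per taxon.

## Activity clustering

Pairwise Pearson correlation `r` between taxon %RP profiles
(pairwise-complete over defined cells) maps to distance `d = (1 − r)/2`,
so perfectly tracking taxa sit at 0, uncorrelated at 0.5, perfectly
opposed at 1. Taxa with fewer than 3 defined samples or zero profile
variance have no defined correlation and are excluded with a warning.
Complete-linkage agglomeration (whose merge heights are provably
monotone, so the dendrogram has no inversions) is cut into exactly `k`
flat clusters; `k` defaults to 7 but is a free parameter, and mean
silhouette widths for `k = 2..12` are reported alongside so the choice is
inspectable. Labels are renumbered in order of first appearance along the
taxon list for cross-platform determinism. The dendrogram is exported as
Newick with branch lengths equal to differences of merge heights, so
root-to-leaf distances equal the root height. Because Pearson correlation
is affine-invariant, clustering sees only profile *shape*; raw and
standardized profiles give identical results.

## Indicator analysis

A *hit* is a (taxon, KO, sample) record with count ≥ 1; hit counts can
exceed one when several genes of a taxon bin to the same KO. *Detection*
is the binarized hit. For KO *k* and cluster *c*:

* `H_c` = summed hits over the cluster's taxa and all samples;
  `N_c = H_c / |c|` (normalization by cluster size removes the advantage
  of large clusters);
* specificity `= N_c / Σ_c' N_c'` (shares sum to 1 for any expressed KO);
* fidelity `=` detected (taxon, sample) cells `/ (|c| · n_samples)`, with
  the denominator counting every cell whether or not the taxon recruited
  reads in that sample (the literal definition; it makes fidelity a
  property of the design, not of coverage);
* `IV = 100 · specificity · fidelity`, so `IV = 100` iff the KO is
  detected in every cell of its cluster and nowhere else. A KO with no
  hits anywhere gets `IV = 0` with undefined specificity, keeping the
  result table total.

Significance: taxa are randomly reassigned to clusters with sizes
preserved (`n_iter` = 1000 by default) and `p` is the add-one proportion
of null IVs ≥ observed. Multiplicity in hit counts raises specificity
weight but not fidelity, and the permutation carries each taxon's whole
hit vector, so the null respects per-taxon expression idiosyncrasy.

**Day/night variant.** Within one cluster (chosen explicitly, or by
default the cluster with the most day-enriched taxa), the two "clusters"
of the IV computation become the day- and night-sample groups: hits are
summed over the cluster's taxa per sample, normalized by group sample
count, and fidelity's denominator is `|cluster taxa| · |group samples|`.
Significance permutes the sample day/night labels (default 10,000
iterations).

**Pathway enrichment.** For each cluster, the observed count of
significant indicator KOs annotated to a pathway is compared with
redrawing the same number of KOs uniformly without replacement from the
cluster's expressed-KO universe. This KO-resampling null conditions on
*how many* indicators the cluster has and asks only whether they
concentrate in a pathway; KOs annotated to several pathways count once
per pathway.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
starting at the binned-count level (reads, assembly, and annotation are
not simulated):

* **Design** — five seasonal campaigns (summer1, fall, winter, spring,
  summer2) × 2 day–night pairs = 20 samples; optional technical
  replicates re-sequence a library (same latent biology, independent
  counting).
* **Activity** — each of the `k = 7` clusters has a season profile of
  mean %RP between 1 and 15 (three cold-biased, four warm-biased). The
  default profiles were chosen so their pairwise Pearson correlations top
  out near 0.55, which keeps within-cluster correlation (≈ 0.87 at
  default noise) well above between-cluster correlation — the planted
  partition is resolvable by construction, and cluster recovery measures
  pipeline correctness rather than luck. Cluster 2 additionally carries a
  `+5 %RP` day offset for all its members, mirroring a community whose
  heterotrophs run a strong diel rhythm.
* **Noise** — biological noise is logit-normal (SD 0.25 on the logit
  scale, ≈ 25% coefficient of variation at these %RP levels), which
  respects the (0, 100) bounds; bin depths are negative binomial (mean
  20,000, shape 4) because metatranscriptome bin sizes are overdispersed;
  RP reads are `Binomial(depth, %RP/100)`. Noise is drawn per replicate
  group, so technical replicates share biology and differ only in
  counting.
* **Spike-in** — each sample has a latent sequencing fraction
  (uniform 2–8 × 10⁻⁸) and `standard_reads = round(copies × fraction)`,
  deterministic. The ground-truth concentration is defined as the RP
  transcripts captured into the library scaled back through fraction and
  volume, so spike-in recovery is exactly invertible up to the rounding of
  the standard count; this isolates the normalization arithmetic from
  binomial sampling of the library, which is tested separately.
* **KO hits** — each cluster gets 5 planted indicator KOs (per-sample
  detection probability 0.9 in members, 0.1 elsewhere) over 100 background
  KOs (0.3 everywhere); hits per detection are `1 + Poisson(0.5)`, so
  multi-gene KOs occur. Indicator KOs carry a per-cluster pathway,
  background KOs one of ten background pathways.

Everything is deterministic given `SimConfig.seed`; the three generator
stages draw from separate children of the master seed.

**What passing tests do and do not show.** The generator plants clean,
balanced clusters with exchangeable noise; real metatranscriptomes have
phylogenetically correlated profiles, abundance-dependent %RP variance,
uneven cluster sizes, compositional coupling between taxa, and annotation
error, none of which are simulated. Recovery results (ARI, power,
indicator recovery) therefore validate the *procedures* — that the
implemented statistics find structure exactly of the kind they assume —
not the field performance of the method on real communities.

## Numerical and design choices

* Permutation tie counting uses a `1e-9` relative tolerance (see above);
  bootstrap CIs are clipped to bracket the point estimate; distances are
  symmetrized only through construction (pandas `corr` is symmetric).
* The pipeline derives one `SeedSequence` child per randomized stage from
  the master seed in a fixed spawn order, so stages are independently
  reproducible and inserting a stage does not shift another's stream.
  Output TSVs carry a `# config=<hash> seed=<n>` header (the output
  directory is excluded from the hash).
* Technical replicates are averaged on the %RP scale, not by summing
  reads, so replicate libraries weigh equally rather than by depth; the
  same collapsing rule is applied to `rp_per_L`. If %RP is undefined in
  some members, the defined mean is used with a warning.
* Season-of-maximum summaries resolve ties toward the earliest season in
  the fixed seasonal order, then by sample id.
* Problem sizes in the validation suite: enumeration oracles run on
  instances small enough for exhaustion (≤ 4 pairs, ≤ 8 samples, ≤ 6 taxa);
  calibration uses 500 null taxa at 1000 permutations; recovery uses the
  full default design (200 taxa, 20 samples). These sizes give
  Monte-Carlo error comfortably below every margin tested while keeping
  the whole suite under a minute of compute.

## Known limitations

* %RP is a *potential*-activity proxy; taxa with non-growth ribosome
  regulation violate its premise, and the package makes no attempt to
  detect them.
* The day–night repartition null assumes exchangeability of samples
  across pairs; strong seasonal trends leak variance into the diel null,
  making the test conservative for taxa with large seasonal effects (the
  sign-flip null is stricter about pairing structure).
* Pairwise-complete correlations can make the distance matrix non-Euclidean
  when missingness is heavy; complete linkage only needs a dissimilarity,
  but silhouette values should then be read qualitatively.
* The pathway null resamples KOs within a cluster's expressed universe;
  it does not model correlated detection among KOs of one operon or
  pathway, so mild enrichment p-values should not be over-read.
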