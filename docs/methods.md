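# Methods

This note documents the statistical model behind `growthsig`, the design
choices that were genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## The analysis model

The pipeline assumes bulk muscle expression is a mixture of transcriptional
programs contributed by distinct cell populations (contractile fibers,
fibro/adipogenic progenitors, endothelium, satellite cells, adipocytes,
pericytes). A growth phenotype that is driven by the abundance or activity
of one population — proliferating FAP-lineage cells, in the motivating
biology — will then correlate with the *output genes* of that program
rather than with regulators, and a small average-z signature of those genes
is a more stable tracker than any single gene. Two independent lines of
evidence are combined: correlation with the phenotype in one cohort, and
co-expression through development in another. Attribution of a program to
a cell type goes through published marker genes: if a marker co-clusters
with a GO term's genes in most independent clustering analyses, the term's
signal is provisionally assigned to the marker's cell type.

## Statistics

**ADG/kg.** `adg / ((w_start + w_end)/2)`, units 1/day. Weights must be
positive; the phenotype is treated as error-free.

**Ranking.** Pearson (product-moment) correlation per gene; signed
descending order (an `absolute=True` switch exists because a ranking by |r|
is also defensible; signed is the default since the enriched processes of
interest are positively correlated). Constant genes have no defined
correlation and are excluded rather than assigned r = 0 — an undefined
correlation must not occupy a rank. Ties are broken by gene ID so reruns
are reproducible.

**Minimum hypergeometric scan.** For membership vector v over the ranked
universe, mHG = min_n P(X ≥ b(n)) with X ~ Hypergeom(N, B, n); the earliest
minimizing prefix is reported. The exact p-value
P(mHG ≤ observed | uniformly random ranking) is computed by counting
monotone lattice paths (one step per rank, diagonal on member ranks) that
avoid the rejection region {(n, b): tail(n, b) ≤ mHG}; the count over
C(N, B) gives the survival fraction. Implementation notes:

- the tail table over the whole (n, b) lattice is computed from the log
  pmf (`gammaln`) with a reversed cumulative sum; accuracy ~1e-13 relative,
  adequate for threshold comparisons performed with a 1e-9 relative guard
  so the achieving cell itself always counts as rejected;
- path counts use float64 (exact for counts < 2^53 and accurate to ~1e-13
  beyond) with an exact big-integer recount whenever the float result is
  below 1e-8, where the complement 1 − W/C(N,B) loses precision
  catastrophically;
- lattices above `max_states` (default 10^7 cells) fall back to a seeded
  permutation estimate with the +1/+1 correction.

The p-value is always ≥ the raw mHG (the scan minimum is not itself a
p-value); both are reported.

**FDR.** Benjamini–Hochberg step-up, delegated to
`statsmodels.stats.multitest` behind the `bh_fdr` surface; inputs are
validated to (0, 1].

**z-scores.** Per gene over the declared sample universe; the sample SD
(n − 1) is the default, with `ddof=0` available (spreadsheet provenance of
the convention is ambiguous; with 48–80 samples the difference is ~1%).
Constant genes are excluded with a warning.

**Signature selection.** Members of a term are visited in ranked order;
the first gene seeds the set and each later gene is accepted when its
developmental z-profile correlates ≥ `coexpr_min` (default 0.6) with the
running mean profile of the accepted genes. The criterion "co-expressed
through development" is stated qualitatively in the source methodology; the
running-mean-profile correlation with a 0.6 threshold is this package's
quantification, and both genotypes' profiles are pooled (a per-genotype
variant was considered and rejected as stricter than the described
procedure). Every accept/reject decision is recorded in the set's
provenance.

**Empirical null.** Random sets of the signature's size are drawn
uniformly from the *full* z-scored universe (no exclusion of the observed
genes — the described procedure states none). Default draws: 100,000
(the method description's count; a larger 10^7 figure appears elsewhere in
the source narrative and is reachable by setting `n_draws`). Strict
exceedance with the (x + 1)/(n + 1) estimator keeps p away from zero. Two
numerical details make the estimator exact rather than approximately
order-invariant: draw indices are sorted before scoring, and the observed
set is evaluated inside the same BLAS batch as the draws, so an identical
random set yields a bit-equal correlation and never a spurious strict
exceedance.

**Loose co-expression filter.** Sign tests only, no thresholds: pooled
mean at birth > pooled mean at the final stage, and high-marbling mean >
high-muscling mean at each stage of interest (12 and 25 months by
default). Deliberately permissive — the filter's job is to build a large
weakly co-expressed universe for clustering, not to call significance.

**Clustering.** k-means (Euclidean, random initialization, 10 restarts,
best within-cluster sum of squares, seeded) on per-(stage, genotype) mean
z-profiles — not per-animal columns, so each gene contributes one smoothed
profile per analysis. Four analyses by default: k ∈ {10, 13} × windows
{all ten stages, seven postnatal stages}; the 8–13 sweep for estimating k
uses average-linkage hierarchical clustering and picks the k with the
largest relative merge-height gap (ratio of the height that destroys k
clusters to the height that created them), returning the lower bound with
a warning when all profiles are identical. "Equivalent clusters" across
analyses are matched by shared GO-term enrichment, not by label alignment.
Consensus membership defaults to ≥ 3 of 4 analyses, with the 2-of-3
variant and a strict greater-than reading available as options.

**Contrasts.** Welch's unequal-variance two-sided t-test throughout
(scipy); set-level tests pool the k member z-scores × animals per group by
default (matching the described 5-members-per-set testing), with a
per-sample set-score mode as an alternative. The single-gene test compares
a gene's between-genotype difference with the central 95% interval
(linear-interpolated quantiles — the quantile rule was unspecified) of all
genes' differences at that time point, and reports a mean-rank percentile.
A one-sample Kolmogorov–Smirnov normality check is provided as a reported
diagnostic only; it gates nothing, since the source procedure reported it
and proceeded with t-tests regardless.

## The synthetic cohorts

`SimulationConfig` defaults define the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 2000 | total genes (signature blocks + background) |
| `n_celltypes` | 6 | planted programs (proliferating, ecm, angiogenesis, adipogenic, satellite, contractile) |
| `signatures_per_celltype` | 50 | genes per program |
| `phenotype_effect` | 0.7 | target Pearson r of growth-program genes with ADG/kg |
| `noise_sd` | 0.3 | log2 Gaussian noise SD |
| `amplitude` | 8.0 | log2 shift per unit cell fraction (phenotype cohort) |
| `profile_amplitude` | 2.0 | log2 swing of stage profiles (development cohort) |
| `dirichlet_concentration` | 2.0 per type | latent fraction variability |
| `n_phenotype_samples` | 48 | steers, 2 sites × treatment/control |
| `n_animals_per_group` | 4 | per stage per genotype in the time course |
| `genotype_offsets` | ecm +0.5 log2 at 12/25 mo | planted genotype divergence |

Phenotype cohort: per-sample cell fractions are Dirichlet; a signature gene
of cell type c is baseline + amplitude·(f_c − E f_c) + noise; ADG/kg is an
affine map of the *proliferating* fraction plus Gaussian noise whose
variance is solved analytically so that growth-program genes reach the
target correlation in expectation — the phenotype is coupled to the latent
fraction, never to any individual gene, so signature recovery genuinely
tests the pipeline. Targets that the noise level makes unreachable raise
instead of silently degrading. The ADG/kg scale (0.002 ± 0.0004 per day)
matches steers gaining ~1 kg/day at ~450 kg liveweight; intramuscular fat
is drawn from the 2–9% range typical of the motivating cohorts.

Development cohort: ten stages (60/135/195 days post conception, birth,
3/7/12/20/25/30 months), genotypes `highmuscle`/`highmarble`. Each program
follows a piecewise-linear stage profile in [0, 1]; the ECM program
defaults to the canonical post-birth decline, and the default genotype
offsets plant the 12/25-month ECM divergence the loose filter looks for.
Random profiles are drawn with a greedy separation rule — among in-range
candidates (dynamic range ≥ 0.5 within both the full and the postnatal
window), the draw least correlated with previously drawn programs is kept.
Without this, "distinct programs" can be accidental near-copies or
window-flat curves, and recovery benchmarks would measure the generator's
degeneracy rather than the pipeline; `bump_stage_profiles` provides fully
deterministic well-separated profiles when a benchmark needs an exact
program count. All randomness flows from the single config seed through
one generator stream per cohort; equal configs give byte-identical
cohorts.

What the generator does *not* emulate: probe-level effects, dye/batch
structure, normalization artifacts, correlated noise between genes beyond
the shared latent fractions, serial-biopsy autocorrelation, and the
mixed-model normalization applied upstream of the original matrices.
Passing recovery benchmarks therefore demonstrates the pipeline's
correctness and calibration under its own assumptions, not performance on
raw microarray data.

## Benchmarks the suite asserts

- mHG exact p vs a 20,000-permutation estimate (3 Monte-Carlo SE) and the
  hypergeometric tail vs exhaustive enumeration (all N ≤ 12).
- Empirical-null uniformity on pure-noise cohorts (KS, α = 0.01, 200
  replicates of 2,000 × 48).
- Signature recovery at target r = 0.7: planted genes' median rank in the
  top 5%; planted set p ≤ 0.001 at 10,000 draws in ≥ 95% of 40 seeds.
- Cluster recovery at noise 0.5 over 6 programs, 4 analyses × 20 seeds:
  median ARI ≥ 0.8 against planted labels (computed over planted genes;
  background genes carry no true label) and ≥ 90% correct marker
  attribution. The residual ARI shortfall from 1 reflects k > 6 splitting
  tight programs, which the enrichment-based consensus absorbs by design.
- Exactness of Welch/BH/z/ADG arithmetic to 1e-10 and a genotype set-test
  type-I error within [0.03, 0.07] at α = 0.05 over 2,000 null cohorts.
- Byte-identical artifact checksums across pipeline reruns.

Problem sizes in the test suite and acceptance script (e.g. 100–200 null
replicates, 10–40 seeds per benchmark, 120–2,000-gene cohorts) were chosen
to give stable Monte-Carlo margins at desk scale; all are plain function
arguments and can be raised.

## Known limitations

- GO structure is flat: no DAG propagation or term-redundancy reduction,
  so parent/child terms can double-count genes.
- The mHG exact p assumes a uniformly random ranking as the null; under
  strong inter-gene correlation it is anti-conservative, which is why the
  signature-level claim rests on the random-set empirical null instead.
- Multiple-testing control is per-stage for the contrast tests, mirroring
  the per-time-point reporting convention of the motivating analysis, and
  serial biopsies are treated as independent.
- Gene identifiers are assumed already collapsed to gene level; probe
  handling and GEO retrieval are out of scope.
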