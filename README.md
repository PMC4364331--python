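# growthsig

Small gene-set signatures of skeletal-muscle growth rate, and marker-based
attribution of developmental co-expression clusters to muscle cell types.

`growthsig` is aimed at transcriptomics researchers working with bulk
expression data from growing muscle (the motivating system is bovine
*longissimus* muscle) who want to (i) find small, robust sets of genes whose
combined expression tracks a growth phenotype, (ii) calibrate how surprising
that tracking is against random gene sets, and (iii) work out *which cell
population* is most likely producing each co-expression signal, using
published cell-type markers rather than single-cell data.

## The method

**Phenotype.** The growth phenotype is size-normalized average daily gain,

&nbsp;&nbsp;&nbsp;&nbsp;ADG/kg = ADG / ((W_start + W_end) / 2)&nbsp;&nbsp;&nbsp;[1/day],

i.e. daily liveweight gain divided by the mean liveweight over the gain
period.

**Ranking and enrichment.** Every gene g is ranked by the Pearson
correlation r_g between its log2 expression and ADG/kg across animals.
Functional enrichment towards the top of the ranked list uses the minimum
hypergeometric (mHG) scan: for a term with B members in a universe of N
genes, mHG = min over prefixes n of P(X ≥ b(n)), X ~ Hypergeom(N, B, n).
Because this minimum is taken over N dependent tests, its exact p-value is
computed by a lattice-path dynamic program that counts, among all C(N, B)
placements of the term's members, the fraction whose scan reaches the
observed minimum; a seeded permutation estimate is the fallback for very
large problems. FDR across terms is Benjamini–Hochberg.

**Signatures.** A 5-gene signature for an enriched term is built by walking
the term's members in ranked order and keeping genes that are co-expressed
through development (Pearson correlation with the running set-mean
developmental profile ≥ 0.6). The signature's per-sample score is the mean
of the member z-scores (each gene standardized to mean 0, SD 1 across the
cohort). Its correlation with ADG/kg is calibrated with an empirical null:
sample k random genes, score, correlate, repeat n_draws times, and report
p = (#{r_random > r_observed} + 1) / (n_draws + 1).

**Cell-type attribution.** In a two-genotype developmental time course
(high-muscling vs high-marbling crosses, ten stages from 60 days post
conception to 30 months), genes weakly co-expressed with the
extracellular-matrix program are kept by a loose sign-only filter
(expression decreasing after birth; higher in the high-marbling genotype at
12 and 25 months). The filtered genes are k-means clustered on their
per-(stage, genotype) mean z-profiles in four analyses (k = 10 and 13, over
the full course and the postnatal window; k itself is estimated by
average-linkage hierarchical clustering). Clusters are annotated by
hypergeometric GO enrichment; genes co-clustered with a term in ≥ 3 of the
4 analyses form its consensus list, and a marker gene is attributed to the
process whose enriched term it co-clusters with in ≥ 3 analyses.

**Contrasts.** Genotype and treatment comparisons of a signature use
two-sided Welch t-tests on the pooled member z-scores; single genes are
instead judged against the empirical 95% interval of all genes'
between-genotype differences at the same time point.

Because the original cohorts are not redistributable, the package ships a
synthetic-cohort generator: a latent Dirichlet cell-type mixture on the
log2 scale whose "proliferating" fraction drives the phenotype, with smooth
per-cell-type stage profiles and plantable genotype offsets, all seeded and
with full ground truth recorded — so every stage of the pipeline has
parameter-recovery tests.

## Worked example

```bash
cat > run.yaml <<'YAML'
seed: 7
simulation: {n_genes: 2000}
n_draws: 10000
YAML
growthsig run --config run.yaml --outdir out/
```

prints

```
growth-signature pipeline report
==================================
signature (TERM:proliferating): PROLIFERATING_0017, PROLIFERATING_0001, PROLIFERATING_0032, PROLIFERATING_0047, PROLIFERATING_0015
  phenotype correlation r = 0.728, empirical p = 1.00e-04 (10000 draws)
loose co-expression filter: 292 / 2000 genes
consensus list for TERM:ecm: 48 genes
markers: 9 / 30 present in clustered universe
recovery vs planted truth:
  growth_gene_median_rank_pct = 1.275
  growth_term_q = 1.302e-99
  marker_attribution_accuracy = 1
  median_ari = 1
  set_empirical_p = 9.999e-05
  set_observed_r = 0.7278
```

Reading this: the pipeline recovered a 5-gene signature from the planted
growth program whose mean z-score correlates r = 0.728 with ADG/kg; only
~1 in 10,000 random 5-gene sets beat it (empirical p = 1.0e-4, the minimum
possible at 10,000 draws). The planted growth genes sit at the 1.3rd
percentile of the correlation ranking, the planted term dominates the mHG
enrichment (q ≈ 1e-99), the loose filter kept 292 genes (the 100 planted
ECM genes plus sign-test survivors), clustering reproduced the planted
partition exactly (ARI = 1), and every planted marker present in the
clustered universe was attributed to its true program.

Every output (expression TSVs, sample CSVs, ranked list, enrichment table,
gene-set GMT, null JSON, cluster/consensus/attribution TSVs) lands in
`out/` together with `manifest.json` recording each stage's seed, counts
and artifact SHA-256 checksums; rerunning the same config reproduces the
checksums byte for byte.

The same stages are available piecemeal (`growthsig rank`, `enrich`,
`build-set`, `null`, `contrast`, ...) and as library functions
(`rank_by_correlation`, `enrich_ranked_list`, `select_top_genes`,
`empirical_null_pvalue`, `run_kmeans_analyses`, `attribute_markers`, ...).

## File formats

- **Expression**: TSV, first column `gene`, remaining columns sample IDs,
  body of finite log2 intensities ('.' decimal, no quoting, no missing
  values).
- **Samples**: CSV with columns `sample_id, cohort, genotype, stage,
  age_days, treatment, site, adg_per_kg, imf_pct`.
- **Gene sets / annotation**: standard GMT (term, description, genes).
- **Markers**: CSV with `gene, cell_type, sign, source`; a reconstructed
  table of published skeletal-muscle cell-type markers ships with the
  package (`growthsig.load_builtin_markers()`).
- **Reports / truth / manifests**: JSON.

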