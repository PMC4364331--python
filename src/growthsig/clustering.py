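"""Consensus k-means clustering of developmental profiles and marker-based
cell-type attribution.

The procedure mirrors a four-analysis consensus design: genes passing a
loose co-expression filter are clustered by k-means at two values of k (10
and 13 by default, k estimated beforehand by hierarchical clustering) over
two stage windows (the whole time course and the postnatal stages only).
Each cluster of each analysis is annotated by hypergeometric GO enrichment;
"equivalent clusters" across analyses are linked by sharing an enriched
term, a consensus gene list keeps the genes co-clustered with a term in
enough analyses, and published cell-type markers are attributed to the
process whose term they co-cluster with in enough analyses.

Clustering operates on per-(stage, genotype) mean z-profiles, not on
per-animal columns, so an analysis sees one smoothed profile per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .io import (
    POSTNATAL_STAGES,
    ExpressionMatrix,
    GeneAnnotation,
    MarkerTable,
    SampleTable,
)
from .enrichment import enrich_cluster

logger = logging.getLogger(__name__)

WINDOWS = ("all", "postnatal")


def window_stages(samples: SampleTable, window: str) -> list[str]:
    present = samples.stages_present()
    if window == "all":
        return present
    if window == "postnatal":
        return [s for s in present if s in POSTNATAL_STAGES]
    raise ValueError(f"unknown window {window!r} (expected 'all' or 'postnatal')")


def stage_genotype_profiles(
    z: pd.DataFrame,
    samples: SampleTable,
    window: str = "all",
) -> pd.DataFrame:
    """Genes x (stage, genotype) matrix of mean z-scores, stage-ordered.

    This is the profile space every clustering analysis operates in: one
    column per (stage, genotype) cell, averaging the animals in that cell.
    """
    stages = window_stages(samples, window)
    if len(stages) < 2:
        raise ValueError(f"window {window!r} covers {len(stages)} stages; need >= 2")
    genotypes = sorted(set(samples.data["genotype"]))
    columns = {}
    for stage in stages:
        for geno in genotypes:
            ids = [s for s in samples.samples_where(stage=stage, genotype=geno) if s in z.columns]
            if not ids:
                continue
            columns[f"{stage}|{geno}"] = z[ids].mean(axis=1)
    return pd.DataFrame(columns)


def loose_coexpression_filter(
    dev_matrix: ExpressionMatrix,
    samples: SampleTable,
    stages_of_interest: tuple[str, ...] = ("12mo", "25mo"),
    high_genotype: str = "highmarble",
    low_genotype: str = "highmuscle",
) -> list[str]:
    """Sign-only filter for genes weakly co-expressed with the ECM program.

    A gene passes when (a) its pooled-genotype mean expression at birth
    exceeds its pooled mean at the final stage (expression decreasing after
    birth), and (b) its ``high_genotype`` mean exceeds its ``low_genotype``
    mean at every stage of interest.  Deliberately loose: sign comparisons
    only, no significance threshold.
    """
    present = samples.stages_present()
    required = {"birth", *stages_of_interest}
    missing = sorted(required - set(present))
    if missing:
        raise ValueError(f"required stages missing from cohort: {missing}")
    final_stage = present[-1]
    data = dev_matrix.data

    def group_mean(stage: str, genotype: str | None = None) -> pd.Series:
        if genotype is None:
            ids = samples.samples_where(stage=stage)
        else:
            ids = samples.samples_where(stage=stage, genotype=genotype)
        return data[list(ids)].mean(axis=1)

    keep = group_mean("birth") > group_mean(final_stage)
    for stage in stages_of_interest:
        keep &= group_mean(stage, high_genotype) > group_mean(stage, low_genotype)
    passed = sorted(data.index[keep])
    logger.info("loose co-expression filter kept %d of %d genes", len(passed), len(data))
    return passed


def estimate_k(profiles: pd.DataFrame, k_range: tuple[int, int] = (8, 13)) -> int:
    """Estimate the cluster count by hierarchical clustering.

    Average-linkage Euclidean agglomeration of the profiles; k is the value
    in ``k_range`` with the largest relative merge-height gap (the ratio of
    the height that destroys k clusters to the height that created them).
    Degenerate all-identical profiles return the lower bound with a warning.
    """
    kmin, kmax = k_range
    X = profiles.to_numpy()
    n = X.shape[0]
    if n < 2 * kmax:
        raise ValueError(f"need at least {2 * kmax} genes to estimate k in {k_range}")
    heights = linkage(X, method="average", metric="euclidean")[:, 2]
    if heights[-1] <= 0:
        logger.warning("all profiles identical; returning k=%d", kmin)
        return kmin
    eps = 1e-12
    best_k, best_gap = kmin, -np.inf
    for k in range(kmin, kmax + 1):
        # after merge n-k-1 there are k clusters; merge n-k destroys them
        gap = heights[n - k] / (heights[n - k - 1] + eps)
        if gap > best_gap + 1e-12:
            best_k, best_gap = k, gap
    return best_k


@dataclass
class ClusterAnalysis:
    """One k-means analysis: a partition of the filtered genes."""

    analysis_id: str
    k: int
    window: str
    labels: pd.Series  # gene -> cluster int
    centroids: pd.DataFrame  # cluster x profile columns
    seed: int
    n_iter: int

    def cluster_genes(self, cluster: int) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster])

    def clusters(self) -> list[int]:
        return sorted(set(self.labels))


def run_kmeans_analyses(
    z: pd.DataFrame,
    samples: SampleTable,
    genes=None,
    ks: tuple[int, ...] = (10, 13),
    windows: tuple[str, ...] = WINDOWS,
    seed: int = 0,
    n_init: int = 10,
) -> list[ClusterAnalysis]:
    """k-means over every (k, window) combination.

    Each analysis clusters the per-(stage, genotype) mean z-profiles with
    ``n_init`` random restarts, keeping the lowest within-cluster sum of
    squares; all randomness derives from ``seed`` so reruns are identical.
    """
    if genes is not None:
        z = z.loc[[g for g in genes if g in z.index]]
    analyses: list[ClusterAnalysis] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(ks) * len(windows))
    i = 0
    for window in windows:
        profiles = stage_genotype_profiles(z, samples, window)
        for k in ks:
            state = int(child_seeds[i] % (2**31)); i += 1
            km = KMeans(n_clusters=k, init="random", n_init=n_init, random_state=state)
            labels = km.fit_predict(profiles.to_numpy())
            analyses.append(
                ClusterAnalysis(
                    analysis_id=f"k{k}_{window}",
                    k=k,
                    window=window,
                    labels=pd.Series(labels, index=profiles.index),
                    centroids=pd.DataFrame(km.cluster_centers_, columns=profiles.columns),
                    seed=state,
                    n_iter=int(km.n_iter_),
                )
            )
    return analyses


@dataclass
class AnnotatedAnalyses:
    """Per-analysis map cluster -> enriched term IDs (q at or below threshold)."""

    analyses: list[ClusterAnalysis]
    enriched: dict[str, dict[int, list[str]]]
    q_threshold: float

    def term_cluster(self, analysis_id: str, term_id: str) -> list[int]:
        """Clusters of one analysis enriched for a term."""
        return [c for c, terms in self.enriched[analysis_id].items() if term_id in terms]

    def all_terms(self) -> list[str]:
        terms = set()
        for per_cluster in self.enriched.values():
            for t in per_cluster.values():
                terms.update(t)
        return sorted(terms)


def annotate_analyses(
    analyses: list[ClusterAnalysis],
    annotation: GeneAnnotation,
    q_threshold: float = 0.05,
    min_term_size: int = 5,
) -> AnnotatedAnalyses:
    """Hypergeometric enrichment of every cluster of every analysis.

    The universe of each test is that analysis's clustered gene list.
    """
    if len(annotation) == 0:
        logger.warning("empty annotation: no cluster will be annotated")
    enriched: dict[str, dict[int, list[str]]] = {}
    for analysis in analyses:
        universe = list(analysis.labels.index)
        analysis_annotation = annotation.restricted_to(universe)  # harmonize once
        per_cluster: dict[int, list[str]] = {}
        for cluster in analysis.clusters():
            members = analysis.cluster_genes(cluster)
            if not members or len(analysis_annotation) == 0:
                per_cluster[cluster] = []
                continue
            table = enrich_cluster(
                members, analysis_annotation, universe, min_term_size=min_term_size
            )
            hits = table.loc[table["q"] <= q_threshold, "term_id"] if len(table) else []
            per_cluster[cluster] = sorted(hits)
        enriched[analysis.analysis_id] = per_cluster
    return AnnotatedAnalyses(analyses=analyses, enriched=enriched, q_threshold=q_threshold)


def consensus_genes(
    annotated: AnnotatedAnalyses,
    term_id: str,
    term_genes,
    min_support: int = 3,
    strict: bool = False,
) -> list[str]:
    """Genes of a term co-clustered with it in at least ``min_support`` analyses.

    A gene supports the term in an analysis when the cluster holding the gene
    is enriched for the term there.  ``strict=True`` requires support
    strictly greater than ``min_support`` (the literal 'more than' reading).
    """
    support = consensus_support(annotated, term_id, term_genes)
    if not support:
        logger.warning("term %s enriched in no analysis; empty consensus", term_id)
        return []
    if strict:
        return sorted(g for g, s in support.items() if s > min_support)
    return sorted(g for g, s in support.items() if s >= min_support)


def consensus_support(annotated: AnnotatedAnalyses, term_id: str, term_genes) -> dict[str, int]:
    """Per-gene count of analyses in which the gene co-clusters with the term."""
    term_genes = set(term_genes)
    counts: dict[str, int] = {}
    any_enriched = False
    for analysis in annotated.analyses:
        clusters = annotated.term_cluster(analysis.analysis_id, term_id)
        if clusters:
            any_enriched = True
        hit_genes = set()
        for c in clusters:
            hit_genes.update(analysis.cluster_genes(c))
        for g in term_genes & hit_genes:
            counts[g] = counts.get(g, 0) + 1
    if not any_enriched:
        return {}
    for g in term_genes:
        counts.setdefault(g, 0)
    return counts


@dataclass
class MarkerAttribution:
    """A marker gene's attributed process(es) with consensus support."""

    marker: str
    cell_type: str  # published cell type of the marker
    attributed_terms: tuple[str, ...]
    support: dict[str, int] = field(default_factory=dict)
    terms_per_analysis: dict[str, list[str]] = field(default_factory=dict)
    present: bool = True


def attribute_markers(
    annotated: AnnotatedAnalyses,
    markers: MarkerTable,
    min_support: int = 3,
) -> list[MarkerAttribution]:
    """Attribute each positive marker to the process whose enriched term it
    co-clusters with in at least ``min_support`` analyses.

    Markers absent from the clustered universe are reported unattributed;
    ties (several terms reaching support) are reported, not broken.
    """
    universe = set()
    for analysis in annotated.analyses:
        universe.update(analysis.labels.index)
    out: list[MarkerAttribution] = []
    for _, row in markers.positive_markers().iterrows():
        gene, cell_type = row["gene"], row["cell_type"]
        if gene not in universe:
            out.append(
                MarkerAttribution(gene, cell_type, (), present=False)
            )
            continue
        support: dict[str, int] = {}
        per_analysis: dict[str, list[str]] = {}
        for analysis in annotated.analyses:
            if gene not in analysis.labels.index:
                continue
            cluster = int(analysis.labels.loc[gene])
            terms = annotated.enriched[analysis.analysis_id].get(cluster, [])
            per_analysis[analysis.analysis_id] = list(terms)
            for t in terms:
                support[t] = support.get(t, 0) + 1
        attributed = tuple(sorted(t for t, s in support.items() if s >= min_support))
        out.append(
            MarkerAttribution(
                marker=gene,
                cell_type=cell_type,
                attributed_terms=attributed,
                support=support,
                terms_per_analysis=per_analysis,
            )
        )
    return out
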