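"""Loose co-expression filter, k estimation, consensus clustering, attribution."""

import numpy as np
import pandas as pd
import pytest

import growthsig as gs
from growthsig.clustering import (
    AnnotatedAnalyses,
    ClusterAnalysis,
    consensus_support,
    stage_genotype_profiles,
    window_stages,
)


def independent_filter_oracle(matrix, samples, stages=("12mo", "25mo")):
    """Re-apply the two sign rules gene by gene, straight off the metadata."""
    passed = []
    meta = samples.data
    final_stage = samples.stages_present()[-1]
    for gene in matrix.genes:
        row = matrix.data.loc[gene]

        def mean_of(stage, geno=None):
            sel = meta["stage"] == stage
            if geno:
                sel &= meta["genotype"] == geno
            return row[meta.loc[sel, "sample_id"]].mean()

        ok = mean_of("birth") > mean_of(final_stage)
        for st in stages:
            ok = ok and mean_of(st, "highmarble") > mean_of(st, "highmuscle")
        if ok:
            passed.append(gene)
    return sorted(passed)


class TestLooseFilter:
    def test_flat_gene_rejected_and_constructed_gene_accepted(self):
        config = gs.SimulationConfig(
            seed=0, n_genes=12, n_celltypes=2, signatures_per_celltype=3,
            noise_sd=0.0,
            stage_profiles={"proliferating": [0.5] * 10, "ecm": gs.simulate._ECM_PROFILE},
            genotype_offsets={("ecm", "12mo"): 0.5, ("ecm", "25mo"): 0.5},
        )
        matrix, samples, truth = gs.generate_development_cohort(config)
        kept = gs.loose_coexpression_filter(matrix, samples)
        flat = set(truth.signature_genes("proliferating"))
        declining = set(truth.signature_genes("ecm"))
        assert declining <= set(kept)  # decreasing + offset: accepted
        assert not (flat & set(kept))  # flat: fails strict decrease

    def test_missing_stage_rejected(self):
        config = gs.SimulationConfig(seed=1, n_genes=20, signatures_per_celltype=2)
        matrix, samples, _ = gs.generate_development_cohort(config)
        trimmed = gs.SampleTable(samples.data[samples.data["stage"] != "25mo"])
        kept_cols = list(trimmed.sample_ids)
        with pytest.raises(ValueError, match="25mo"):
            gs.loose_coexpression_filter(matrix.subset_samples(kept_cols), trimmed)

    def test_planted_recall_and_oracle_agreement(self):
        """Most planted ECM genes pass, and the pass-set equals an
        independent re-application of the two rules; the pass-set is
        enriched for the planted term."""
        config = gs.SimulationConfig(seed=2, n_genes=600, signatures_per_celltype=50)
        matrix, samples, truth = gs.generate_development_cohort(config)
        kept = gs.loose_coexpression_filter(matrix, samples)
        assert kept == independent_filter_oracle(matrix, samples)
        ecm = set(truth.signature_genes("ecm"))
        assert len(ecm & set(kept)) >= 0.9 * len(ecm)
        annotation = gs.generate_annotation(truth, n_background_terms=0)
        table = gs.enrich_cluster(kept, annotation, list(matrix.genes))
        row = table[table["term_id"] == "TERM:ecm"].iloc[0]
        assert row["q"] < 0.01


class TestEstimateK:
    def _profiles(self, config):
        matrix, samples, truth = gs.generate_development_cohort(config)
        z = gs.zscore_standardize(matrix)
        signature = [g for g in z.index if g in truth.celltype_of_gene]
        return stage_genotype_profiles(z.loc[signature], samples, "all")

    def test_three_separated_groups(self):
        config = gs.SimulationConfig(
            seed=0, n_celltypes=3, signatures_per_celltype=10, n_genes=40,
            noise_sd=0.0, genotype_offsets={},
        )
        assert gs.estimate_k(self._profiles(config), (2, 6)) == 3

    def test_identical_profiles_return_lower_bound(self):
        profiles = pd.DataFrame(np.ones((30, 8)), index=[f"g{i}" for i in range(30)])
        assert gs.estimate_k(profiles, (2, 5)) == 2

    def test_ten_program_fixture_recovered(self):
        """Planted 10-program cohorts: k = 10 recovered in most seeds."""
        hits = 0
        profiles = gs.simulate.bump_stage_profiles(10)
        for seed in range(20):
            config = gs.SimulationConfig(
                seed=seed, n_celltypes=10, signatures_per_celltype=30, n_genes=340,
                noise_sd=0.3, genotype_offsets={}, stage_profiles=profiles,
            )
            hits += gs.estimate_k(self._profiles(config), (8, 13)) == 10
        assert hits >= 16


class TestKmeansAnalyses:
    def test_k1_single_cluster(self, development_cohort):
        _, matrix, samples, _ = development_cohort
        z = gs.zscore_standardize(matrix)
        (analysis,) = gs.run_kmeans_analyses(z, samples, ks=(1,), windows=("all",), seed=0)
        assert set(analysis.labels) == {0}
        assert len(analysis.labels) == len(z)

    def test_partition_property(self, development_cohort):
        _, matrix, samples, _ = development_cohort
        z = gs.zscore_standardize(matrix)
        analyses = gs.run_kmeans_analyses(z, samples, seed=5)
        for analysis in analyses:
            assert sorted(analysis.labels.index) == sorted(z.index)
            assert analysis.labels.notna().all()

    def test_zero_noise_partition_equals_planted_grouping(self):
        config = gs.SimulationConfig(
            seed=3, n_celltypes=4, signatures_per_celltype=10, n_genes=40,
            noise_sd=0.0, genotype_offsets={},
        )
        matrix, samples, truth = gs.generate_development_cohort(config)
        z = gs.zscore_standardize(matrix)
        (analysis,) = gs.run_kmeans_analyses(z, samples, ks=(4,), windows=("all",), seed=1)
        mapping = {}
        for gene, label in analysis.labels.items():
            program = truth.celltype_of_gene[gene]
            mapping.setdefault(program, set()).add(label)
        # each program maps to exactly one cluster and clusters don't mix programs
        assert all(len(labels) == 1 for labels in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == 4

    def test_seeded_determinism(self, development_cohort):
        _, matrix, samples, _ = development_cohort
        z = gs.zscore_standardize(matrix)
        a1 = gs.run_kmeans_analyses(z, samples, seed=7)
        a2 = gs.run_kmeans_analyses(z, samples, seed=7)
        for x, y in zip(a1, a2):
            assert x.labels.equals(y.labels)

    def test_tiny_window_rejected(self, development_cohort):
        _, matrix, samples, _ = development_cohort
        z = gs.zscore_standardize(matrix)
        birth_only = gs.SampleTable(samples.data[samples.data["stage"] == "birth"])
        with pytest.raises(ValueError, match="stages"):
            gs.run_kmeans_analyses(
                z[list(birth_only.sample_ids)], birth_only, ks=(2,), windows=("all",), seed=0
            )


def _manual_annotated(term_to_clusters, labels_per_analysis):
    """Build an AnnotatedAnalyses by hand for consensus/attribution tests."""
    analyses = []
    enriched = {}
    for aid, labels in labels_per_analysis.items():
        series = pd.Series(labels)
        analyses.append(
            ClusterAnalysis(aid, k=len(set(labels.values())), window="all",
                            labels=series, centroids=pd.DataFrame(), seed=0, n_iter=1)
        )
        enriched[aid] = term_to_clusters.get(aid, {})
    return AnnotatedAnalyses(analyses=analyses, enriched=enriched, q_threshold=0.05)


class TestConsensus:
    def make(self):
        # four analyses; gene x co-clusters with term T in 4, gene y in 2
        labels = {
            f"A{i}": {"x": 0, "y": 1 if i < 2 else 0, "z": 2} for i in range(4)
        }
        enriched = {f"A{i}": {0: ["T"], 1: [], 2: []} for i in range(4)}
        return _manual_annotated(enriched, labels)

    def test_support_counts_and_thresholds(self):
        annotated = self.make()
        support = consensus_support(annotated, "T", ["x", "y", "z"])
        assert support == {"x": 4, "y": 2, "z": 0}
        assert gs.consensus_genes(annotated, "T", ["x", "y", "z"], min_support=3) == ["x"]
        assert gs.consensus_genes(annotated, "T", ["x", "y", "z"], min_support=2) == ["x", "y"]
        # literal 'more than three' reading
        assert gs.consensus_genes(annotated, "T", ["x", "y", "z"], min_support=3, strict=True) == ["x"]

    def test_monotone_in_min_support(self):
        annotated = self.make()
        sizes = [
            len(gs.consensus_genes(annotated, "T", ["x", "y", "z"], min_support=s))
            for s in (1, 2, 3, 4)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_unenriched_term_gives_empty_list(self):
        annotated = self.make()
        assert gs.consensus_genes(annotated, "MISSING", ["x"], min_support=1) == []

    def test_order_invariance(self):
        annotated = self.make()
        reversed_annotated = AnnotatedAnalyses(
            analyses=annotated.analyses[::-1],
            enriched=annotated.enriched,
            q_threshold=0.05,
        )
        assert consensus_support(annotated, "T", ["x", "y"]) == consensus_support(
            reversed_annotated, "T", ["x", "y"]
        )


class TestAttribution:
    def test_marker_attributed_at_full_support(self):
        labels = {f"A{i}": {"m": 0, "x": 0} for i in range(4)}
        enriched = {f"A{i}": {0: ["TERM:angiogenesis"]} for i in range(4)}
        annotated = _manual_annotated(enriched, labels)
        markers = gs.MarkerTable(
            pd.DataFrame({"gene": ["m"], "cell_type": ["endothelial"], "sign": ["+"], "source": ["s"]})
        )
        (attribution,) = gs.attribute_markers(annotated, markers, min_support=3)
        assert attribution.attributed_terms == ("TERM:angiogenesis",)
        assert attribution.support == {"TERM:angiogenesis": 4}

    def test_absent_marker_reported_unattributed(self):
        labels = {"A0": {"x": 0}}
        annotated = _manual_annotated({"A0": {0: []}}, labels)
        markers = gs.MarkerTable(
            pd.DataFrame({"gene": ["ghost"], "cell_type": ["fap"], "sign": ["+"], "source": ["s"]})
        )
        (attribution,) = gs.attribute_markers(annotated, markers)
        assert not attribution.present and attribution.attributed_terms == ()

    def test_planted_markers_attributed_zero_noise(self):
        config = gs.SimulationConfig(
            seed=5, n_celltypes=4, signatures_per_celltype=10, n_genes=60,
            noise_sd=0.0, genotype_offsets={},
        )
        matrix, samples, truth = gs.generate_development_cohort(config)
        z = gs.zscore_standardize(matrix)
        analyses = gs.run_kmeans_analyses(z, samples, ks=(4,), windows=("all", "postnatal"), seed=2)
        annotation = gs.generate_annotation(truth, n_background_terms=0)
        annotated = gs.annotate_analyses(analyses, annotation)
        markers = gs.synthetic_marker_table(truth, per_type=3)
        attributions = gs.attribute_markers(annotated, markers, min_support=2)
        for attribution in attributions:
            assert f"TERM:{attribution.cell_type}" in attribution.attributed_terms


class TestAnnotateAnalyses:
    def test_planted_cluster_term_retained(self):
        config = gs.SimulationConfig(
            seed=6, n_celltypes=3, signatures_per_celltype=10, n_genes=60,
            noise_sd=0.2, genotype_offsets={},
        )
        matrix, samples, truth = gs.generate_development_cohort(config)
        z = gs.zscore_standardize(matrix)
        analyses = gs.run_kmeans_analyses(z, samples, ks=(6,), windows=("all",), seed=3)
        annotation = gs.generate_annotation(truth, n_background_terms=0)
        annotated = gs.annotate_analyses(analyses, annotation)
        retained = set()
        for per_cluster in annotated.enriched.values():
            for terms in per_cluster.values():
                retained.update(terms)
        assert {"TERM:proliferating", "TERM:ecm", "TERM:angiogenesis"} <= retained

    def test_empty_annotation_gives_empty_maps(self, development_cohort):
        _, matrix, samples, _ = development_cohort
        z = gs.zscore_standardize(matrix)
        analyses = gs.run_kmeans_analyses(z, samples, ks=(2,), windows=("all",), seed=0)
        outside = gs.GeneAnnotation(
            {"X": gs.AnnotationTerm("X", "x", frozenset(["nope1", "nope2", "nope3", "nope4", "nope5"]))}
        )
        annotated = gs.annotate_analyses(analyses, outside)
        assert all(terms == [] for terms in annotated.enriched["k2_all"].values())


def test_window_stage_selection(development_cohort):
    _, _, samples, _ = development_cohort
    assert len(window_stages(samples, "all")) == 10
    assert window_stages(samples, "postnatal") == ["3mo", "7mo", "12mo", "20mo", "25mo", "30mo"]
    with pytest.raises(ValueError):
        window_stages(samples, "prenatal")
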