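"""End-to-end orchestration: synthesize (or load) cohorts, rank genes against
the growth phenotype, enrich the ranked list, build and calibrate a 5-gene
signature, filter and cluster the development cohort, attribute markers, and
run the genotype/treatment contrasts — all from one YAML-able configuration,
with a manifest of every artifact's checksum so a rerun can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, enrichment, ranking, scoring, simulate
from .contrasts import genotype_set_test, treatment_set_test
from .io import (
    load_builtin_markers,
    read_expression,
    read_markers,
    read_samples,
    validate_cohort,
    write_expression,
    write_gmt,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phenotype": "adg_per_kg",
    "simulation": {},
    "annotation": {"n_background_terms": 20, "term_size_range": [10, 50]},
    "enrichment": {"min_term_size": 5, "q_threshold": 0.05},
    "set_size": 5,
    "coexpr_min": 0.6,
    "n_draws": 10000,
    "ks": [10, 13],
    "windows": ["all", "postnatal"],
    "min_support": 3,
    "cluster_input": "filtered",
    "markers": "synthetic",
}

_REQUIRED_KEYS = ("seed", "phenotype", "set_size", "n_draws", "ks", "windows", "min_support")


class ConfigError(ValueError):
    """Raised when the pipeline configuration fails validation."""


def validate_config(config: dict) -> dict:
    """Merge with defaults and check the schema before any stage runs."""
    merged = {**DEFAULT_CONFIG, **config}
    for section in ("annotation", "enrichment", "simulation"):
        merged[section] = {**DEFAULT_CONFIG.get(section, {}), **(config.get(section) or {})}
    for key in _REQUIRED_KEYS:
        if merged.get(key) is None:
            raise ConfigError(f"config missing required key {key!r}")
    if not isinstance(merged["seed"], int):
        raise ConfigError("seed must be an integer")
    if merged["set_size"] < 1 or merged["n_draws"] < 1 or merged["min_support"] < 1:
        raise ConfigError("set_size, n_draws and min_support must be positive")
    if not all(isinstance(k, int) and k >= 1 for k in merged["ks"]):
        raise ConfigError("ks must be positive integers")
    bad = [w for w in merged["windows"] if w not in clustering.WINDOWS]
    if bad:
        raise ConfigError(f"unknown windows {bad}")
    if merged["cluster_input"] not in ("filtered", "all"):
        raise ConfigError("cluster_input must be 'filtered' or 'all'")
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest.

    All artifacts land under ``outdir``; the manifest records every stage's
    inputs, seed, row counts and output checksums.  Identical configurations
    produce identical checksums.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": [], "artifacts": {}, "metrics": {}}
    seeds = np.random.SeedSequence(cfg["seed"]).generate_state(8) % (2**31)

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s: %s", stage, info)

    def save(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path.name), "sha256": _sha256(path)}

    # -- cohorts -------------------------------------------------------
    sim_cfg = simulate.SimulationConfig(**cfg["simulation"], seed=int(seeds[0]))
    phen_expr, phen_samples, phen_truth = simulate.generate_phenotype_cohort(sim_cfg)
    dev_expr, dev_samples, dev_truth = simulate.generate_development_cohort(sim_cfg)
    write_expression(phen_expr, outdir / "phenotype_expr.tsv")
    phen_samples.data.to_csv(outdir / "phenotype_samples.csv", index=False)
    write_expression(dev_expr, outdir / "development_expr.tsv")
    dev_samples.data.to_csv(outdir / "development_samples.csv", index=False)
    phen_truth.to_json(outdir / "phenotype_truth.json")
    dev_truth.to_json(outdir / "development_truth.json")
    for name in (
        "phenotype_expr.tsv", "phenotype_samples.csv", "development_expr.tsv",
        "development_samples.csv", "phenotype_truth.json", "development_truth.json",
    ):
        save(name, outdir / name)
    for label, (m, t, kind) in {
        "phenotype": (phen_expr, phen_samples, "phenotype"),
        "development": (dev_expr, dev_samples, "development"),
    }.items():
        check = validate_cohort(m, t, analysis=kind)
        if not check.ok:
            raise RuntimeError(f"stage validate_cohort[{label}] failed: {check}")
    record("synthesize", seed=int(seeds[0]), n_genes=phen_expr.shape[0],
           n_phenotype_samples=phen_expr.shape[1], n_development_samples=dev_expr.shape[1])

    # -- ranking -------------------------------------------------------
    phenotype = phen_samples.phenotype(cfg["phenotype"])
    ranked = ranking.rank_by_correlation(phen_expr, phenotype)
    ranked.to_tsv(outdir / "ranked.tsv")
    save("ranked.tsv", outdir / "ranked.tsv")
    growth_program = sim_cfg.celltypes[0]
    growth_genes = phen_truth.signature_genes(growth_program)
    ranks = [ranked.rank_of(g) for g in growth_genes if g in set(ranked.genes)]
    median_rank_pct = 100.0 * float(np.median(ranks)) / len(ranked)
    manifest["metrics"]["growth_gene_median_rank_pct"] = median_rank_pct
    record("rank", phenotype=cfg["phenotype"], n_ranked=len(ranked),
           n_excluded=ranked.n_excluded)

    # -- annotation + ranked-list enrichment ---------------------------
    ann_cfg = cfg["annotation"]
    annotation = simulate.generate_annotation(
        phen_truth,
        n_background_terms=int(ann_cfg["n_background_terms"]),
        term_size_range=tuple(ann_cfg["term_size_range"]),
        universe=list(phen_expr.genes),
    )
    write_gmt(annotation, outdir / "annotation.gmt")
    save("annotation.gmt", outdir / "annotation.gmt")
    enr = enrichment.enrich_ranked_list(
        ranked, annotation,
        min_term_size=int(cfg["enrichment"]["min_term_size"]),
        seed=int(seeds[1]),
    )
    enrichment.results_frame(enr).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    save("enrichment.tsv", outdir / "enrichment.tsv")
    growth_term = f"TERM:{growth_program}"
    growth_q = next((r.q for r in enr if r.term_id == growth_term), float("nan"))
    manifest["metrics"]["growth_term_q"] = growth_q
    record("enrich", n_terms=len(enr), top_term=enr[0].term_id if enr else None)

    # -- signature construction + empirical null -----------------------
    phen_z = scoring.zscore_standardize(phen_expr)
    dev_z = scoring.zscore_standardize(dev_expr)
    gene_set = None
    for result in enr:
        if result.B < int(cfg["set_size"]):
            continue
        try:
            gene_set = scoring.select_top_genes(
                annotation[result.term_id].genes, ranked, dev_z,
                k=int(cfg["set_size"]), coexpr_min=float(cfg["coexpr_min"]),
                name=result.term_id,
            )
            break
        except ValueError:
            continue
    if gene_set is None:
        raise RuntimeError("stage build_set failed: no enriched term yields a full set")
    write_gmt(
        simulate.GeneAnnotation(
            {gene_set.name: simulate.AnnotationTerm(gene_set.name, "signature", frozenset(gene_set.genes))}
        ),
        outdir / "gene_set.gmt",
    )
    save("gene_set.gmt", outdir / "gene_set.gmt")
    null = scoring.empirical_null_pvalue(
        phen_z, phenotype, gene_set, n_draws=int(cfg["n_draws"]), seed=int(seeds[2])
    )
    (outdir / "null.json").write_text(json.dumps(null.__dict__, indent=1, sort_keys=True))
    save("null.json", outdir / "null.json")
    manifest["metrics"]["set_observed_r"] = null.observed_r
    manifest["metrics"]["set_empirical_p"] = null.p_empirical
    record("build_set", term=gene_set.name, genes=list(gene_set.genes),
           observed_r=null.observed_r, empirical_p=null.p_empirical,
           n_draws=null.n_draws, seed=int(seeds[2]))

    # -- loose filter + consensus clustering ---------------------------
    filtered = clustering.loose_coexpression_filter(dev_expr, dev_samples)
    (outdir / "filtered_genes.txt").write_text("\n".join(filtered) + "\n")
    save("filtered_genes.txt", outdir / "filtered_genes.txt")
    record("loose_filter", n_passed=len(filtered), n_total=dev_expr.shape[0])
    cluster_genes = filtered if cfg["cluster_input"] == "filtered" else list(dev_z.index)
    analyses = clustering.run_kmeans_analyses(
        dev_z, dev_samples, genes=cluster_genes,
        ks=tuple(cfg["ks"]), windows=tuple(cfg["windows"]), seed=int(seeds[3]),
    )
    labels_frame = pd.DataFrame(
        {a.analysis_id: a.labels for a in analyses}
    ).sort_index()
    labels_frame.to_csv(outdir / "clusters.tsv", sep="\t")
    save("clusters.tsv", outdir / "clusters.tsv")
    annotated = clustering.annotate_analyses(
        analyses, annotation, q_threshold=float(cfg["enrichment"]["q_threshold"])
    )
    record("cluster", analyses=[a.analysis_id for a in analyses],
           n_clustered=len(analyses[0].labels), seed=int(seeds[3]))

    # recovery vs truth on planted genes present in the clustered universe
    truth_labels = dev_truth.celltype_of_gene
    aris = []
    for a in analyses:
        planted = [g for g in a.labels.index if g in truth_labels]
        if len(planted) >= 2:
            aris.append(
                adjusted_rand_score(
                    [truth_labels[g] for g in planted],
                    [int(a.labels.loc[g]) for g in planted],
                )
            )
    manifest["metrics"]["median_ari"] = float(np.median(aris)) if aris else float("nan")

    ecm_term = "TERM:ecm"
    consensus: list[str] = []
    if ecm_term in annotation:
        consensus = clustering.consensus_genes(
            annotated, ecm_term, annotation[ecm_term].genes, min_support=int(cfg["min_support"])
        )
        (outdir / "consensus_ecm.txt").write_text("\n".join(consensus) + "\n")
        save("consensus_ecm.txt", outdir / "consensus_ecm.txt")
    record("consensus", term=ecm_term, n_genes=len(consensus))

    if cfg["markers"] == "synthetic":
        markers = simulate.synthetic_marker_table(dev_truth)
    elif cfg["markers"] == "builtin":
        markers = load_builtin_markers()
    else:
        markers = read_markers(cfg["markers"])
    attributions = clustering.attribute_markers(annotated, markers, min_support=int(cfg["min_support"]))
    attr_frame = pd.DataFrame(
        [
            {
                "marker": at.marker, "cell_type": at.cell_type,
                "attributed": ";".join(at.attributed_terms),
                "support": ";".join(f"{t}:{s}" for t, s in sorted(at.support.items())),
                "present": at.present,
            }
            for at in attributions
        ]
    )
    attr_frame.to_csv(outdir / "attributions.tsv", sep="\t", index=False)
    save("attributions.tsv", outdir / "attributions.tsv")
    if cfg["markers"] == "synthetic":
        present = [a for a in attributions if a.present]
        correct = sum(1 for a in present if f"TERM:{a.cell_type}" in a.attributed_terms)
        manifest["metrics"]["marker_attribution_accuracy"] = (
            correct / len(present) if present else float("nan")
        )
    record("attribute", n_markers=len(attributions),
           n_present=sum(a.present for a in attributions))

    # -- contrasts -----------------------------------------------------
    contrasts = []
    ecm_genes = dev_truth.signature_genes("ecm")[: int(cfg["set_size"])]
    if len(ecm_genes) == int(cfg["set_size"]):
        ecm_set = scoring.GeneSet("ecm_signature", tuple(ecm_genes))
        for stage in ("12mo", "25mo"):
            res = genotype_set_test(dev_z, ecm_set, dev_samples, stage)
            contrasts.append(res.__dict__)
    res = treatment_set_test(phen_z, gene_set, phen_samples)
    contrasts.append(res.__dict__)
    pd.DataFrame(contrasts).to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
    save("contrasts.tsv", outdir / "contrasts.tsv")
    record("contrasts", n=len(contrasts))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    (outdir / "report.txt").write_text(report(manifest))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable summary of a completed (or partial) run."""
    lines = ["growth-signature pipeline report", "=" * 34]
    stages = {s["stage"]: s for s in manifest.get("stages", [])}
    expected = (
        "synthesize", "rank", "enrich", "build_set", "loose_filter",
        "cluster", "consensus", "attribute", "contrasts",
    )
    missing = [s for s in expected if s not in stages]
    if missing:
        lines.append(f"PARTIAL RUN — missing stages: {', '.join(missing)}")
    if "build_set" in stages:
        s = stages["build_set"]
        lines.append(f"signature ({s['term']}): {', '.join(s['genes'])}")
        lines.append(
            f"  phenotype correlation r = {s['observed_r']:.3f}, "
            f"empirical p = {s['empirical_p']:.2e} ({s['n_draws']} draws)"
        )
    if "loose_filter" in stages:
        s = stages["loose_filter"]
        lines.append(f"loose co-expression filter: {s['n_passed']} / {s['n_total']} genes")
    if "consensus" in stages:
        s = stages["consensus"]
        lines.append(f"consensus list for {s['term']}: {s['n_genes']} genes")
    if "attribute" in stages:
        s = stages["attribute"]
        lines.append(f"markers: {s['n_present']} / {s['n_markers']} present in clustered universe")
    metrics = manifest.get("metrics", {})
    if metrics:
        lines.append("recovery vs planted truth:")
        for key in sorted(metrics):
            value = metrics[key]
            lines.append(f"  {key} = {value:.4g}" if isinstance(value, float) else f"  {key} = {value}")
    return "\n".join(lines) + "\n"


def load_cohort(expr_path: str | Path, samples_path: str | Path):
    """Load an expression matrix + sample table pair from disk."""
    return read_expression(expr_path), read_samples(samples_path)
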