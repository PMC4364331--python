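"""Synthetic cohorts with planted ground truth.

Two cohorts are generated from a latent cell-type mixture model on the log2
scale:

* a *phenotype cohort* of 48 steers (two sites x hormonal growth promotant
  treatment vs control), where each sample is a Dirichlet mixture of cell
  types, each cell type owns a block of signature genes, and the growth
  phenotype (ADG/kg liveweight, 1/day) is an affine function of the latent
  *proliferating* cell fraction plus noise — so phenotype–expression coupling
  flows through the mixture, never through any single gene;

* a *development cohort* of two genotypes (high-muscling vs high-marbling)
  sampled at ten stages from 60 days post conception to 30 months, where each
  cell type follows a smooth piecewise-linear stage profile and
  genotype-specific log2 offsets can be planted at chosen stages (the default
  plants the extracellular-matrix program higher in the high-marbling
  genotype at 12 and 25 months, the divergence the downstream filter looks
  for).

Noise is additive Gaussian on the log2 scale, matching microarray convention.
Every random choice flows from the single integer seed of the configuration,
so equal configurations produce byte-identical cohorts, and all planted
structure is recorded in :class:`SyntheticTruth` for parameter-recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    STAGE_AGE_DAYS,
    STAGE_ORDER,
    ExpressionMatrix,
    GeneAnnotation,
    AnnotationTerm,
    MarkerTable,
    SampleTable,
)

#: Default planted programs, one per cell type.  "proliferating" is the
#: growth program coupled to the phenotype; "ecm" declines after birth.
DEFAULT_CELLTYPES = (
    "proliferating", "ecm", "angiogenesis", "adipogenic", "satellite", "contractile",
)

DEFAULT_STAGES: tuple[tuple[str, int], ...] = tuple(
    (s, STAGE_AGE_DAYS[s]) for s in STAGE_ORDER
)

#: Canonical declining profile for the ECM program: high prenatally, peaking
#: at birth, decaying through the postnatal stages.
_ECM_PROFILE = (0.85, 0.9, 0.95, 1.0, 0.75, 0.55, 0.4, 0.3, 0.25, 0.2)

GENOTYPES = ("highmuscle", "highmarble")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-mixture simulator.

    Parameters
    ----------
    n_genes
        Total genes; signature blocks are carved from the front, the rest are
        background genes with no planted structure.
    n_celltypes, signatures_per_celltype
        Number of planted programs and signature genes per program.
    phenotype_effect
        Target Pearson correlation (in expectation) between each growth-
        program signature gene and the ADG/kg phenotype, in [0, 1).
    noise_sd
        SD of the additive Gaussian noise, log2 units.
    dirichlet_concentration
        Concentration per cell type for the latent fractions; default 2.0
        each (moderately variable, no dominant type).
    amplitude
        log2 shift per unit latent fraction for signature genes in the
        phenotype cohort.  8.0 by default: fractions move by roughly +-0.1,
        so signature genes swing by roughly +-0.8 log2.
    profile_amplitude
        log2 swing of the stage profiles in the development cohort.
    stages
        Ordered (label, age_days) pairs; ages strictly increasing.
    stage_profiles
        Optional per-cell-type profile (sequence over stages, values in
        [0, 1]) overriding the generated smooth profiles.
    genotype_offsets
        Map (celltype, stage) -> log2 shift applied to the high-marbling
        genotype's signature genes at that stage.
    treatment_effect
        log2 shift on growth-program signature genes in treated samples of
        the phenotype cohort.
    n_animals_per_group
        Animals per stage per genotype in the development cohort.
    n_phenotype_samples
        Phenotype-cohort size (divided over a 2x2 site x treatment layout).
    """

    n_genes: int = 2000
    n_celltypes: int = 6
    signatures_per_celltype: int = 50
    phenotype_effect: float = 0.7
    noise_sd: float = 0.3
    dirichlet_concentration: tuple[float, ...] | None = None
    amplitude: float = 8.0
    profile_amplitude: float = 2.0
    stages: tuple[tuple[str, int], ...] = DEFAULT_STAGES
    stage_profiles: Mapping[str, Sequence[float]] | None = None
    genotype_offsets: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("ecm", "12mo"): 0.5, ("ecm", "25mo"): 0.5}
    )
    treatment_effect: float = 0.0
    n_animals_per_group: int = 4
    n_phenotype_samples: int = 48
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_celltypes < 1 or self.signatures_per_celltype <= 0:
            raise ValueError("counts must be positive (n_celltypes >= 1)")
        if self.n_celltypes * self.signatures_per_celltype > self.n_genes:
            raise ValueError("signature genes exceed n_genes")
        if not (0.0 <= self.phenotype_effect <= 0.999):
            raise ValueError("phenotype_effect must be in [0, 0.999]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_animals_per_group < 1 or self.n_phenotype_samples < 4:
            raise ValueError("cohort sizes too small")
        ages = [age for _, age in self.stages]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("stage ages must be strictly increasing")
        if self.dirichlet_concentration is not None:
            if len(self.dirichlet_concentration) != self.n_celltypes:
                raise ValueError("dirichlet_concentration length != n_celltypes")
            if any(a <= 0 for a in self.dirichlet_concentration):
                raise ValueError("dirichlet_concentration must be positive")
        if self.stage_profiles is not None:
            for ct, prof in self.stage_profiles.items():
                if len(prof) != len(self.stages):
                    raise ValueError(f"stage profile for {ct!r} has wrong length")

    # -- derived layout -------------------------------------------------

    @property
    def celltypes(self) -> tuple[str, ...]:
        names = list(DEFAULT_CELLTYPES[: self.n_celltypes])
        for i in range(len(names), self.n_celltypes):
            names.append(f"program{i}")
        return tuple(names)

    @property
    def alpha(self) -> np.ndarray:
        if self.dirichlet_concentration is not None:
            return np.asarray(self.dirichlet_concentration, dtype=float)
        return np.full(self.n_celltypes, 2.0)

    def gene_ids(self) -> tuple[list[str], dict[str, str]]:
        """All gene IDs plus the gene -> cell-type map for signature genes."""
        genes: list[str] = []
        celltype_of: dict[str, str] = {}
        for ct in self.celltypes:
            for j in range(self.signatures_per_celltype):
                g = f"{ct.upper()}_{j:04d}"
                genes.append(g)
                celltype_of[g] = ct
        n_bg = self.n_genes - len(genes)
        genes.extend(f"BG_{j:05d}" for j in range(n_bg))
        return genes, celltype_of


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic cohort."""

    celltype_of_gene: dict[str, str]
    true_fractions: pd.DataFrame | None  # samples x celltypes, rows sum to 1
    true_profiles: pd.DataFrame | None  # samples x celltypes latent profile values
    true_phenotype_corr: dict[str, float]
    seed: int

    def signature_genes(self, celltype: str) -> list[str]:
        return sorted(g for g, ct in self.celltype_of_gene.items() if ct == celltype)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "celltype_of_gene": self.celltype_of_gene,
            "true_fractions": None
            if self.true_fractions is None
            else self.true_fractions.to_dict(orient="index"),
            "true_profiles": None
            if self.true_profiles is None
            else self.true_profiles.to_dict(orient="index"),
            "true_phenotype_corr": self.true_phenotype_corr,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _dirichlet_var(alpha: np.ndarray, i: int = 0) -> float:
    a0 = alpha.sum()
    return float(alpha[i] * (a0 - alpha[i]) / (a0**2 * (a0 + 1)))


def generate_phenotype_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth]:
    """Simulate the 48-steer phenotype cohort.

    Expression of a signature gene is baseline + amplitude * (fraction of its
    cell type - its mean) + noise; ADG/kg is an affine map of the
    proliferating fraction plus Gaussian noise scaled so that growth-program
    genes reach ``phenotype_effect`` correlation with the phenotype in
    expectation.  Raises if the target correlation is unreachable at the
    configured noise level.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_phenotype_samples
    genes, celltype_of = config.gene_ids()
    celltypes = config.celltypes
    alpha = config.alpha

    if config.n_celltypes == 1:
        fractions = np.ones((n, 1))  # degenerate mixture: one cell type
    else:
        fractions = rng.dirichlet(alpha, size=n)  # n x K, rows sum to 1
    baselines = rng.uniform(6.0, 12.0, size=config.n_genes)

    expr = np.tile(baselines[:, None], (1, n))
    ct_index = {ct: i for i, ct in enumerate(celltypes)}
    frac_mean = alpha / alpha.sum()
    for gi, g in enumerate(genes):
        ct = celltype_of.get(g)
        if ct is not None:
            expr[gi] += config.amplitude * (fractions[:, ct_index[ct]] - frac_mean[ct_index[ct]])
    if config.noise_sd > 0:
        expr += rng.normal(0.0, config.noise_sd, size=expr.shape)

    # 2x2 site x treatment layout
    sites = np.array(["siteA", "siteB"])[(np.arange(n) // (n // 2)) % 2]
    treatments = np.array(["control", "HGP"])[(np.arange(n) % (n // 2) // (n // 4)) % 2]
    if config.treatment_effect != 0.0:
        treated = treatments == "HGP"
        growth = celltypes[0]
        rows = [gi for gi, g in enumerate(genes) if celltype_of.get(g) == growth]
        expr[np.ix_(rows, np.where(treated)[0])] += config.treatment_effect

    # phenotype coupled to the proliferating fraction
    rho = config.phenotype_effect
    f0 = fractions[:, 0]
    var_f0 = _dirichlet_var(alpha, 0)
    if rho > 0:
        if var_f0 == 0:
            raise ValueError("cannot couple phenotype: proliferating fraction is constant")
        sd_sig = config.amplitude * np.sqrt(var_f0)
        rho_x = sd_sig / np.hypot(sd_sig, config.noise_sd)
        rho_y = rho / rho_x
        if rho_y >= 1.0:
            raise ValueError(
                f"phenotype_effect={rho} unreachable: signature genes correlate with "
                f"the latent fraction at only {rho_x:.3f} under noise_sd={config.noise_sd}"
            )
        sd_y_noise = np.sqrt(var_f0) * np.sqrt(1.0 / rho_y**2 - 1.0)
        y_latent = f0 + rng.normal(0.0, sd_y_noise, size=n)
    else:
        y_latent = rng.normal(0.0, 1.0, size=n)
    # realistic scale: ~0.002/day center, matching steers gaining ~1 kg/day at ~450 kg
    y_std = (y_latent - y_latent.mean()) / y_latent.std(ddof=1)
    adg_per_kg = 0.002 + 0.0004 * y_std

    sample_ids = [f"BR{i + 1:03d}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids)
    )
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort": "phenotype",
                "genotype": "brahman",
                "stage": "20mo",
                "age_days": STAGE_AGE_DAYS["20mo"],
                "treatment": treatments,
                "site": sites,
                "adg_per_kg": adg_per_kg,
                "imf_pct": np.round(rng.uniform(2.0, 9.0, size=n), 2),
            }
        )
    )
    growth = celltypes[0]
    truth = SyntheticTruth(
        celltype_of_gene=celltype_of,
        true_fractions=pd.DataFrame(fractions, index=sample_ids, columns=list(celltypes)),
        true_profiles=None,
        true_phenotype_corr={g: (rho if ct == growth else 0.0) for g, ct in celltype_of.items()},
        seed=config.seed,
    )
    return matrix, table, truth


def _stage_profile(
    rng: np.random.Generator,
    n_stages: int,
    existing: list[np.ndarray] | None = None,
    windows: tuple[np.ndarray, ...] = (),
    max_corr: float = 0.5,
    min_range: float = 0.5,
    max_tries: int = 500,
) -> np.ndarray:
    """Smooth random profile in [0, 1]: piecewise-linear through 5 anchors.

    Candidate profiles are drawn in a batch; among those keeping a dynamic
    range of at least ``min_range`` inside every analysis window (the full
    course and the postnatal stages), the draw least correlated with the
    previously drawn profiles is kept.  Planted programs are meant to be
    *distinct* cell-type dynamics, not accidental near-copies or window-flat
    curves; without this greedy separation, recovery failures would measure
    the generator's degeneracy, not the pipeline.
    """
    n_anchors = min(5, n_stages)
    anchor_pos = np.linspace(0, n_stages - 1, n_anchors)
    grid = np.arange(n_stages)
    if not windows:
        windows = (grid,)
    anchors = rng.uniform(0.0, 1.0, size=(max_tries, n_anchors))
    candidates = np.stack([np.interp(grid, anchor_pos, a) for a in anchors])
    worst = np.zeros(max_tries)
    valid = np.ones(max_tries, dtype=bool)
    for w in windows:
        sub = candidates[:, w]
        valid &= sub.max(axis=1) - sub.min(axis=1) >= min_range
        if existing:
            sc = sub - sub.mean(axis=1, keepdims=True)
            norm = np.linalg.norm(sc, axis=1)
            for other in existing:
                oc = other[w] - other[w].mean()
                onorm = np.linalg.norm(oc)
                if onorm == 0:
                    continue
                with np.errstate(invalid="ignore"):
                    corr = np.abs(sc @ oc) / (norm * onorm)
                worst = np.maximum(worst, np.nan_to_num(corr, nan=1.0))
    if valid.any():  # the in-range draw least correlated with existing programs
        worst[~valid] = np.inf
        return candidates[int(np.argmin(worst))]
    return candidates[0]


def generate_development_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth]:
    """Simulate the two-genotype developmental time course.

    Each cell type follows a smooth stage profile (the ECM program defaults
    to the canonical post-birth decline); ``genotype_offsets`` shift the
    high-marbling genotype's signature genes at the named stages.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes, celltype_of = config.gene_ids()
    celltypes = config.celltypes
    stage_labels = [s for s, _ in config.stages]
    n_stages = len(stage_labels)

    postnatal = np.array(
        [i for i, (_, age) in enumerate(config.stages) if age > 0], dtype=int
    )
    windows = (np.arange(n_stages),)
    if len(postnatal) >= 2:
        windows = (np.arange(n_stages), postnatal)
    profiles = np.empty((len(celltypes), n_stages))
    drawn: list[np.ndarray] = []
    for ci, ct in enumerate(celltypes):
        if config.stage_profiles is not None and ct in config.stage_profiles:
            profiles[ci] = np.asarray(config.stage_profiles[ct], dtype=float)
        elif ct == "ecm" and n_stages == len(_ECM_PROFILE):
            profiles[ci] = _ECM_PROFILE
        else:
            profiles[ci] = _stage_profile(rng, n_stages, existing=drawn, windows=windows)
        drawn.append(profiles[ci])

    baselines = rng.uniform(6.0, 12.0, size=config.n_genes)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    ct_index = {ct: i for i, ct in enumerate(celltypes)}
    stage_idx: list[int] = []
    marble: list[bool] = []
    for si, (stage, age) in enumerate(config.stages):
        for geno in GENOTYPES:
            for a in range(config.n_animals_per_group):
                sid = f"{'PH' if geno == 'highmuscle' else 'WH'}_{stage}_{a + 1}"
                sample_ids.append(sid)
                stage_idx.append(si)
                marble.append(geno == "highmarble")
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cohort": "development",
                        "genotype": geno,
                        "stage": stage,
                        "age_days": age,
                        "treatment": "none",
                        "site": "station",
                        "adg_per_kg": np.nan,
                        "imf_pct": np.nan,
                    }
                )
    stage_idx = np.asarray(stage_idx)
    marble = np.asarray(marble)

    # gene -> program row (-1 for background) and per-(program, stage) offsets
    ct_of_gene = np.array([ct_index.get(celltype_of.get(g, ""), -1) for g in genes])
    offsets = np.zeros((len(celltypes), n_stages))
    for (ct, stage), shift in config.genotype_offsets.items():
        if ct in ct_index and stage in stage_labels:
            offsets[ct_index[ct], stage_labels.index(stage)] = shift

    expr = np.tile(baselines[:, None], (1, len(sample_ids)))
    sig = ct_of_gene >= 0
    expr[sig] += config.profile_amplitude * profiles[np.ix_(ct_of_gene[sig], stage_idx)]
    expr[sig] += offsets[np.ix_(ct_of_gene[sig], stage_idx)] * marble[None, :]
    latent_rows = [profiles[:, si] for si in stage_idx]
    if config.noise_sd > 0:
        expr += rng.normal(0.0, config.noise_sd, size=expr.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids)
    )
    table = SampleTable(pd.DataFrame(meta_rows))
    truth = SyntheticTruth(
        celltype_of_gene=celltype_of,
        true_fractions=None,
        true_profiles=pd.DataFrame(
            np.vstack(latent_rows), index=sample_ids, columns=list(celltypes)
        ),
        true_phenotype_corr={},
        seed=config.seed,
    )
    return matrix, table, truth


def generate_annotation(
    truth: SyntheticTruth,
    n_background_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 50),
    universe: Sequence[str] | None = None,
    seed: int | None = None,
) -> GeneAnnotation:
    """GO-like annotation: one term per planted program holding exactly its
    signature genes, plus random terms drawn from the background genes.

    ``universe`` defaults to every gene named in the truth's cell-type map
    plus background genes cannot be inferred from truth alone, so pass the
    cohort's gene list for background terms to be drawn.
    """
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid term_size_range")
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 3])
    )
    terms: dict[str, AnnotationTerm] = {}
    planted = set(truth.celltype_of_gene)
    for ct in sorted(set(truth.celltype_of_gene.values())):
        members = frozenset(truth.signature_genes(ct))
        terms[f"TERM:{ct}"] = AnnotationTerm(f"TERM:{ct}", f"{ct} program", members)
    if n_background_terms > 0:
        if universe is None:
            raise ValueError("universe required to draw background terms")
        background = sorted(set(universe) - planted)
        if hi > len(background):
            raise ValueError(
                f"term_size_range upper bound {hi} exceeds the {len(background)} background genes"
            )
        for j in range(n_background_terms):
            size = int(rng.integers(lo, hi + 1))
            members = frozenset(rng.choice(background, size=size, replace=False))
            tid = f"BG:{j:04d}"
            terms[tid] = AnnotationTerm(tid, f"background term {j}", members)
    return GeneAnnotation(terms)


def bump_stage_profiles(
    n_celltypes: int, n_stages: int = len(DEFAULT_STAGES), width: float = 2.5
) -> dict[str, np.ndarray]:
    """Deterministic well-separated profiles: program i peaks at stage i.

    Each cell type's activity is a triangular bump of half-width ``width``
    stages centred at evenly spaced peaks — a stylized version of cell
    populations waxing and waning at different developmental times.  Useful
    as an explicit ``stage_profiles`` override when a benchmark needs a
    known number of clearly distinct programs.
    """
    names = SimulationConfig(n_celltypes=n_celltypes).celltypes
    grid = np.arange(n_stages)
    return {
        name: np.clip(1.0 - np.abs(grid - i * (n_stages - 1) / max(1, n_celltypes - 1)) / width, 0.0, 1.0)
        for i, name in enumerate(names)
    }


def synthetic_marker_table(truth: SyntheticTruth, per_type: int = 5) -> MarkerTable:
    """Marker table naming the first ``per_type`` signature genes of each
    planted program as positive markers of that program (synthetic stand-in
    for a published marker table, with known ground truth)."""
    rows = []
    for ct in sorted(set(truth.celltype_of_gene.values())):
        for g in truth.signature_genes(ct)[:per_type]:
            rows.append({"gene": g, "cell_type": ct, "sign": "+", "source": "synthetic"})
    return MarkerTable(pd.DataFrame(rows))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same configuration, different seed."""
    return replace(config, seed=seed)
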