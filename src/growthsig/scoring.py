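"""Five-gene signature construction, z-score set scoring, and the
random-gene-set empirical null.

A candidate signature is built by walking a term's members in phenotype-
correlation order and keeping the first k genes that are co-expressed through
development (correlation with the running set-mean profile above a
threshold).  The signature's per-sample score is the arithmetic mean of its
members' z-scores, and the significance of its correlation with the
phenotype is calibrated against sets of the same size drawn uniformly from
the full gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .ranking import RankedGeneList, pearson_r

logger = logging.getLogger(__name__)


def zscore_standardize(
    matrix: ExpressionMatrix,
    universe_samples=None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-gene standardization to mean 0, SD 1 over ``universe_samples``.

    The sample SD (``ddof=1``) is the default; pass ``ddof=0`` for the
    population convention.  Constant genes are excluded with a warning —
    their z-score is undefined.
    """
    data = matrix.data if universe_samples is None else matrix.data.loc[:, list(universe_samples)]
    if data.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    values = data.to_numpy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    keep = sd[:, 0] > 0
    if (~keep).any():
        logger.warning("excluded %d constant genes from z-standardization", int((~keep).sum()))
    z = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=data.index[keep], columns=data.columns)


@dataclass(frozen=True)
class GeneSet:
    """A small named signature (typically 5 genes)."""

    name: str
    genes: tuple[str, ...]
    source_term: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set members must be unique")
        if not self.genes:
            raise ValueError("gene set cannot be empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetScore:
    """Per-sample average z-score of a gene set's members."""

    scores: pd.Series
    n_genes: int
    set_name: str = ""


def set_score(z: pd.DataFrame, genes: GeneSet) -> GeneSetScore:
    """Sample-wise mean of the member z-score rows."""
    missing = [g for g in genes.genes if g not in z.index]
    if missing:
        raise KeyError(f"gene set members missing from z-matrix: {missing}")
    scores = z.loc[list(genes.genes)].mean(axis=0)
    scores.name = genes.name or "set_score"
    return GeneSetScore(scores=scores, n_genes=len(genes), set_name=genes.name)


def select_top_genes(
    term_genes,
    ranked: RankedGeneList,
    dev_z: pd.DataFrame,
    k: int = 5,
    coexpr_min: float = 0.6,
    name: str = "",
) -> GeneSet:
    """Pick the top-k term members that are co-expressed through development.

    Walk the term's members in ranked (phenotype-correlation) order.  The
    first gene is always accepted; each later gene is accepted when the
    Pearson correlation of its developmental profile with the running mean
    profile of the accepted genes reaches ``coexpr_min``.  The walk stops at
    ``k`` members and raises if the term cannot supply them; every
    accept/reject decision is recorded in the set's provenance.
    """
    members = set(term_genes)
    candidates = [g for g in ranked.genes if g in members and g in dev_z.index]
    if len(candidates) < k:
        raise ValueError(
            f"term has only {len(candidates)} rankable members with development "
            f"profiles; {k} required"
        )
    accepted: list[str] = []
    provenance: list[str] = []
    running: np.ndarray | None = None
    for g in candidates:
        if len(accepted) == k:
            break
        profile = dev_z.loc[g].to_numpy()
        if running is None:
            accepted.append(g)
            provenance.append(f"accept {g} (rank {ranked.rank_of(g)}, seed gene)")
            running = profile.copy()
            continue
        r = pearson_r(profile, running / len(accepted))
        if r >= coexpr_min:
            accepted.append(g)
            running += profile
            provenance.append(f"accept {g} (rank {ranked.rank_of(g)}, coexpr r={r:.3f})")
        else:
            provenance.append(f"reject {g} (rank {ranked.rank_of(g)}, coexpr r={r:.3f})")
    if len(accepted) < k:
        raise ValueError(
            f"only {len(accepted)} of {k} members passed coexpr_min={coexpr_min}; "
            f"walk: {provenance}"
        )
    return GeneSet(
        name=name or f"top{k}", genes=tuple(accepted),
        source_term=name, provenance=tuple(provenance),
    )


@dataclass
class EmpiricalNullResult:
    """Random-gene-set calibration of a signature's phenotype correlation."""

    observed_r: float
    n_draws: int
    n_exceeding: int
    p_empirical: float
    set_size: int
    seed: int


def empirical_null_pvalue(
    z: pd.DataFrame,
    phenotype: pd.Series,
    observed_set: GeneSet,
    n_draws: int = 100_000,
    seed: int = 0,
) -> EmpiricalNullResult:
    """Compare a signature's phenotype correlation with random same-size sets.

    ``n_draws`` sets of the same size are sampled uniformly without
    replacement from the full gene universe of ``z``; each is scored by the
    member-mean z and correlated with the phenotype.  The one-sided p-value
    uses the standard permutation estimator p = (#{r_draw > r_obs} + 1) /
    (n_draws + 1) with strict exceedance, so p is never zero.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    k = len(observed_set)
    n_genes = z.shape[0]
    if k > n_genes:
        raise ValueError(f"set size {k} exceeds the {n_genes}-gene universe")
    y = phenotype.reindex(z.columns).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some samples")

    rng = np.random.default_rng(seed)
    Z = z.to_numpy()
    yc = y - y.mean()
    ynorm = np.sqrt(yc @ yc)

    def score_corr(index_rows: np.ndarray) -> np.ndarray:
        scores = Z[index_rows].mean(axis=1)
        sc = scores - scores.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", sc, sc))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (sc @ yc) / (norms * ynorm)

    position = {g: i for i, g in enumerate(z.index)}
    obs_idx = np.sort([position[g] for g in observed_set.genes])
    observed_r = float(score_corr(obs_idx[None, :])[0])
    if not np.isfinite(observed_r):
        raise ValueError("observed set score is constant; correlation undefined")

    n_exceeding = 0
    chunk = 20_000
    for start in range(0, n_draws, chunk):
        m = min(chunk, n_draws - start)
        idx = rng.integers(0, n_genes, size=(m, k))
        # resample rows containing a duplicate gene (rare for k << n_genes)
        while True:
            idx = np.sort(idx, axis=1)
            bad = (np.diff(idx, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n_genes, size=(int(bad.sum()), k))
        # the observed set rides along as row 0 of every batch: sorted
        # indices and a shared BLAS call give bit-equal correlations for
        # identical sets, so strict exceedance is exact, never an artifact
        # of float summation order
        r = score_corr(np.vstack([obs_idx[None, :], idx]))
        n_exceeding += int(np.nansum(r[1:] > r[0]))
    return EmpiricalNullResult(
        observed_r=observed_r,
        n_draws=n_draws,
        n_exceeding=n_exceeding,
        p_empirical=(n_exceeding + 1) / (n_draws + 1),
        set_size=k,
        seed=seed,
    )
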