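"""Significance machinery for genotype and treatment contrasts.

Set-level contrasts use Welch's two-sided unequal-variance t-test on the
pooled member z-scores (k genes x animals per group).  Single genes are
instead judged against the empirical distribution of between-genotype mean
differences across *all* genes at the same time point: a gene is called
significant when its difference falls outside the central 95% interval of
that all-gene distribution.  A one-sample Kolmogorov–Smirnov normality check
is available as a reported diagnostic (it does not gate any test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleTable
from .scoring import GeneSet, set_score


@dataclass
class ContrastResult:
    """Outcome of a two-group contrast."""

    label: str
    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    df: float = float("nan")


def welch_ttest(a, b, label: str = "") -> ContrastResult:
    """Two-sided Welch t-test (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in contrast groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return ContrastResult(
        label=label, statistic=t, pvalue=p,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=int(a.size), n_b=int(b.size),
        df=float(getattr(res, "df", np.nan)),
    )


def _pooled_member_values(z: pd.DataFrame, gene_set: GeneSet, sample_ids) -> np.ndarray:
    ids = [s for s in sample_ids if s in z.columns]
    missing = [g for g in gene_set.genes if g not in z.index]
    if missing:
        raise KeyError(f"set members missing from z-matrix: {missing}")
    return z.loc[list(gene_set.genes), ids].to_numpy().ravel()


def genotype_set_test(
    z: pd.DataFrame,
    gene_set: GeneSet,
    samples: SampleTable,
    stage: str,
    genotypes: tuple[str, str] = ("highmuscle", "highmarble"),
) -> ContrastResult:
    """Welch t-test of a gene set between genotypes at one stage.

    Pools the member z-scores (k genes x animals) of each genotype, per the
    convention that a 5-gene set contributes 5 x n values per group.
    """
    a_ids = samples.samples_where(stage=stage, genotype=genotypes[0])
    b_ids = samples.samples_where(stage=stage, genotype=genotypes[1])
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError(f"stage {stage!r} lacks samples for both genotypes")
    a = _pooled_member_values(z, gene_set, a_ids)
    b = _pooled_member_values(z, gene_set, b_ids)
    return welch_ttest(a, b, label=f"{genotypes[0]} vs {genotypes[1]} @ {stage}")


def treatment_set_test(
    z: pd.DataFrame,
    gene_set: GeneSet,
    samples: SampleTable,
    treatments: tuple[str, str] = ("HGP", "control"),
    mode: str = "pooled",
) -> ContrastResult:
    """Welch t-test of a gene set between treatment groups.

    ``mode='pooled'`` compares the pooled member z-scores; ``mode='score'``
    compares the per-sample set scores instead.
    """
    a_ids = samples.samples_where(treatment=treatments[0])
    b_ids = samples.samples_where(treatment=treatments[1])
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError(f"cohort lacks both treatment groups {treatments}")
    if mode == "pooled":
        a = _pooled_member_values(z, gene_set, a_ids)
        b = _pooled_member_values(z, gene_set, b_ids)
    elif mode == "score":
        scores = set_score(z, gene_set).scores
        a = scores.loc[[s for s in a_ids if s in scores.index]].to_numpy()
        b = scores.loc[[s for s in b_ids if s in scores.index]].to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return welch_ttest(a, b, label=f"{treatments[0]} vs {treatments[1]}")


@dataclass
class IntervalTestResult:
    """Single-gene test against the all-gene empirical difference interval."""

    gene: str
    stage: str
    difference: float
    percentile: float
    significant: bool
    coverage: float
    lower: float
    upper: float
    n_genes: int


def single_gene_interval_test(
    dev_matrix: ExpressionMatrix,
    samples: SampleTable,
    gene: str,
    stage: str,
    coverage: float = 0.95,
    genotypes: tuple[str, str] = ("highmuscle", "highmarble"),
    min_genes: int = 1000,
) -> IntervalTestResult:
    """Flag a gene whose between-genotype difference is extreme among all genes.

    The between-genotype difference of stage means is computed for every gene;
    the query gene is significant when its difference lies outside the
    central ``coverage`` interval (linear-interpolated empirical quantiles) of
    that distribution.  The gene's mean-rank percentile is returned.
    """
    if dev_matrix.shape[0] < min_genes:
        raise ValueError(
            f"only {dev_matrix.shape[0]} genes; >= {min_genes} needed for a stable interval"
        )
    if gene not in dev_matrix.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    a_ids = list(samples.samples_where(stage=stage, genotype=genotypes[0]))
    b_ids = list(samples.samples_where(stage=stage, genotype=genotypes[1]))
    if not a_ids or not b_ids:
        raise ValueError(f"stage {stage!r} lacks samples for both genotypes")
    data = dev_matrix.data
    diffs = data[a_ids].mean(axis=1) - data[b_ids].mean(axis=1)
    d = float(diffs.loc[gene])
    alpha = 1.0 - coverage
    lower, upper = np.quantile(diffs.to_numpy(), [alpha / 2, 1 - alpha / 2])
    # mean-rank percentile: 50 for the exact median
    values = diffs.to_numpy()
    percentile = 100.0 * ((values < d).sum() + 0.5 * (values == d).sum()) / values.size
    return IntervalTestResult(
        gene=gene, stage=stage, difference=d, percentile=float(percentile),
        significant=bool(d < lower or d > upper), coverage=coverage,
        lower=float(lower), upper=float(upper), n_genes=int(values.size),
    )


def normality_diagnostic(values, label: str = "") -> dict:
    """One-sample KS check against a normal with fitted mean/SD (diagnostic only)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.std(ddof=1) == 0:
        return {"label": label, "n": int(v.size), "ks_stat": float("nan"), "ks_p": float("nan")}
    res = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return {"label": label, "n": int(v.size), "ks_stat": float(res.statistic), "ks_p": float(res.pvalue)}
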