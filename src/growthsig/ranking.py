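"""Growth phenotype computation and correlation ranking of genes.

The phenotype is ADG/kg liveweight: average daily gain divided by the mean of
the liveweights at the start and end of the gain period, a size-normalized
growth rate in 1/day.  Every gene on the array is then ranked by the Pearson
correlation of its log2 expression with that phenotype across animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def compute_adg_per_kg(adg: float, weight_start: float, weight_end: float) -> float:
    """ADG/kg liveweight: daily gain (kg/day) over mean liveweight (kg).

    Returns a rate in 1/day.
    """
    if weight_start <= 0 or weight_end <= 0:
        raise ValueError("liveweights must be positive")
    return adg / ((weight_start + weight_end) / 2.0)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class RankedGeneList:
    """Genes ordered by correlation with a phenotype.

    ``table`` has columns ``gene``, ``r``, ``rank`` (1-based, descending r,
    ties broken by gene ID).  Constant-expression genes are excluded rather
    than assigned a rank (``n_excluded`` counts them).
    """

    table: pd.DataFrame
    phenotype: str
    n_samples: int
    n_excluded: int = 0

    def __post_init__(self):
        r = self.table["r"].to_numpy()
        if not np.isfinite(r).all():
            raise ValueError("non-finite correlation in ranked list")
        if (np.diff(r) > 1e-12).any():
            raise ValueError("ranked list not sorted by descending r")
        expected = np.arange(1, len(self.table) + 1)
        if not np.array_equal(self.table["rank"].to_numpy(), expected):
            raise ValueError("ranks must be consecutive from 1")

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def rank_of(self, gene: str) -> int:
        row = self.table.loc[self.table["gene"] == gene, "rank"]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in ranked list")
        return int(row.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, phenotype: str = "", n_samples: int = 0):
        return cls(pd.read_csv(path, sep="\t"), phenotype, n_samples)


def rank_by_correlation(
    matrix: ExpressionMatrix,
    phenotype: pd.Series,
    absolute: bool = False,
) -> RankedGeneList:
    """Rank every gene by Pearson correlation with the phenotype.

    ``phenotype`` must be indexed by the matrix's sample IDs.  Signed
    descending order is the default; ``absolute=True`` ranks by |r| instead.
    Constant genes are excluded (their correlation is undefined) and ties are
    broken by gene ID ascending for determinism.
    """
    y = phenotype.reindex(matrix.samples).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some samples")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to rank by correlation")
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y == 0:
        raise ValueError("phenotype is constant; ranking undefined")

    X = matrix.data.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    ss_x = np.einsum("ij,ij->i", Xc, Xc)
    keep = ss_x > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("excluded %d constant genes from ranking", n_excluded)
    r = (Xc[keep] @ yc) / np.sqrt(ss_x[keep] * ss_y)
    r = np.clip(r, -1.0, 1.0)

    frame = pd.DataFrame({"gene": matrix.genes[keep], "r": r})
    key = frame["r"].abs() if absolute else frame["r"]
    order = np.lexsort((frame["gene"].to_numpy(), -key.to_numpy()))
    frame = frame.iloc[order].reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return RankedGeneList(
        table=frame,
        phenotype=str(phenotype.name or "phenotype"),
        n_samples=int(matrix.shape[1]),
        n_excluded=n_excluded,
    )
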