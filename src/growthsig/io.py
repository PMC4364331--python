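"""Shared data containers and readers/writers for the formats the pipeline touches.

Expression matrices are tab-separated (genes in rows, samples in columns,
normalized log2 intensities), sample metadata is CSV, gene-set annotation is
GMT, and reports/ground truth are JSON.  All containers validate on
construction and readers fail loudly, naming the offending line or identifier:
the downstream statistics assume complete, finite, gene-level input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered developmental-stage vocabulary: three prenatal stages (days post
#: conception), birth, and six postnatal ages.  Ages are in days relative to
#: birth (cattle gestation ~281 d).
STAGE_ORDER: tuple[str, ...] = (
    "60dpc", "135dpc", "195dpc", "birth",
    "3mo", "7mo", "12mo", "20mo", "25mo", "30mo",
)

STAGE_AGE_DAYS: dict[str, int] = {
    "60dpc": -221, "135dpc": -146, "195dpc": -86, "birth": 0,
    "3mo": 90, "7mo": 210, "12mo": 365, "20mo": 600, "25mo": 750, "30mo": 900,
}

POSTNATAL_STAGES: tuple[str, ...] = tuple(
    s for s in STAGE_ORDER if STAGE_AGE_DAYS[s] >= 0 and s != "birth"
)

SAMPLE_COLUMNS = (
    "sample_id", "cohort", "genotype", "stage", "age_days",
    "treatment", "site", "adg_per_kg", "imf_pct",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ExpressionMatrix:
    """Genes x samples matrix of normalized log2 intensities.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene symbols
    and whose columns hold unique sample identifiers.  All values must be
    finite and at least two samples are required (correlations and z-scores
    are undefined otherwise).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        if data.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 samples")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = data.index[~np.isfinite(values).all(axis=1)][0]
            raise FormatError(f"non-finite expression value in gene {bad!r}")
        self.data = data.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)])

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header of sample IDs, first column gene IDs)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.split("\t")[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(columns) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(columns) + 1} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    frame = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=columns)
    return ExpressionMatrix(frame)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV with shortest round-tripping float representation."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(map(str, matrix.samples)) + "\n")
        values = matrix.data.to_numpy()
        for gene, row in zip(matrix.genes, values):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


class SampleTable:
    """Per-sample metadata: cohort, genotype, developmental stage, treatment,
    site and phenotypes (ADG/kg liveweight in 1/day, intramuscular fat %)."""

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in SAMPLE_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        if data["sample_id"].duplicated().any():
            dup = data.loc[data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        self.data = data.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def phenotype(self, name: str) -> pd.Series:
        """Phenotype values indexed by sample ID."""
        if name not in self.data.columns:
            raise KeyError(f"unknown phenotype {name!r}")
        return pd.Series(
            self.data[name].to_numpy(), index=self.sample_ids, name=name
        )

    def samples_where(self, **conditions) -> pd.Index:
        mask = pd.Series(True, index=self.data.index)
        for column, value in conditions.items():
            mask &= self.data[column] == value
        return pd.Index(self.data.loc[mask, "sample_id"])

    def stages_present(self) -> list[str]:
        present = set(self.data["stage"])
        return [s for s in STAGE_ORDER if s in present]


def read_samples(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path))


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    genes: frozenset[str]


class GeneAnnotation:
    """Mapping from term ID to a named member gene set (GO-like)."""

    def __init__(self, terms: Mapping[str, AnnotationTerm]):
        for term in terms.values():
            if not term.genes:
                raise FormatError(f"empty annotation term {term.term_id!r}")
        self.terms = dict(terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        return self.terms[term_id]

    def restricted_to(self, universe: Iterable[str]) -> "GeneAnnotation":
        """Drop genes outside ``universe``; drop terms left empty."""
        uni = set(universe)
        kept: dict[str, AnnotationTerm] = {}
        n_dropped_genes = 0
        n_dropped_terms = 0
        for term in self:
            members = term.genes & uni
            n_dropped_genes += len(term.genes) - len(members)
            if members:
                kept[term.term_id] = AnnotationTerm(term.term_id, term.name, frozenset(members))
            else:
                n_dropped_terms += 1
        if n_dropped_genes or n_dropped_terms:
            logger.warning(
                "annotation harmonization dropped %d genes and %d empty terms",
                n_dropped_genes, n_dropped_terms,
            )
        return GeneAnnotation(kept)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneAnnotation:
    """Read a GMT file (term, description, tab-separated genes per line)."""
    path = Path(path)
    terms: dict[str, AnnotationTerm] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            term_id, name, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms[term_id] = AnnotationTerm(term_id, name, frozenset(genes))
    annotation = GeneAnnotation(terms)
    if universe is not None:
        annotation = annotation.restricted_to(universe)
    return annotation


def write_gmt(annotation: GeneAnnotation, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in sorted(annotation, key=lambda t: t.term_id):
            fh.write("\t".join([term.term_id, term.name, *sorted(term.genes)]) + "\n")


class MarkerTable:
    """Published cell-type markers: rows of (gene, cell_type, sign, source).

    Sign uses the reporting conventions '+', '-', '+?', '?'.
    """

    COLUMNS = ("gene", "cell_type", "sign", "source")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"marker table missing columns: {missing}")
        if data.duplicated(subset=["gene", "cell_type"]).any():
            row = data.loc[data.duplicated(subset=["gene", "cell_type"])].iloc[0]
            raise FormatError(
                f"duplicate marker entry: {row['gene']!r} / {row['cell_type']!r}"
            )
        self.data = data.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]))

    def positive_markers(self) -> pd.DataFrame:
        """Rows whose reported sign is positive ('+' or '+?')."""
        return self.data[self.data["sign"].isin(["+", "+?"])]


def read_markers(path: str | Path) -> MarkerTable:
    return MarkerTable(pd.read_csv(path))


def load_builtin_markers() -> MarkerTable:
    """Built-in marker table for the major cell types of bovine skeletal muscle.

    Reconstructed from the published marker literature (pericytes, satellite
    cells, endothelial cells, fibro/adipogenic progenitors, pre/adipocytes,
    fibroblasts); each row cites its marker class.
    """
    with resources.files("growthsig").joinpath("data/markers_muscle.csv").open("r") as fh:
        return MarkerTable(pd.read_csv(fh))


@dataclass
class ValidationReport:
    """Outcome of cohort validation; empty ``violations`` means a clean cohort."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "cohort OK"
        return "cohort violations:\n" + "\n".join(f"  - {v}" for v in self.violations)


def validate_cohort(
    matrix: ExpressionMatrix,
    table: SampleTable,
    analysis: str | None = None,
) -> ValidationReport:
    """Check matrix/metadata agreement without mutating either.

    ``analysis`` may be ``"phenotype"`` (requires ADG/kg for every sample) or
    ``"development"`` (requires stages from the declared vocabulary and both
    genotypes).  All violations are listed, none raised.
    """
    report = ValidationReport()
    matrix_ids = list(matrix.samples)
    table_ids = list(table.sample_ids)
    if set(matrix_ids) != set(table_ids):
        only_m = sorted(set(matrix_ids) - set(table_ids))[:5]
        only_t = sorted(set(table_ids) - set(matrix_ids))[:5]
        report.violations.append(
            f"sample ID mismatch (matrix-only: {only_m}, table-only: {only_t})"
        )
    elif matrix_ids != table_ids:
        report.violations.append("sample order differs between matrix and table")
    unknown = sorted(set(table.data["stage"].dropna()) - set(STAGE_ORDER))
    if unknown:
        report.violations.append(f"stages outside vocabulary: {unknown}")
    if analysis == "phenotype":
        if table.data["adg_per_kg"].isna().any():
            n = int(table.data["adg_per_kg"].isna().sum())
            report.violations.append(f"adg_per_kg missing for {n} samples")
    if analysis == "development":
        genotypes = set(table.data["genotype"])
        if len(genotypes) < 2:
            report.violations.append(
                f"development cohort needs two genotypes, found {sorted(genotypes)}"
            )
    return report
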