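"""Tabular I/O with one fixed dialect: UTF-8, tab-separated, header mandatory.

The pipeline exchanges three table kinds — a gene x sample count matrix, a
sample sheet (study design) and an optional gene -> functional-category
annotation. All are read and written through :mod:`pandas` with strict
validation; errors name the offending cell so malformed inputs fail loudly
rather than propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from pandas.errors import ParserError

from .errors import DesignError, FormatError

GENE_ID = "gene_id"
DESIGN_COLUMNS = ("sample_id", "genotype", "condition", "replicate")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts, genes in rows, samples in columns.

    ``counts`` is a DataFrame indexed by gene identifier with one column per
    sample identifier; both axes must be free of duplicates.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicated gene_id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicated sample_id {dup!r}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                raise FormatError("counts must be integers")
            if (values < 0).any():
                g, s = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix TSV (first column ``gene_id``, one column/sample)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.columns[0] != GENE_ID:
        raise FormatError(
            f"{path}: first column must be named {GENE_ID!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(GENE_ID)
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric counts in sample {col!r}")
    values = df.to_numpy()
    frac = np.mod(values, 1)
    if (frac != 0).any():
        r, c = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"{path}: non-integer count at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return CountMatrix(df.astype(np.int64))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label=GENE_ID)


def detected_genes(matrix: CountMatrix) -> set[str]:
    """Genes with at least one count across all samples.

    All-zero genes are excluded from every downstream stage (their
    normalization ratios are undefined).
    """
    totals = matrix.counts.sum(axis=1)
    return set(totals.index[totals >= 1])


def filter_detected(matrix: CountMatrix) -> CountMatrix:
    """Drop all-zero genes, preserving the original gene order."""
    keep = matrix.counts.sum(axis=1) >= 1
    return CountMatrix(matrix.counts.loc[keep])


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Sample sheet: one row per sample with genotype, condition, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"design is missing column(s) {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicated sample_id {dup!r} in design")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def samples_in_cell(self, genotype: str, condition: str) -> list[str]:
        mask = (self.table["genotype"] == genotype) & (
            self.table["condition"] == condition
        )
        return list(self.table.loc[mask, "sample_id"])

    def cells(self) -> Iterator[tuple[str, str, list[str]]]:
        for genotype in self.genotypes:
            for condition in self.conditions:
                samples = self.samples_in_cell(genotype, condition)
                if samples:
                    yield genotype, condition, samples

    def validate_against(self, matrix: CountMatrix) -> None:
        design_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if design_ids != matrix_ids:
            only_d = sorted(design_ids - matrix_ids)
            only_m = sorted(matrix_ids - design_ids)
            raise DesignError(
                f"design/matrix sample mismatch: design-only={only_d}, "
                f"matrix-only={only_m}"
            )


def read_design(path: str | Path) -> StudyDesign:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str})
    except ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.Series:
    """Read a gene -> functional-category table (columns gene_id, category).

    Unannotated genes are simply absent. Returns a Series indexed by gene_id.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    for col in (GENE_ID, "category"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation needs column {col!r}")
    if df[GENE_ID].duplicated().any():
        dup = df[GENE_ID][df[GENE_ID].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated gene_id {dup!r} in annotation")
    return df.set_index(GENE_ID)["category"]


def write_annotation(annotation: pd.Series, path: str | Path) -> None:
    annotation.rename("category").to_csv(path, sep="\t", index_label=GENE_ID)
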