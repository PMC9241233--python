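"""Readers and writers for the four standard input tables and the edge-table output.

All tabular files are tab-separated with a header row and the first column
holding the row identifier; the delimiter is configurable.  Missing-value
tokens are the empty string, ``NA`` and ``NaN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FitnessMatrix",
    "MutationTable",
    "ExpressionMatrix",
    "SampleMetadata",
    "EdgeTable",
    "read_fitness_matrix",
    "read_mutation_table",
    "read_expression_matrix",
    "read_sample_metadata",
    "read_edge_table",
    "write_fitness_matrix",
    "write_edge_table",
    "DEFAULT_MUTATION_DIALECT",
    "METADATA_FIELDS",
]

NA_TOKENS = ["", "NA", "NaN"]

#: canonical -> on-disk column names for the mutation call table (CCLE dialect)
DEFAULT_MUTATION_DIALECT: Mapping[str, str] = {
    "gene": "Hugo_Symbol",
    "cell_line": "DepMap_ID",
    "variant_annotation": "Variant_annotation",
    "is_tcga_hotspot": "isTCGAhotspot",
    "is_cosmic_hotspot": "isCOSMIChotspot",
}

#: the recognised per-cell-line categorical metadata fields
METADATA_FIELDS = ("lineage", "lineage_subtype", "lineage_sub_subtype", "culture_type", "sex")

_EDGE_COLUMNS = ["geneA", "geneB", "context", "n_context", "pcc_all", "pcc_excl", "dpcc", "p_emp", "class"]
_EDGE_FLOATS = ["pcc_all", "pcc_excl", "dpcc", "p_emp"]

_TRUE_TOKENS = {"true", "1"}
_FALSE_TOKENS = {"false", "0"}


@dataclass(frozen=True)
class FitnessMatrix:
    """Gene x cell-line matrix of log Bayes Factors.

    Positive BF indicates the knockout causes a fitness defect (the gene is
    likely essential in that line).  ``normalized`` marks whether the matrix
    has been rank-mean quantile normalized; raw BF is required for
    essentiality binarization, normalized BF for all correlation work.
    """

    values: pd.DataFrame
    normalized: bool = False
    dropped_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_matrix(self.values, "FitnessMatrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def dropped_count(self) -> int:
        return len(self.dropped_genes)

    def with_values(self, values: pd.DataFrame, *, normalized: bool | None = None) -> "FitnessMatrix":
        return replace(self, values=values, normalized=self.normalized if normalized is None else normalized)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x cell-line matrix of log-TPM expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix(self.values, "ExpressionMatrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class MutationTable:
    """Long-form mutation call records with hotspot annotations."""

    records: pd.DataFrame  # columns: gene, cell_line, variant_annotation, is_tcga_hotspot, is_cosmic_hotspot

    def __post_init__(self) -> None:
        required = ["gene", "cell_line", "variant_annotation", "is_tcga_hotspot", "is_cosmic_hotspot"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"MutationTable missing canonical columns: {missing}")
        if len(self.records) and (self.records["variant_annotation"].astype(str).str.len() == 0).any():
            raise ValueError("MutationTable contains empty variant_annotation entries")

    def __len__(self) -> int:
        return len(self.records)

    def restrict(self, cell_lines: Sequence[str]) -> "MutationTable":
        universe = set(cell_lines)
        return MutationTable(self.records[self.records["cell_line"].isin(universe)].reset_index(drop=True))


@dataclass(frozen=True)
class SampleMetadata:
    """One categorical record per cell line (lineage, culture, sex, ...)."""

    table: pd.DataFrame  # index: cell line, columns subset of METADATA_FIELDS; NaN = missing

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell-line IDs in metadata: {dupes}")
        unknown = [c for c in self.table.columns if c not in METADATA_FIELDS]
        if unknown:
            raise ValueError(f"unknown metadata fields: {unknown}")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class EdgeTable:
    """Differential-correlation edge calls plus run provenance."""

    edges: pd.DataFrame  # columns _EDGE_COLUMNS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"EdgeTable missing columns: {missing}")
        if len(self.edges):
            bad = self.edges["geneA"] >= self.edges["geneB"]
            if bad.any():
                raise ValueError("EdgeTable pairs must be canonically ordered geneA < geneB")
            if self.edges.duplicated(subset=["geneA", "geneB", "context"]).any():
                raise ValueError("EdgeTable contains duplicate (geneA, geneB, context) triples")

    def __len__(self) -> int:
        return len(self.edges)

    def sorted(self) -> pd.DataFrame:
        """Rows ordered by |dPCC| descending with a deterministic tiebreak."""
        df = self.edges.copy()
        df["_absd"] = df["dpcc"].abs()
        df = df.sort_values(["_absd", "geneA", "geneB", "context"], ascending=[False, True, True, True], kind="mergesort")
        return df.drop(columns="_absd").reset_index(drop=True)


def _check_matrix(df: pd.DataFrame, what: str) -> None:
    if df.index.duplicated().any():
        raise ValueError(f"{what}: duplicate gene IDs: {df.index[df.index.duplicated()].tolist()}")
    if df.columns.duplicated().any():
        raise ValueError(f"{what}: duplicate cell-line IDs: {df.columns[df.columns.duplicated()].tolist()}")
    arr = df.to_numpy()
    if arr.size and not np.isfinite(arr.astype(float)).all():
        raise ValueError(f"{what}: non-finite values present")


def _read_numeric_matrix(path, delimiter: str, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, na_values=NA_TOKENS, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(f"{what}: non-numeric cell at row {row!r}, column {col!r}")
            df[col] = coerced
    return df.astype(float)


def read_fitness_matrix(path, *, delimiter: str = "\t", normalized: bool = False) -> FitnessMatrix:
    """Load a gene x cell-line log Bayes Factor TSV.

    Genes containing any missing value are dropped; their identities are
    retained in ``dropped_genes`` so the removal is auditable.
    """
    df = _read_numeric_matrix(path, delimiter, "fitness matrix")
    if df.index.duplicated().any():
        raise ValueError(f"fitness matrix: duplicate gene IDs: {df.index[df.index.duplicated()].tolist()}")
    has_na = df.isna().any(axis=1)
    dropped = tuple(df.index[has_na])
    df = df.loc[~has_na]
    return FitnessMatrix(values=df, normalized=normalized, dropped_genes=dropped)


def write_fitness_matrix(fm: FitnessMatrix, path, *, delimiter: str = "\t", float_format: str = "%.6f") -> None:
    fm.values.to_csv(path, sep=delimiter, index_label="gene", float_format=float_format, lineterminator="\n")


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    if pd.api.types.is_bool_dtype(col):
        return col.astype(bool)
    tokens = col.astype(str).str.strip().str.lower()
    out = pd.Series(index=col.index, dtype=bool)
    is_true = tokens.isin(_TRUE_TOKENS)
    is_false = tokens.isin(_FALSE_TOKENS)
    bad = ~(is_true | is_false)
    if bad.any():
        raise ValueError(f"mutation table: unparseable boolean {col[bad].iloc[0]!r} in column {name!r}")
    out[:] = is_true
    return out


def read_mutation_table(
    path,
    *,
    delimiter: str = "\t",
    dialect: Mapping[str, str] | None = None,
    cell_line_universe: Sequence[str] | None = None,
) -> MutationTable:
    """Load a CCLE-dialect mutation call TSV.

    ``dialect`` remaps canonical field names to on-disk headers; hotspot flags
    accept True/False/TRUE/FALSE/1/0.  When a ``cell_line_universe`` is given,
    records outside it are a hard error.
    """
    dialect = dict(DEFAULT_MUTATION_DIALECT if dialect is None else dialect)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, na_values=NA_TOKENS, keep_default_na=False)
    missing = [disk for disk in dialect.values() if disk not in raw.columns]
    if missing:
        raise ValueError(f"mutation table missing required columns: {missing}")
    df = pd.DataFrame({canon: raw[disk] for canon, disk in dialect.items()})
    if len(df):
        df["is_tcga_hotspot"] = _parse_bool_column(df["is_tcga_hotspot"], dialect["is_tcga_hotspot"])
        df["is_cosmic_hotspot"] = _parse_bool_column(df["is_cosmic_hotspot"], dialect["is_cosmic_hotspot"])
    else:
        df = df.astype({"is_tcga_hotspot": bool, "is_cosmic_hotspot": bool})
    if cell_line_universe is not None and len(df):
        stray = sorted(set(df["cell_line"]) - set(cell_line_universe))
        if stray:
            raise ValueError(f"mutation table references cell lines outside the declared universe: {stray}")
    return MutationTable(df.reset_index(drop=True))


def read_expression_matrix(path, *, delimiter: str = "\t") -> ExpressionMatrix:
    """Load a gene x cell-line log-TPM TSV. Marker-gene presence is validated downstream."""
    df = _read_numeric_matrix(path, delimiter, "expression matrix")
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return ExpressionMatrix(df)


def read_sample_metadata(path, *, delimiter: str = "\t") -> SampleMetadata:
    """Load per-cell-line categorical metadata; unknown columns are dropped with a warning."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, na_values=NA_TOKENS, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate cell-line IDs in metadata: {df.index[df.index.duplicated()].tolist()}")
    unknown = [c for c in df.columns if c not in METADATA_FIELDS]
    if unknown:
        warnings.warn(f"ignoring unknown metadata columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    return SampleMetadata(df)


def write_edge_table(edges: EdgeTable, path, *, delimiter: str = "\t") -> None:
    """Write edge calls as TSV, floats at 6 decimals, rows sorted by |dPCC| descending."""
    df = edges.sorted()
    out = df[_EDGE_COLUMNS].copy()
    for col in _EDGE_FLOATS:
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def read_edge_table(path, *, delimiter: str = "\t") -> EdgeTable:
    df = pd.read_csv(path, sep=delimiter, na_values=NA_TOKENS, keep_default_na=False)
    if len(df) == 0:
        df = pd.DataFrame(columns=_EDGE_COLUMNS)
    df["n_context"] = df["n_context"].astype(int) if len(df) else df.get("n_context", pd.Series(dtype=int))
    for col in _EDGE_FLOATS:
        df[col] = df[col].astype(float) if len(df) else df.get(col, pd.Series(dtype=float))
    return EdgeTable(df.reset_index(drop=True))
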