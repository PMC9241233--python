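"""Binary predictor features from mutations, expression and cell-line metadata.

Each cell line is described by binary context features: gain/loss-of-function
mutation status per gene, an epithelial/mesenchymal (EMT) expression state,
and one-hot encodings of lineage and other metadata.  Low-support features
are removed and highly correlated features de-duplicated before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MutationTable, SampleMetadata

__all__ = [
    "FeatureTable",
    "classify_lesions",
    "derive_emt_features",
    "encode_metadata",
    "merge_feature_tables",
    "filter_low_support",
    "deduplicate_features",
    "build_feature_table",
]

CATEGORIES = ("LOF", "GOF", "EMT", "lineage", "lineage_subtype", "lineage_sub_subtype", "culture_type", "sex")

DAMAGING = "damaging"
OTHER_NON_CONSERVING = "other non-conserving"


@dataclass(frozen=True)
class FeatureTable:
    """Cell-line x feature binary matrix with per-feature category metadata.

    ``support`` (the number of lines carrying a feature) is always the live
    column sum, never a cached value, so filtering can never desynchronise it.
    """

    values: pd.DataFrame  # cell lines x features, values in {0,1}
    categories: pd.Series  # feature name -> category

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate cell-line IDs in feature table")
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("feature values must be binary 0/1")
        if list(self.categories.index) != list(self.values.columns):
            raise ValueError("categories index must match feature columns")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def support(self) -> pd.Series:
        return self.values.sum(axis=0).astype(int)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def mask(self, feature: str) -> np.ndarray:
        """Boolean membership vector of a feature over the cell-line universe."""
        return self.values[feature].to_numpy().astype(bool)

    def select(self, names: Sequence[str]) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.values[names], self.categories[names])


def _empty(cell_lines: Sequence[str]) -> FeatureTable:
    return FeatureTable(
        pd.DataFrame(index=pd.Index(cell_lines, name="cell_line"), dtype="int8"),
        pd.Series(dtype=object),
    )


def classify_lesions(muts: MutationTable, cell_lines: Sequence[str]) -> FeatureTable:
    """Classify per-gene lesion status into GENE_LOF / GENE_GOF features.

    A cell line gets GENE_LOF = 1 if it carries at least one lesion of the
    gene annotated "damaging"; GENE_GOF = 1 if it carries a lesion that is a
    TCGA or COSMIC hotspot and annotated "other non-conserving".  Lesions
    matching neither rule contribute nothing, and genes with no qualifying
    lesion in any line produce no column.
    """
    if not len(cell_lines):
        raise ValueError("cell_lines must be non-empty")
    rec = muts.restrict(cell_lines).records
    if len(rec) == 0:
        return _empty(cell_lines)
    lof = rec[rec["variant_annotation"] == DAMAGING]
    gof = rec[
        (rec["is_tcga_hotspot"] | rec["is_cosmic_hotspot"])
        & (rec["variant_annotation"] == OTHER_NON_CONSERVING)
    ]
    index = pd.Index(cell_lines, name="cell_line")
    cols: dict[str, pd.Series] = {}
    cats: dict[str, str] = {}
    for sub, suffix, cat in ((lof, "LOF", "LOF"), (gof, "GOF", "GOF")):
        for gene, grp in sub.groupby("gene", sort=True):
            name = f"{gene}_{suffix}"
            vec = pd.Series(0, index=index, dtype="int8")
            vec[vec.index.isin(set(grp["cell_line"]))] = 1
            cols[name] = vec
            cats[name] = cat
    if not cols:
        return _empty(cell_lines)
    values = pd.DataFrame(cols, index=index)
    return FeatureTable(values, pd.Series(cats)[values.columns])


def derive_emt_features(
    expr: ExpressionMatrix,
    hi_cut: float = 1.0,
    lo_cut: float = -4.0,
    cell_lines: Sequence[str] | None = None,
) -> FeatureTable:
    """EMT state features from the CDH1 − VIM log-expression ratio.

    CDH_VIM_hi marks epithelial lines (ratio strictly above ``hi_cut``),
    CDH_VIM_lo mesenchymal lines (ratio strictly below ``lo_cut``); the
    midzone, and any cell line absent from the expression matrix, is 0 in
    both — the matrix stays binary rather than acquiring missing values.
    """
    for gene in ("CDH1", "VIM"):
        if gene not in expr.values.index:
            raise ValueError(f"expression matrix lacks required gene row {gene!r}")
    ratio = expr.values.loc["CDH1"] - expr.values.loc["VIM"]
    universe = list(expr.cell_line_ids) if cell_lines is None else list(cell_lines)
    index = pd.Index(universe, name="cell_line")
    hi = pd.Series(0, index=index, dtype="int8")
    lo = pd.Series(0, index=index, dtype="int8")
    present = [c for c in universe if c in ratio.index]
    hi[present] = (ratio[present] > hi_cut).astype("int8")
    lo[present] = (ratio[present] < lo_cut).astype("int8")
    values = pd.DataFrame({"CDH_VIM_hi": hi, "CDH_VIM_lo": lo})
    return FeatureTable(values, pd.Series({"CDH_VIM_hi": "EMT", "CDH_VIM_lo": "EMT"}))


def encode_metadata(meta: SampleMetadata) -> FeatureTable:
    """One-hot encode categorical metadata: one feature per (field, value) pair.

    Features are named ``field:value``; missing entries contribute 0 to every
    feature of that field.
    """
    if not len(meta.table.index):
        raise ValueError("metadata must describe at least one cell line")
    index = pd.Index(meta.cell_line_ids, name="cell_line")
    cols: dict[str, pd.Series] = {}
    cats: dict[str, str] = {}
    for field in meta.table.columns:
        col = meta.table[field]
        for value in sorted(col.dropna().unique()):
            name = f"{field}:{value}"
            cols[name] = (col == value).astype("int8").set_axis(index)
            cats[name] = field
    if not cols:
        return _empty(meta.cell_line_ids)
    values = pd.DataFrame(cols, index=index)
    return FeatureTable(values, pd.Series(cats)[values.columns])


def merge_feature_tables(tables: Iterable[FeatureTable]) -> FeatureTable:
    """Concatenate feature tables over the union of their cell-line universes.

    Rows are aligned by cell line with zero fill (a line absent from a source
    table simply lacks those features); duplicate feature names across tables
    are a hard error.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no feature tables to merge")
    if len(tables) == 1:
        return tables[0]
    names = pd.concat([t.categories for t in tables])
    if names.index.duplicated().any():
        dupes = names.index[names.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature names across tables: {dupes}")
    universe: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for cl in t.cell_line_ids:
            if cl not in seen:
                universe.append(cl)
                seen.add(cl)
    index = pd.Index(sorted(universe), name="cell_line")
    parts = [t.values.reindex(index, fill_value=0).astype("int8") for t in tables]
    values = pd.concat(parts, axis=1)
    return FeatureTable(values, names[values.columns])


def filter_low_support(ft: FeatureTable, min_support: int = 7) -> FeatureTable:
    """Drop features describing fewer than ``min_support`` cell lines.

    The default keeps features present in at least 7 lines, i.e. removes
    those describing six or fewer.
    """
    keep = ft.support[ft.support >= min_support].index.tolist()
    return ft.select(keep)


def deduplicate_features(
    ft: FeatureTable, pcc_cut: float = 0.9, seed: int = 0
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove collinear features: of every surviving pair with PCC >= ``pcc_cut``,
    discard the one describing fewer cell lines.

    Pairs are visited in a deterministic order (support descending, then name
    ascending) so results are reproducible; when two correlated features have
    equal support the victim is chosen by the seeded RNG.  Zero-variance
    features, whose PCC is undefined, are dropped with a warning first.

    Returns the surviving table and a discard log with columns
    (kept, discarded, pcc).
    """
    rng = np.random.default_rng(seed)
    log_rows: list[tuple[str, str, float]] = []

    values = ft.values
    var = values.to_numpy().astype(float).var(axis=0)
    zero_var = [name for name, v in zip(values.columns, var) if v == 0.0]
    if zero_var:
        warnings.warn(f"dropping {len(zero_var)} zero-variance feature(s) before dedup: {zero_var[:5]}", stacklevel=2)
        keep = [c for c in values.columns if c not in set(zero_var)]
        ft = ft.select(keep)
        values = ft.values
    if ft.n_features == 0:
        return ft, pd.DataFrame(columns=["kept", "discarded", "pcc"])

    support = ft.support
    order = sorted(values.columns, key=lambda name: (-support[name], name))
    mat = values[order].to_numpy().astype(float)
    pcc = np.corrcoef(mat, rowvar=False) if len(order) > 1 else np.ones((1, 1))

    alive = {name: True for name in order}
    for i, a in enumerate(order):
        if not alive[a]:
            continue
        for j in range(i + 1, len(order)):
            b = order[j]
            if not alive[b]:
                continue
            r = float(pcc[i, j])
            if r >= pcc_cut:
                if support[a] > support[b]:
                    victim, kept = b, a
                elif support[a] < support[b]:
                    victim, kept = a, b
                else:
                    victim = a if rng.integers(2) == 0 else b
                    kept = b if victim == a else a
                alive[victim] = False
                log_rows.append((kept, victim, r))
                if victim == a:
                    break
    survivors = [name for name in ft.feature_names if alive.get(name, False)]
    log = pd.DataFrame(log_rows, columns=["kept", "discarded", "pcc"])
    return ft.select(survivors), log


def build_feature_table(
    muts: MutationTable,
    expr: ExpressionMatrix | None,
    meta: SampleMetadata,
    cell_lines: Sequence[str],
    *,
    min_support: int = 7,
    dedup_pcc: float = 0.9,
    seed: int = 0,
    emt_hi_cut: float = 1.0,
    emt_lo_cut: float = -4.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Full feature chain: classify -> EMT -> one-hot -> merge -> filter -> dedup."""
    parts = [classify_lesions(muts, cell_lines)]
    if expr is not None:
        parts.append(derive_emt_features(expr, emt_hi_cut, emt_lo_cut, cell_lines))
    parts.append(encode_metadata(meta))
    merged = merge_feature_tables(parts)
    merged = FeatureTable(
        merged.values.reindex(pd.Index(sorted(cell_lines), name="cell_line"), fill_value=0),
        merged.categories,
    )
    filtered = filter_low_support(merged, min_support=min_support)
    return deduplicate_features(filtered, pcc_cut=dedup_pcc, seed=seed)
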