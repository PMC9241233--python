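"""Leave-one-out differential correlation (dPCC) with a bootstrap empirical null.

The coessentiality network is the all-by-all Pearson correlation of
quantile-normalized gene fitness profiles across cell lines.  For a binary
context (a mutation, lineage, culture or expression state shared by *n*
lines), interaction rewiring is measured per gene pair as

    dPCC = PCC_all − PCC_~context

where PCC_~context is recomputed after excluding the *n* context lines.
Positive dPCC is a gain of interaction (GOI: the correlation depends on the
context lines being present), negative a loss of interaction (LOI: removing
them improves it).  Significance is empirical: remove *n* cell lines at
random B times, recompute dPCC_rand for each replicate, and compare the
observed dPCC to that null with a two-sided empirical P in steps of 1/B.

The approach deliberately leans on Pearson's sensitivity to coherent
outliers — a functionally coherent subset of lines can dominate a
correlation, and removing it is exactly what the statistic detects — so no
rank-based correlation is offered here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable
from .io import EdgeTable, FitnessMatrix

__all__ = [
    "ContextMask",
    "CorrelationMatrix",
    "BootstrapNull",
    "quantile_normalize",
    "correlation_matrix",
    "dpcc_for_context",
    "bootstrap_null",
    "empirical_pvalues",
    "classify_edges",
    "summarize_features",
    "DifferentialNetwork",
    "DifferentialNetworkResults",
]


@dataclass(frozen=True)
class ContextMask:
    """Binary membership of cell lines in one context."""

    context_name: str
    mask: np.ndarray  # boolean, aligned with the fitness matrix columns

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if not (1 <= m.sum() < m.size):
            raise ValueError(
                f"context {self.context_name!r}: must flag at least 1 and fewer than all cell lines"
            )

    @property
    def n_context(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_feature(cls, ft: FeatureTable, feature: str) -> "ContextMask":
        return cls(feature, ft.mask(feature))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix with provenance."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    provenance: str = "all"
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.gene_ids),) * 2:
            raise ValueError("correlation matrix shape must match gene list")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.gene_ids))


@dataclass(frozen=True)
class BootstrapNull:
    """Streaming exceedance counters for the bootstrap dPCC null.

    For each tracked gene pair, ``count_ge`` is the number of null replicates
    with dPCC_rand >= dPCC_obs and ``count_le`` the number with
    dPCC_rand <= dPCC_obs; ties count in both, so count_ge + count_le >= B.
    Memory is O(pairs), independent of B.
    """

    context_name: str
    B: int
    seed: int
    n_removed: int
    gene_ids: tuple[str, ...]
    count_ge: np.ndarray
    count_le: np.ndarray
    pairs: np.ndarray | None = None  # (P, 2) int indices when tracking a subset

    def __post_init__(self) -> None:
        if ((self.count_ge + self.count_le) < self.B).any():
            raise ValueError("tie accounting violated: count_ge + count_le < B for some pair")


def quantile_normalize(fm: FitnessMatrix) -> FitnessMatrix:
    """Rank-mean quantile normalization across cell lines, without a reference.

    Within each cell line (column), the value at rank r is replaced by the
    mean over all cell lines of their rank-r values, so every column ends up
    with the same sorted values.  Ties within a column receive the mean of
    the rank-mean values across the tied span.
    """
    if fm.normalized:
        warnings.warn("fitness matrix already flagged normalized; recomputing anyway", stacklevel=2)
    vals = fm.values.to_numpy(dtype=float)
    n_genes, n_lines = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    if (sorted_vals == sorted_vals[:, :1]).all():
        # columns already share their sorted values (e.g. a repeated
        # application): the rank mean is that common value, exactly
        ref = sorted_vals[:, 0].copy()
    else:
        ref = sorted_vals.mean(axis=1)  # mean of rank-r values across columns
    out = np.empty_like(vals)
    for j in range(n_lines):
        col_sorted = sorted_vals[:, j]
        assigned = ref.copy()
        # spread ties: each run of equal input values gets the mean ref over its span
        boundaries = np.flatnonzero(np.diff(col_sorted)) + 1
        starts = np.concatenate(([0], boundaries))
        if len(starts) < n_genes:  # only loop when ties exist
            sums = np.add.reduceat(ref, starts)
            lengths = np.diff(np.concatenate((starts, [n_genes])))
            means = sums / lengths
            assigned = np.repeat(means, lengths)
        out[order[:, j], j] = assigned
    df = pd.DataFrame(out, index=fm.values.index, columns=fm.values.columns)
    return FitnessMatrix(values=df, normalized=True, dropped_genes=fm.dropped_genes)


def _corr_with_zero_var(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of rows; zero-variance rows get correlation 0 (flagged)."""
    # constancy via the range: std of a constant row can round off to ~1e-17
    zero = np.ptp(X, axis=1) == 0.0
    if zero.any():
        Xs = X.copy()
        Xs[zero] = np.arange(X.shape[1], dtype=float)  # placeholder; rows zeroed after
        corr = np.corrcoef(Xs)
        corr[zero, :] = 0.0
        corr[:, zero] = 0.0
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.corrcoef(X)
    return np.clip(corr, -1.0, 1.0), zero


def correlation_matrix(fm: FitnessMatrix, exclude: ContextMask | None = None) -> CorrelationMatrix:
    """All-by-all Pearson correlation of gene profiles, optionally excluding a context.

    A gene with zero variance over the included lines gets correlation 0 with
    everything (flagged in ``zero_variance``) rather than NaN, so downstream
    arithmetic stays finite; such pairs are excluded from edge calls.
    """
    if not fm.normalized:
        raise ValueError("correlation requires a quantile-normalized fitness matrix")
    X = fm.values.to_numpy(dtype=float)
    if exclude is not None:
        if exclude.mask.size != X.shape[1]:
            raise ValueError("context mask length must equal the number of cell lines")
        keep = ~exclude.mask
        if keep.sum() < 3:
            raise ValueError("fewer than 3 cell lines remain after excluding the context")
        X = X[:, keep]
        prov = f"excluding:{exclude.context_name}"
    else:
        prov = "all"
    corr, zero = _corr_with_zero_var(X)
    genes = tuple(fm.gene_ids)
    return CorrelationMatrix(genes, corr, prov, tuple(np.array(genes)[zero]))


@dataclass(frozen=True)
class DpccResult:
    """PCC_all, PCC_~context and their difference for one context."""

    context: ContextMask
    pcc_all: CorrelationMatrix
    pcc_excl: CorrelationMatrix
    dpcc: np.ndarray

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.pcc_all.gene_ids


def dpcc_for_context(
    fm: FitnessMatrix, mask: ContextMask, pcc_all: CorrelationMatrix | None = None
) -> DpccResult:
    """dPCC = PCC_all − PCC_~context, elementwise over all gene pairs.

    One global PCC_all serves every context; pass it in to avoid recomputation.
    """
    if pcc_all is None:
        pcc_all = correlation_matrix(fm)
    pcc_excl = correlation_matrix(fm, exclude=mask)
    return DpccResult(mask, pcc_all, pcc_excl, pcc_all.values - pcc_excl.values)


def _pair_correlations(X: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Pearson r for an explicit (P, 2) set of row pairs; zero-variance rows give 0."""
    mu = X.mean(axis=1, keepdims=True)
    sd = np.where(np.ptp(X, axis=1) == 0.0, 0.0, X.std(axis=1))
    Z = X - mu
    denom = sd[pairs[:, 0]] * sd[pairs[:, 1]] * X.shape[1]
    num = np.einsum("ij,ij->i", Z[pairs[:, 0]], Z[pairs[:, 1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def bootstrap_null(
    fm: FitnessMatrix,
    n_removed: int,
    dpcc_obs: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    *,
    context_name: str = "context",
    pairs: np.ndarray | None = None,
) -> BootstrapNull:
    """Empirical dPCC null by random removal of ``n_removed`` cell lines, B times.

    Each replicate removes a fresh uniform random subset (without replacement
    within a replicate, independent across replicates), recomputes
    dPCC_rand = PCC_all − PCC_rand for the tracked pairs, and updates
    streaming >=/<= counters against ``dpcc_obs``.  With ``pairs`` given, only
    that (P, 2) pair subset is tracked and dpcc_obs must be a length-P vector;
    otherwise full matrices are used.  One shared set of removals serves all
    pairs within the context.
    """
    if n_removed < 1:
        raise ValueError("n_removed must be >= 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not fm.normalized:
        raise ValueError("bootstrap requires a quantile-normalized fitness matrix")
    X = fm.values.to_numpy(dtype=float)
    n_lines = X.shape[1]
    if n_removed >= n_lines - 2:
        raise ValueError(f"cannot remove {n_removed} of {n_lines} cell lines (need >= 3 left)")
    rng = np.random.default_rng(seed)
    if pairs is not None:
        pairs = np.asarray(pairs, dtype=int)
        obs = np.asarray(dpcc_obs, dtype=float)
        if obs.shape != (pairs.shape[0],):
            raise ValueError("with pairs, dpcc_obs must be a vector of per-pair values")
        pcc_all = _pair_correlations(X, pairs)
    else:
        obs = np.asarray(dpcc_obs, dtype=float)
        if obs.shape != (X.shape[0], X.shape[0]):
            raise ValueError("dpcc_obs must be a genes x genes matrix")
        pcc_all, _ = _corr_with_zero_var(X)
    count_ge = np.zeros_like(obs, dtype=np.int64)
    count_le = np.zeros_like(obs, dtype=np.int64)
    for _ in range(B):
        removed = rng.choice(n_lines, size=n_removed, replace=False)
        keep = np.ones(n_lines, dtype=bool)
        keep[removed] = False
        Xk = X[:, keep]
        if pairs is not None:
            pcc_rand = _pair_correlations(Xk, pairs)
        else:
            pcc_rand, _ = _corr_with_zero_var(Xk)
        d_rand = pcc_all - pcc_rand
        count_ge += d_rand >= obs
        count_le += d_rand <= obs
    return BootstrapNull(
        context_name, B, seed, n_removed, tuple(fm.gene_ids), count_ge, count_le, pairs
    )


def empirical_pvalues(null: BootstrapNull) -> np.ndarray:
    """Two-sided empirical P per pair: min(1, 2·min(count_ge, count_le)/B), floored at 1/B.

    The null is sampled, so P is discrete in steps of 1/B; a dPCC_obs more
    extreme than every replicate reports the resolution floor, not zero.
    """
    B = null.B
    tail = np.minimum(null.count_ge, null.count_le)
    p = 2.0 * tail / B
    return np.clip(p, 1.0 / B, 1.0)


def classify_edges(
    dres: DpccResult,
    p: np.ndarray,
    alpha: float = 0.001,
    min_abs_dpcc: float = 0.0,
    *,
    pairs: np.ndarray | None = None,
    provenance: Mapping | None = None,
) -> EdgeTable:
    """Call GOI/LOI edges: p <= alpha, |dPCC| >= min_abs_dpcc, sign gives the class.

    Self-pairs and pairs touching a zero-variance gene (in either correlation)
    are excluded; gene pairs are emitted in canonical lexicographic order.
    """
    genes = np.array(dres.gene_ids)
    flagged = set(dres.pcc_all.zero_variance) | set(dres.pcc_excl.zero_variance)
    if pairs is None:
        iu = np.triu_indices(len(genes), k=1)
        idx_a, idx_b = iu
        dvec = dres.dpcc[idx_a, idx_b]
        pvec = np.asarray(p)[idx_a, idx_b]
        pall = dres.pcc_all.values[idx_a, idx_b]
        pexc = dres.pcc_excl.values[idx_a, idx_b]
    else:
        idx_a, idx_b = pairs[:, 0], pairs[:, 1]
        dvec = dres.dpcc[idx_a, idx_b]
        pvec = np.asarray(p)
        pall = dres.pcc_all.values[idx_a, idx_b]
        pexc = dres.pcc_excl.values[idx_a, idx_b]
    keep = (pvec <= alpha) & (np.abs(dvec) >= min_abs_dpcc) & (dvec != 0.0) & (idx_a != idx_b)
    rows = []
    for ia, ib, pa, pe, d, pv in zip(
        idx_a[keep], idx_b[keep], pall[keep], pexc[keep], dvec[keep], pvec[keep]
    ):
        ga, gb = genes[ia], genes[ib]
        if ga in flagged or gb in flagged:
            continue
        if gb < ga:
            ga, gb = gb, ga
        rows.append(
            (ga, gb, dres.context.context_name, dres.context.n_context, pa, pe, d, pv, "GOI" if d > 0 else "LOI")
        )
    df = pd.DataFrame(
        rows,
        columns=["geneA", "geneB", "context", "n_context", "pcc_all", "pcc_excl", "dpcc", "p_emp", "class"],
    )
    return EdgeTable(df, dict(provenance or {}))


def summarize_features(
    edge_tables: Sequence[EdgeTable], categories: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-context edge counts plus grand totals.

    A context (feature) is GOI-associated if it has at least one GOI edge and
    LOI-associated if it has at least one LOI edge; both can hold at once.
    The returned frame has one row per context and a final ``TOTAL`` row.
    """
    counts: dict[str, dict[str, int]] = {}
    for et in edge_tables:
        for _, row in et.edges.iterrows():
            ctx = counts.setdefault(row["context"], {"n_goi": 0, "n_loi": 0})
            ctx["n_goi" if row["class"] == "GOI" else "n_loi"] += 1
    rows = []
    for ctx in sorted(counts):
        c = counts[ctx]
        rows.append(
            {
                "feature": ctx,
                "category": (categories or {}).get(ctx, ""),
                "n_goi": c["n_goi"],
                "n_loi": c["n_loi"],
                "goi_associated": c["n_goi"] > 0,
                "loi_associated": c["n_loi"] > 0,
            }
        )
    df = pd.DataFrame(rows, columns=["feature", "category", "n_goi", "n_loi", "goi_associated", "loi_associated"])
    total = {
        "feature": "TOTAL",
        "category": "",
        "n_goi": int(df["n_goi"].sum()) if len(df) else 0,
        "n_loi": int(df["n_loi"].sum()) if len(df) else 0,
        "goi_associated": bool((df["n_goi"] > 0).any()) if len(df) else False,
        "loi_associated": bool((df["n_loi"] > 0).any()) if len(df) else False,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


class DifferentialNetwork:
    """Model: context-dependent rewiring of a coessentiality network.

    Parameters
    ----------
    fitness : FitnessMatrix
        Gene x cell-line log Bayes Factors; quantile-normalized on entry if
        not already.
    contexts : mapping of name -> boolean mask, or FeatureTable
        The binary contexts to test.  With a FeatureTable, every feature
        column becomes a context.
    screen_abs_dpcc : float or None
        When set, only gene pairs with |dPCC| >= this screening cut enter the
        bootstrap (the cheap desk-scale route); None bootstraps all pairs.
    """

    def __init__(
        self,
        fitness: FitnessMatrix,
        contexts: Mapping[str, np.ndarray] | FeatureTable,
        *,
        screen_abs_dpcc: float | None = None,
    ) -> None:
        self.fitness = fitness if fitness.normalized else quantile_normalize(fitness)
        if isinstance(contexts, FeatureTable):
            if list(contexts.cell_line_ids) != list(self.fitness.cell_line_ids):
                raise ValueError("feature table cell lines must match fitness matrix columns")
            masks = {name: contexts.mask(name) for name in contexts.feature_names}
        else:
            masks = {name: np.asarray(m, dtype=bool) for name, m in contexts.items()}
        self.contexts = {name: ContextMask(name, m) for name, m in masks.items()}
        self.screen_abs_dpcc = screen_abs_dpcc
        self.pcc_all = correlation_matrix(self.fitness)

    def fit(
        self,
        B: int = 1000,
        seed: int = 0,
        alpha: float = 0.001,
        min_abs_dpcc: float = 0.0,
    ) -> "DifferentialNetworkResults":
        """Run the leave-one-out test plus bootstrap null for every context."""
        n_genes = len(self.fitness.gene_ids)
        dres: dict[str, DpccResult] = {}
        pvals: dict[str, np.ndarray] = {}
        nulls: dict[str, BootstrapNull] = {}
        edge_tables: dict[str, EdgeTable] = {}
        seeds = _spawn_seeds(seed, len(self.contexts))
        for sub_seed, (name, mask) in zip(seeds, sorted(self.contexts.items())):
            res = dpcc_for_context(self.fitness, mask, pcc_all=self.pcc_all)
            iu = np.triu_indices(n_genes, k=1)
            if self.screen_abs_dpcc is not None:
                sel = np.abs(res.dpcc[iu]) >= self.screen_abs_dpcc
                pairs = np.column_stack((iu[0][sel], iu[1][sel]))
            else:
                pairs = np.column_stack(iu)
            obs = res.dpcc[pairs[:, 0], pairs[:, 1]]
            null = bootstrap_null(
                self.fitness, mask.n_context, obs, B=B, seed=sub_seed, context_name=name, pairs=pairs
            )
            pv = empirical_pvalues(null)
            prov = {
                "context": name,
                "n_context": mask.n_context,
                "B": B,
                "seed": int(sub_seed),
                "alpha": alpha,
                "min_abs_dpcc": min_abs_dpcc,
                "screen_abs_dpcc": self.screen_abs_dpcc,
            }
            edge_tables[name] = classify_edges(
                res, pv, alpha=alpha, min_abs_dpcc=min_abs_dpcc, pairs=pairs, provenance=prov
            )
            dres[name], pvals[name], nulls[name] = res, pv, null
        return DifferentialNetworkResults(self, dres, pvals, nulls, edge_tables, B=B, seed=seed, alpha=alpha)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent per-context sub-seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(n, 1))]


@dataclass
class DifferentialNetworkResults:
    """Per-context dPCC matrices, empirical p-values, nulls and edge calls."""

    model: DifferentialNetwork
    dpcc: Mapping[str, DpccResult]
    pvalues: Mapping[str, np.ndarray]
    nulls: Mapping[str, BootstrapNull]
    edges: Mapping[str, EdgeTable]
    B: int
    seed: int
    alpha: float
    categories: Mapping[str, str] = field(default_factory=dict)

    def edge_table(self) -> EdgeTable:
        """All contexts' edge calls merged into one canonical EdgeTable."""
        frames = [et.edges for et in self.edges.values() if len(et)]
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else next(iter(self.edges.values())).edges.iloc[0:0]
            if self.edges
            else pd.DataFrame(columns=["geneA", "geneB", "context", "n_context", "pcc_all", "pcc_excl", "dpcc", "p_emp", "class"])
        )
        prov = {"B": self.B, "seed": self.seed, "alpha": self.alpha, "contexts": sorted(self.edges)}
        return EdgeTable(df.reset_index(drop=True), prov)

    def summary_table(self) -> pd.DataFrame:
        return summarize_features(list(self.edges.values()), self.categories)

    def summary(self) -> str:
        tab = self.summary_table()
        total = tab[tab["feature"] == "TOTAL"].iloc[0]
        lines = [
            "Differential coessentiality network",
            "===================================",
            f"genes x cell lines: {len(self.model.fitness.gene_ids)} x {len(self.model.fitness.cell_line_ids)}",
            f"contexts tested:    {len(self.edges)}",
            f"bootstrap B:        {self.B} (P resolution {1.0 / self.B:g})",
            f"alpha:              {self.alpha}",
            f"GOI edges:          {int(total['n_goi'])}",
            f"LOI edges:          {int(total['n_loi'])}",
        ]
        return "\n".join(lines)
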