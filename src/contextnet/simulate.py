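"""Seeded synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the statistical shape of the real inputs: a bimodal
log Bayes Factor matrix (nonessential and essential components), CCLE-style
mutation calls, a log-TPM expression matrix carrying the CDH1/VIM EMT
signal, and categorical cell-line metadata.  Contexts are realized as
mutation records, metadata labels or EMT expression states that the
feature-engineering rules recover exactly, so planted truth can be traced
end to end.

Context-restricted coessentiality is planted through a shared latent factor
added only to the relevant line subset, which controls the subgroup
correlation while preserving the marginal bimodality of BF scores.  All
randomness flows from a single master seed through named NumPy seed-sequence
streams, so each sub-draw is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FitnessMatrix, MutationTable, SampleMetadata

__all__ = [
    "ContextSpec",
    "EssentialityPlant",
    "EdgePlant",
    "BFParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cell_lines",
    "simulate_fitness",
    "simulate_dataset",
    "make_null_dataset",
]

METADATA_CATEGORIES = ("lineage", "lineage_subtype", "lineage_sub_subtype", "culture_type", "sex")


@dataclass(frozen=True)
class ContextSpec:
    """One planted context: who carries it and how it is realized on disk."""

    name: str
    n_lines: int
    category: Literal[
        "GOF", "LOF", "EMT_hi", "EMT_lo",
        "lineage", "lineage_subtype", "lineage_sub_subtype", "culture_type", "sex",
    ]


@dataclass(frozen=True)
class EssentialityPlant:
    """A gene whose essentiality flips inside a context.

    direction '+': essential inside the context (with the given penetrance),
    nonessential outside apart from the background rate — a positive
    regression coefficient.  direction '-': the mirror image.
    """

    gene: str
    context: str
    direction: Literal["+", "-"] = "+"
    penetrance: float = 1.0


@dataclass(frozen=True)
class EdgePlant:
    """A gene pair correlated only inside (GOI) or only outside (LOI) a context.

    The relevant subset is the context lines for GOI and the non-context
    lines for LOI; ``r_in`` is the target correlation within that subset,
    ``r_out`` outside it.  Plants are realized as context-coherent essential
    blocks — the GOI pair is co-essential inside the context, the LOI pair
    co-essential outside it with a discordant context block — because
    leave-one-out dPCC detects coherent outlier structure, not mean-free
    covariance; a shared latent factor then sets the within-subset
    correlation to ``r_in`` on top of the block.
    """

    gene_a: str
    gene_b: str
    context: str
    mode: Literal["GOI", "LOI"] = "GOI"
    r_in: float = 0.8
    r_out: float = 0.0


@dataclass(frozen=True)
class BFParams:
    """Two-component log Bayes Factor model.

    Defaults place the nonessential mode well below and the essential mode
    well above the BF >= 10 essentiality cut, with enough spread for
    realistic overlap.
    """

    nonessential_mean: float = -5.0
    nonessential_sd: float = 3.0
    essential_mean: float = 25.0
    essential_sd: float = 8.0
    background_essential_rate: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    n_cell_lines: int = 150
    n_genes: int = 100
    contexts: tuple[ContextSpec, ...] = ()
    planted_essentiality: tuple[EssentialityPlant, ...] = ()
    planted_edges: tuple[EdgePlant, ...] = ()
    bf_params: BFParams = field(default_factory=BFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for ctx in self.contexts:
            if not (1 <= ctx.n_lines <= self.n_cell_lines):
                raise ValueError(f"context {ctx.name!r}: n_lines out of range")
        names = [c.name for c in self.contexts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate context names")
        known = set(names)
        for p in self.planted_essentiality:
            if p.context not in known:
                raise ValueError(f"essentiality plant references unknown context {p.context!r}")
            if not (0.0 <= p.penetrance <= 1.0):
                raise ValueError("penetrance must be in [0, 1]")
        for e in self.planted_edges:
            if e.context not in known:
                raise ValueError(f"edge plant references unknown context {e.context!r}")
            if not (abs(e.r_in) <= 1.0 and abs(e.r_out) <= 1.0):
                raise ValueError("|r_in| and |r_out| must be <= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure in lookup form, plus realized sample correlations."""

    masks: dict[str, np.ndarray]
    essentiality: tuple[EssentialityPlant, ...]
    edges: tuple[EdgePlant, ...]
    realized_correlations: pd.DataFrame  # per planted edge: r inside / outside the relevant subset


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _cell_line_ids(n: int) -> list[str]:
    return [f"CL{i:04d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_cell_lines(
    cfg: SimulationConfig,
) -> tuple[SampleMetadata, MutationTable, ExpressionMatrix, dict[str, np.ndarray]]:
    """Realize contexts as metadata labels, mutation records or EMT expression.

    The products are constructed so the feature-engineering rules recover each
    planted mask exactly: GOF contexts become hotspot "other non-conserving"
    lesions, LOF contexts "damaging" lesions, EMT contexts CDH1/VIM ratios
    beyond the thresholds, and metadata contexts one label per member (with a
    shared filler label elsewhere).  Contexts of the same metadata field must
    not overlap — a line cannot carry two lineages — and a context that would
    end up empty is an error by construction.
    """
    streams = _streams(cfg.seed, ["membership", "mutations", "expression", "fitness", "edges"])
    rng = streams["membership"]
    lines = _cell_line_ids(cfg.n_cell_lines)
    index = pd.Index(lines, name="cell_line")

    masks: dict[str, np.ndarray] = {}
    field_members: dict[str, np.ndarray] = {f: np.zeros(cfg.n_cell_lines, dtype=bool) for f in METADATA_CATEGORIES}
    for ctx in cfg.contexts:
        if ctx.category in METADATA_CATEGORIES:
            free = ~field_members[ctx.category]
            if free.sum() < ctx.n_lines:
                raise ValueError(f"context {ctx.name!r}: overlapping {ctx.category} contexts leave too few lines")
            chosen = rng.choice(np.flatnonzero(free), size=ctx.n_lines, replace=False)
            field_members[ctx.category][chosen] = True
        else:
            chosen = rng.choice(cfg.n_cell_lines, size=ctx.n_lines, replace=False)
        mask = np.zeros(cfg.n_cell_lines, dtype=bool)
        mask[chosen] = True
        masks[ctx.name] = mask

    emt_hi = np.zeros(cfg.n_cell_lines, dtype=bool)
    emt_lo = np.zeros(cfg.n_cell_lines, dtype=bool)
    meta_cols: dict[str, pd.Series] = {}
    mut_rows: list[tuple[str, str, str, bool, bool]] = []
    mrng = streams["mutations"]
    for ctx in cfg.contexts:
        mask = masks[ctx.name]
        if ctx.category == "GOF":
            gene = ctx.name.removesuffix("_GOF")
            for cl in np.array(lines)[mask]:
                tcga = bool(mrng.integers(2))
                mut_rows.append((gene, cl, "other non-conserving", tcga, not tcga or bool(mrng.integers(2))))
        elif ctx.category == "LOF":
            gene = ctx.name.removesuffix("_LOF")
            for cl in np.array(lines)[mask]:
                mut_rows.append((gene, cl, "damaging", False, False))
        elif ctx.category == "EMT_hi":
            if (emt_hi & mask).any() or (emt_lo & mask).any():
                raise ValueError("overlapping EMT contexts")
            emt_hi |= mask
        elif ctx.category == "EMT_lo":
            if (emt_hi & mask).any() or (emt_lo & mask).any():
                raise ValueError("overlapping EMT contexts")
            emt_lo |= mask
        else:
            col = meta_cols.setdefault(ctx.category, None)
            if col is None:
                # diverse filler labels: a single shared filler would be the
                # exact complement of a lone context and alias it in models
                col = pd.Series(
                    rng.choice([f"filler_{c}" for c in "abc"], cfg.n_cell_lines), index=index, dtype=object
                )
                meta_cols[ctx.category] = col
            col[mask] = ctx.name.split(":", 1)[-1]
    # a few non-qualifying noise lesions exercise the rule complement
    n_noise = max(3, cfg.n_cell_lines // 20)
    for _ in range(n_noise):
        cl = lines[int(mrng.integers(cfg.n_cell_lines))]
        mut_rows.append(("NOISE1", cl, "silent", False, False))
        mut_rows.append(("NOISE2", cl, "other non-conserving", False, False))
    muts = MutationTable(
        pd.DataFrame(
            mut_rows,
            columns=["gene", "cell_line", "variant_annotation", "is_tcga_hotspot", "is_cosmic_hotspot"],
        )
    )

    if "lineage" not in meta_cols:
        meta_cols["lineage"] = pd.Series(
            rng.choice([f"filler_{c}" for c in "abc"], cfg.n_cell_lines), index=index, dtype=object
        )
    meta = SampleMetadata(pd.DataFrame(meta_cols, index=index))

    erng = streams["expression"]
    ratio = erng.normal(-1.5, 0.5, cfg.n_cell_lines)  # midzone: neither epithelial nor mesenchymal
    ratio = np.clip(ratio, -3.9, 0.9)
    ratio[emt_hi] = erng.normal(3.0, 0.3, int(emt_hi.sum()))
    ratio[emt_lo] = erng.normal(-6.0, 0.3, int(emt_lo.sum()))
    ratio[emt_hi] = np.maximum(ratio[emt_hi], 1.01)
    ratio[emt_lo] = np.minimum(ratio[emt_lo], -4.01)
    vim = erng.normal(5.0, 1.0, cfg.n_cell_lines)
    expr = pd.DataFrame(
        {"CDH1": vim + ratio, "VIM": vim, "GAPDH": erng.normal(10.0, 1.0, cfg.n_cell_lines)}
    ).T
    expr.columns = index
    expr.index.name = "gene"
    expression = ExpressionMatrix(expr)
    return meta, muts, expression, masks


def simulate_fitness(cfg: SimulationConfig, masks: dict[str, np.ndarray]) -> tuple[FitnessMatrix, GroundTruth]:
    """Draw the log Bayes Factor matrix with the configured plants.

    Baseline entries are i.i.d. two-component draws (essential with the
    background rate).  Essentiality plants overwrite a gene's component
    inside/outside its context with the given penetrance; edge plants build
    the pair from a shared latent factor within the relevant subset so the
    subgroup correlation targets r_in, with r_out outside.
    """
    streams = _streams(cfg.seed, ["membership", "mutations", "expression", "fitness", "edges"])
    rng = streams["fitness"]
    bf = cfg.bf_params
    n_g, n_c = cfg.n_genes, cfg.n_cell_lines
    genes = _gene_ids(n_g)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for plant in cfg.planted_essentiality:
        if plant.gene not in gene_pos:
            raise ValueError(f"essentiality plant gene {plant.gene!r} outside the gene universe")
    for plant in cfg.planted_edges:
        for g in (plant.gene_a, plant.gene_b):
            if g not in gene_pos:
                raise ValueError(f"edge plant gene {g!r} outside the gene universe")

    essential = rng.random((n_g, n_c)) < bf.background_essential_rate
    for plant in cfg.planted_essentiality:
        mask = masks[plant.context]
        gi = gene_pos[plant.gene]
        inside = mask if plant.direction == "+" else ~mask
        essential[gi, inside] = rng.random(int(inside.sum())) < plant.penetrance
        essential[gi, ~inside] = rng.random(int((~inside).sum())) < bf.background_essential_rate
    # edge plants lay out a context-coherent essentiality block first; random
    # component flips on these genes would inject large independent outliers
    # and mask the planted structure.  Genes with an explicit essentiality
    # plant keep that plant's layout.
    ess_plant_genes = {p.gene for p in cfg.planted_essentiality}
    for plant in cfg.planted_edges:
        mask = masks[plant.context]
        subset = mask if plant.mode == "GOI" else ~mask
        ia, ib = gene_pos[plant.gene_a], gene_pos[plant.gene_b]
        if plant.mode == "GOI":
            # pair co-essential inside the context, quiet outside
            if plant.gene_a not in ess_plant_genes:
                essential[ia] = subset
            if plant.gene_b not in ess_plant_genes:
                essential[ib] = subset
        else:
            # pair co-essential outside the context; inside, the block is
            # discordant (A essential, B not), breaking the correlation
            if plant.gene_a not in ess_plant_genes:
                essential[ia, :] = True
            if plant.gene_b not in ess_plant_genes:
                essential[ib] = subset
    values = np.where(
        essential,
        rng.normal(bf.essential_mean, bf.essential_sd, (n_g, n_c)),
        rng.normal(bf.nonessential_mean, bf.nonessential_sd, (n_g, n_c)),
    )

    erng = streams["edges"]
    realized = []
    for plant in cfg.planted_edges:
        mask = masks[plant.context]
        subset = mask if plant.mode == "GOI" else ~mask
        for r, sub in ((plant.r_in, subset), (plant.r_out, ~subset)):
            if abs(r) > 0.999:
                raise ValueError(f"edge plant {plant.gene_a}-{plant.gene_b}: |r|={abs(r)} infeasible")
            if r == 0.0:
                continue
            n_sub = int(sub.sum())
            if n_sub < 3:
                raise ValueError("edge plant subset smaller than 3 lines")
            z = erng.standard_normal(n_sub)
            for g in (plant.gene_a, plant.gene_b):
                gi = gene_pos[g]
                mu = np.where(essential[gi, sub], bf.essential_mean, bf.nonessential_mean)
                sd = np.where(essential[gi, sub], bf.essential_sd, bf.nonessential_sd)
                sign = np.sign(r) if g == plant.gene_b else 1.0
                eps = erng.standard_normal(n_sub)
                values[gi, sub] = mu + sd * (sign * np.sqrt(abs(r)) * z + np.sqrt(1 - abs(r)) * eps)
        ia, ib = gene_pos[plant.gene_a], gene_pos[plant.gene_b]
        r_in_hat = float(np.corrcoef(values[ia, subset], values[ib, subset])[0, 1])
        r_out_hat = float(np.corrcoef(values[ia, ~subset], values[ib, ~subset])[0, 1])
        realized.append(
            (plant.gene_a, plant.gene_b, plant.context, plant.mode, plant.r_in, r_in_hat, plant.r_out, r_out_hat)
        )

    fm = FitnessMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=_cell_line_ids(n_c))
    )
    truth = GroundTruth(
        masks=dict(masks),
        essentiality=tuple(cfg.planted_essentiality),
        edges=tuple(cfg.planted_edges),
        realized_correlations=pd.DataFrame(
            realized,
            columns=["gene_a", "gene_b", "context", "mode", "r_in", "r_in_realized", "r_out", "r_out_realized"],
        ),
    )
    return fm, truth


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[FitnessMatrix, SampleMetadata, MutationTable, ExpressionMatrix, GroundTruth]:
    """Convenience wrapper: cell lines, omics tables and fitness in one call."""
    meta, muts, expr, masks = simulate_cell_lines(cfg)
    fm, truth = simulate_fitness(cfg, masks)
    return fm, meta, muts, expr, truth


def make_null_dataset(
    n_cell_lines: int = 150,
    n_genes: int = 200,
    seed: int = 0,
    *,
    n_masks: int = 1,
    mask_size: int | None = None,
    bf_params: BFParams | None = None,
) -> tuple[FitnessMatrix, dict[str, np.ndarray]]:
    """I.i.d. two-component BF draws with zero planted structure, plus random masks.

    The calibration substrate: any context mask over this matrix is
    exchangeable with random removal, so empirical p-values must be uniform.
    ``mask_size`` defaults to a fifth of the cell lines (30 of the standard
    150).
    """
    if n_cell_lines < 10 or n_genes < 10:
        raise ValueError("null dataset requires at least 10 x 10")
    if mask_size is None:
        mask_size = n_cell_lines // 5
    bf = bf_params or BFParams()
    streams = _streams(seed, ["values", "masks"])
    rng = streams["values"]
    essential = rng.random((n_genes, n_cell_lines)) < bf.background_essential_rate
    values = np.where(
        essential,
        rng.normal(bf.essential_mean, bf.essential_sd, (n_genes, n_cell_lines)),
        rng.normal(bf.nonessential_mean, bf.nonessential_sd, (n_genes, n_cell_lines)),
    )
    fm = FitnessMatrix(
        pd.DataFrame(values, index=pd.Index(_gene_ids(n_genes), name="gene"), columns=_cell_line_ids(n_cell_lines))
    )
    mrng = streams["masks"]
    masks = {}
    for k in range(n_masks):
        chosen = mrng.choice(n_cell_lines, size=mask_size, replace=False)
        m = np.zeros(n_cell_lines, dtype=bool)
        m[chosen] = True
        masks[f"null_context_{k}"] = m
    return fm, masks
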