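# contextnet

Context-dependent rewiring of CRISPR coessentiality networks, plus
elastic-net biomarkers of gene essentiality.

## The problem

Genome-wide CRISPR screens across hundreds of cancer cell lines yield, for
every gene, a knockout-fitness profile (here: log Bayes Factors, BF, where
positive values mean the knockout impairs growth). Genes whose profiles
correlate across lines tend to work together — the *coessentiality* network —
but a global correlation integrates over every genotype and lineage in the
panel and can hide interactions that exist only in a subset of lines
(a mutant oncogene's addiction module, a tissue-specific maturation factor).

`contextnet` implements two linked analyses for this problem:

1. **Which binary contexts drive essentiality?** For each variably essential
   gene *g*, fit an elastic-net logistic regression of its binarized
   essentiality call (essential ⇔ BF ≥ 10) on binary context features
   (per-gene GOF/LOF mutation status, lineage and other metadata one-hots,
   an epithelial/mesenchymal CDH1−VIM expression state):

   logit P(essential_g) = β₀ + Σⱼ βⱼ xⱼ,  elastic-net penalty with L1 ratio 0.25.

   A positive βⱼ means the gene tends to be essential where feature *j* is
   present; |β| > 1.2 is called a strong association.

2. **Which interactions depend on a context?** For a context with *n* member
   lines, each gene pair's rewiring is the leave-one-out differential
   Pearson correlation of quantile-normalized BF profiles:

   dPCC = PCC_all − PCC_~context

   where PCC_~context excludes the *n* context lines. dPCC > 0 is a gain of
   interaction (GOI: the correlation needs the context lines), dPCC < 0 a
   loss of interaction (LOI: removing them improves it). Significance is
   empirical: remove *n* random lines, recompute dPCC, repeat B = 1000
   times, and report the two-sided empirical P (resolution 1/B = 0.001).

A seeded synthetic-data generator emulates all four input tables with known
planted ground truth, so the entire pipeline is testable end to end without
any external download.

## Worked example

```python
from contextnet import (SimulationConfig, ContextSpec, EdgePlant, EssentialityPlant,
                        simulate_dataset, build_feature_table,
                        EssentialityRegression, DifferentialNetwork)

cfg = SimulationConfig(
    n_cell_lines=150, n_genes=200, seed=7,
    contexts=(ContextSpec("KRAS_GOF", 30, "GOF"),),
    planted_essentiality=(EssentialityPlant("G0001", "KRAS_GOF", "+", 0.95),),
    planted_edges=(EdgePlant("G0010", "G0011", "KRAS_GOF", "GOI", r_in=0.8),),
)
fitness, meta, muts, expr, truth = simulate_dataset(cfg)

features, _ = build_feature_table(muts, expr, meta, fitness.cell_line_ids, seed=0)
reg = EssentialityRegression(features, fitness).fit(["G0001"])
print(reg.coefficients["G0001"].round(2).to_string())

net = DifferentialNetwork(fitness, {"KRAS_GOF": features.mask("KRAS_GOF")})
result = net.fit(B=1000, seed=1)
print(result.summary())
print(result.edge_table().sorted().head(3).to_string(index=False))
```

prints

```
feature
KRAS_GOF            4.00
lineage:filler_a   -0.42
lineage:filler_b    0.23
lineage:filler_c    0.00

Differential coessentiality network
===================================
genes x cell lines: 200 x 150
contexts tested:    1
bootstrap B:        1000 (P resolution 0.001)
alpha:              0.001
GOI edges:          40
LOI edges:          106

geneA geneB  context  n_context  pcc_all  pcc_excl     dpcc  p_emp class
G0010 G0011 KRAS_GOF         30 0.919866 -0.002054 0.921920  0.001   GOI
G0001 G0010 KRAS_GOF         30 0.620487  0.013560 0.606927  0.001   GOI
G0001 G0011 KRAS_GOF         30 0.666116  0.072714 0.593402  0.001   GOI
```

Reading the output: the planted biomarker `KRAS_GOF` dominates gene G0001's
regression (β = 4.0, far above the 1.2 strong-association cut; the filler
lineage features pick up only noise-level weight). In the network, the
planted pair G0010–G0011 is the top edge: correlated 0.92 over all lines but
essentially uncorrelated once the 30 KRAS-mutant lines are excluded
(dPCC ≈ 0.92, P at the 0.001 bootstrap floor) — a gain of interaction.
G0001's own edges with the pair are real too: all three genes are essential
specifically in the context lines, so their profiles covary there. Of the
remaining ~20k null pairs, roughly the expected handful reach P ≤ 0.001 by
chance at 1/B resolution.

A configuration-driven CLI chains the stages on files instead:

```sh
contextnet all --config cfg.yaml --out runs/demo --seed 11
# stages: simulate | features | regress | diffnet | all
```

Each stage writes TSV artifacts plus a provenance JSON (config hash, seed,
shapes); re-running with the same config and seed reproduces byte-identical
outputs.

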