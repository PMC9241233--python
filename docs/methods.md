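# Methods

## Inputs and their in-memory form

Four tab-separated tables drive the pipeline, mirroring the public cancer
dependency-map dialects:

* **Fitness matrix** — genes × cell lines of log Bayes Factors (BF), the
  log-odds that a gene's knockout impairs growth in that line. Genes with
  any missing value are dropped on load and recorded. Raw BF is the
  substrate of essentiality calls; quantile-normalized BF of all correlation
  work.
* **Mutation calls** — long-form records with columns for gene symbol,
  cell-line ID, variant annotation and TCGA/COSMIC hotspot flags (header
  names are remappable).
* **Expression matrix** — genes × cell lines of log-TPM; only CDH1 and VIM
  are consumed, for the EMT state.
* **Sample metadata** — per-line categorical fields `lineage`,
  `lineage_subtype`, `lineage_sub_subtype`, `culture_type`, `sex`.

## Binary context features

* **LOF / GOF lesions.** A cell line carries `GENE_LOF` if any lesion of
  that gene is annotated `damaging`, and `GENE_GOF` if any lesion is a TCGA
  or COSMIC hotspot *and* annotated `other non-conserving`. The hotspot rule
  is read as a conjunction — (TCGA ∨ COSMIC) ∧ "other non-conserving" —
  which is the reading consistent with how activating hotspot lesions are
  annotated in these tables. Lesions matching neither rule contribute
  nothing.
* **EMT state.** r = logTPM(CDH1) − logTPM(VIM); `CDH_VIM_hi` iff r > 1,
  `CDH_VIM_lo` iff r < −4, both strict. Lines in the midzone, or absent from
  the expression table, are 0 in both — the matrix stays binary rather than
  acquiring missing values.
* **Metadata one-hots.** One feature per (field, value) pair, named
  `field:value`; missing entries contribute 0 everywhere.
* **Support filter.** Features describing fewer than 7 lines (i.e. six or
  fewer) are removed: below that, neither a regression coefficient nor a
  leave-one-out correlation change is interpretable.
* **De-duplication.** Features are visited in support-descending,
  name-ascending order; whenever two live features have Pearson correlation
  ≥ 0.9 the lower-support one is discarded (ties broken by a seeded RNG),
  and a (kept, discarded, PCC) log is returned. The traversal order is a
  package choice — any order satisfies the "no surviving pair ≥ 0.9"
  postcondition, but a fixed order makes survivors reproducible.
  Zero-variance features are dropped first, since their PCC is undefined.
  Only strongly *positive* correlation triggers removal; complementary
  (negatively correlated) features are both kept, as in the source data
  dialect.

## Essentiality regression

Essential ⇔ BF ≥ 10 (boundary inclusive), on raw BF only. Response genes are
those essential in between 1% and 80% of lines, both bounds inclusive —
genes outside the band are invariant and carry no context signal. Each
response gene is fitted independently:

* scikit-learn `LogisticRegression`, saga solver, elastic net with
  L1 ratio 0.25, inverse regularization strength C = 1.0, tolerance 1e-4,
  max 5000 iterations. Non-convergence is recorded on the result, not
  raised; a single-class response is collected into a failure report when
  fitting in bulk.
* Predictors are not standardized (they are already 0/1, so coefficients are
  directly comparable log-odds shifts) and classes are not re-weighted.
* C is exposed because coefficient magnitudes — and therefore the strong-
  association cut |β| > 1.2 (strict) — are only meaningful relative to the
  regularization strength.
* `fisher_association` provides the classical two-sided Fisher exact test of
  a lesion vector against a dependency vector as an orthogonal screen; the
  odds ratio uses a 0.5 continuity correction only when a table cell is zero
  (flagged).

**The intercept property.** With informative features absent, the fitted
intercept converges to logit of the gene's background essentiality rate
(the intercept is unpenalized). At full scale this holds gene by gene,
because thousands of low-support features are individually L1-zeroed. At
desk scale (tens of genes × a handful of support-30–40 features over 200
lines) the hypergeometric tail guarantees some unplanted gene a chance
feature overlap with |β| ≈ 0.6–0.9, whose intercept legitimately
compensates. The property is therefore validated at population level — the
median unplanted gene's |intercept − logit(background)| stays well under
0.2 — rather than as a per-gene bound.

## Quantile normalization

Rank-mean normalization without a reference distribution: within each cell
line, the value at rank r is replaced by the mean over lines of their rank-r
values, after which every line shares the same sorted values. Ties within a
line receive the mean of the rank-mean values across the tied span. Two
numerical details:

* When all columns already share their sorted values (e.g. a repeated
  application), the reference is taken as that common column directly, so
  normalization is idempotent *exactly* rather than to 1 ulp of the mean.
* Normalizing against a bimodal BF reference stretches the upper tail:
  small rank differences near the essential/nonessential boundary map to
  large value differences. This is faithful to the method — and is one
  reason the leave-one-out statistic responds to coherent outlier blocks.

## Leave-one-out dPCC and the bootstrap null

For a context mask with n member lines (1 ≤ n < N, and N − n ≥ 3):

* `PCC_all` — all-by-all Pearson correlation of normalized profiles over all
  N lines; computed once and shared by every context.
* `PCC_~context` — the same excluding the n context lines.
* `dPCC = PCC_all − PCC_~context`, elementwise. Positive = gain of
  interaction (GOI), negative = loss (LOI).

A gene with zero variance over the included lines (constancy is detected via
the range, since floating-point `std` of a constant row can be ~1e-17 rather
than 0) gets correlation 0 with everything, flagged; flagged pairs never
become edges. Correlations are clipped to [−1, 1].

**Null.** Remove n lines uniformly at random (without replacement within a
replicate, independent across replicates), recompute dPCC against the same
`PCC_all`, repeat B = 1000 times. One shared set of removals serves all
pairs within a context. Counters stream: per tracked pair only
#{dPCC_rand ≥ dPCC_obs} and #{dPCC_rand ≤ dPCC_obs} are kept (ties count in
both), so memory is O(pairs) regardless of B. The tracked pair universe is
either all pairs or a |dPCC|-screened subset (`screen_abs_dpcc`), recorded
in provenance; at the desk scales used here all pairs are affordable.

**Two-sided empirical P.** p = min(1, 2·min(count_ge, count_le)/B), floored
at 1/B. The null is sampled, so P is discrete in steps of 1/B and can never
be 0; B = 1000 gives the 0.001 resolution used for edge calls. No
multiple-testing correction is applied across pairs or contexts — edges are
reported at raw empirical P ≤ α (default 0.001), with an optional
|dPCC| ≥ `min_abs_dpcc` magnitude cut (default 0). Output edges use
lexicographic gene-pair ordering and are ranked by |dPCC|.

Pearson's sensitivity to outliers is deliberate: a functionally coherent
subset of lines (mutants of one oncogene, one tissue) can dominate a
correlation, and removing exactly that subset is what the statistic
measures. Rank-based correlations would suppress the very signal sought, so
none is offered.

## Synthetic data

The generator emulates the statistical shape of the real inputs, with all
randomness flowing from one master seed through named seed-sequence streams
(membership, mutations, expression, fitness, edges), so each sub-draw is
independently reproducible.

* **BF model.** Two components: nonessential ~ Normal(−5, 3), essential ~
  Normal(25, 8), essential with background probability 0.1. The components
  straddle the BF ≥ 10 cut with realistic overlap — which means a
  penetrance-1.0 essentiality plant binarizes to an in-context essential
  fraction *near* 1 (the essential component dips below the cut in ~3% of
  draws), not exactly 1.
* **Contexts** are realized so the feature-engineering rules recover the
  planted masks bit-exactly: GOF contexts as hotspot "other non-conserving"
  lesions, LOF as "damaging" lesions, EMT contexts as CDH1/VIM ratios beyond
  the thresholds, metadata contexts as labels. Filler metadata labels are
  drawn from three generic values per field rather than one shared value: a
  single filler would be the exact complement of a lone context feature and
  alias it in regression models, which real many-category metadata does not
  do.
* **Essentiality plants** set a gene's component inside (direction `+`) or
  outside (`-`) its context with the given penetrance, background rate
  elsewhere.
* **Edge plants** realize context-coherent essentiality blocks: a GOI pair
  is co-essential inside the context and quiet outside; a LOI pair is
  co-essential outside with a discordant context block (one gene essential,
  the other not). A shared latent factor then sets the within-subset
  correlation to `r_in` (and `r_out` outside). The block structure is
  essential, not cosmetic: the leave-one-out statistic detects coherent
  outlier structure, and a mean-free latent correlation confined to 30 of
  150 lines is only marginally detectable against the bootstrap null at
  this scale (measured: misses P ≤ 0.001 in a quarter of runs even at
  r_in = 0.95, whereas coherent blocks are recovered at the floor in every
  run). Realized within/outside sample correlations are reported in the
  ground truth. Genes carrying an explicit essentiality plant keep that
  plant's layout.
* **Null datasets** are i.i.d. two-component draws with zero planted
  structure plus random masks — the calibration substrate, since any mask
  over exchangeable columns must yield uniform empirical p-values.

What the generator does **not** emulate: the empirical BF distribution's
skew and screen-quality variation, gene-gene covariance beyond the planted
edges, copy-number/fusion/methylation features, and realistic
mutation-per-gene rates. Passing tests therefore demonstrate the machinery
and its calibration, not performance on real screens.

## Validation design and problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic data at
desk scale, chosen to keep the full suite under a minute while preserving
the regimes of interest:

* dPCC arithmetic on the published RAS/RAF and PI3K pathway correlation
  pairs (exact).
* Null calibration: 150 lines × 200 genes, a random 30-line context,
  B = 1000. The fraction of tracked pairs with p ≤ 0.05 is checked against
  the 99% binomial interval using 100 gene-disjoint pairs — pairs sharing
  the observed removal and the replicate set are positively dependent, so a
  binomial reference is only valid for a near-independent subset.
* Planted-edge recovery: 30-of-150-line context, r_in = 0.8, B = 1000, all
  ~20k pairs tracked, five independent simulations; every planted GOI/LOI
  edge must be called at p ≤ 0.001 with the correct sign.
* Regression recovery: 200 lines, three contexts of support 30–40, plants at
  penetrance 0.9–0.95; planted features must take the top |β| > 1.2 with
  the planted sign.
* Oracle equivalence: streaming bootstrap counters vs a store-all-replicates
  oracle (10 genes × 40 lines, B = 200, exact); correlations vs the direct
  two-pass formula (≤ 1e-12); quantile-normalization idempotence (exact).

The published full-scale counts (≈2918 features, 2987 response genes, 393
strong features, thousands of GOI/LOI events) require the complete
dependency-map and cell-line-encyclopedia releases and are out of scope
here; the property checks above are the desk-scale substitute.

## Known limitations

* Bootstrap cost scales as B × pairs × lines; full 18k-gene matrices at
  B = 1000 per context are a cluster-scale computation. The streaming
  counters and the |dPCC| screening cut are the levers provided.
* The regression's coefficient scale (and so the 1.2 cut) depends on C;
  comparisons across C values are not meaningful.
* Empirical P-values are floored at 1/B: "P = 0.001" means "at or beyond
  the resolution of 1000 replicates", not a point estimate.
* Contexts are tested marginally; overlapping contexts (e.g. a lineage that
  is also mutation-enriched) are not deconfounded.
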