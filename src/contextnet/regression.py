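"""Elastic-net logistic regression of binarized gene essentiality on binary contexts.

Each response gene's essentiality profile across cell lines (essential iff
log Bayes Factor >= 10) is regressed independently on the same table of binary
context features with an elastic-net penalty (L1 ratio 0.25).  The L1
component drives most coefficients to zero, so a model reduces to a short
list of contexts: a positive coefficient means the gene tends to be essential
where the feature is present (oncogene addiction, paralog loss), a negative
coefficient essential where it is absent.  Feature-gene pairs with
|coefficient| above a cut (default 1.2) are called strong associations.

Predictors are left unstandardized: they are already on a common 0/1 scale,
so coefficients are directly comparable log-odds shifts.  No class
re-weighting is applied.  Regularization strength is exposed as the sklearn
inverse-strength ``C`` (default 1.0); coefficient magnitudes — and therefore
the strong-association cut — are interpreted relative to that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import fisher_exact
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .features import FeatureTable
from .io import FitnessMatrix

__all__ = [
    "EssentialityMatrix",
    "GeneModel",
    "AssociationResult",
    "binarize_essentiality",
    "select_response_genes",
    "fit_gene_model",
    "fit_all_models",
    "select_strong_associations",
    "fisher_association",
    "EssentialityRegression",
    "EssentialityRegressionResults",
]


@dataclass(frozen=True)
class EssentialityMatrix:
    """Binary essential/nonessential calls per gene and cell line."""

    values: pd.DataFrame  # genes x cell lines, {0,1}
    threshold: float

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("essentiality calls must be binary")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneModel:
    """One fitted per-gene logistic model: coefficients are log-odds units."""

    response_gene: str
    coefficients: pd.Series  # indexed by feature name
    intercept: float
    l1_ratio: float
    C: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficients.to_numpy()).all() or not np.isfinite(self.intercept):
            raise ValueError(f"non-finite fit for gene {self.response_gene}")


@dataclass(frozen=True)
class AssociationResult:
    """Fisher exact test of a binary feature against a binary essentiality vector."""

    feature_name: str
    gene: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, feat only], [ess only, neither]]
    odds_ratio: float
    p_value: float
    degenerate: bool = False
    continuity_corrected: bool = False


def binarize_essentiality(fm: FitnessMatrix, threshold: float = 10.0) -> EssentialityMatrix:
    """Call a gene essential in a cell line iff its raw BF >= ``threshold``."""
    if fm.normalized:
        raise ValueError("essentiality must be binarized from raw, not quantile-normalized, BF")
    return EssentialityMatrix((fm.values >= threshold).astype("int8"), threshold)


def select_response_genes(
    em: EssentialityMatrix, min_frac: float = 0.01, max_frac: float = 0.80
) -> list[str]:
    """Keep variably essential genes: essential fraction in [min_frac, max_frac].

    Genes essential in fewer than 1% or more than 80% of lines carry little
    signal for context modelling and are excluded; both bounds are inclusive.
    """
    if em.values.shape[1] == 0:
        raise ValueError("essentiality matrix has no cell lines")
    frac = em.values.mean(axis=1)
    keep = (frac >= min_frac) & (frac <= max_frac)
    return list(em.values.index[keep])


def fit_gene_model(
    ft: FeatureTable,
    response: np.ndarray | pd.Series,
    *,
    gene: str = "gene",
    l1_ratio: float = 0.25,
    C: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> GeneModel:
    """Fit one elastic-net logistic model of a gene's essentiality vector.

    The saga solver is deterministic here (no internal sampling with these
    settings); non-convergence is reported on the result, not raised.
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != len(ft.cell_line_ids):
        raise ValueError("response length must equal the number of cell lines")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"gene {gene!r}: response has a single class; cannot fit")
    X = ft.values.to_numpy().astype(float)
    model = LogisticRegression(
        solver="saga",
        l1_ratio=l1_ratio,
        C=C,
        tol=tol,
        max_iter=max_iter,
        random_state=0,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
            converged = False
    coef = pd.Series(model.coef_[0], index=ft.feature_names)
    return GeneModel(gene, coef, float(model.intercept_[0]), l1_ratio, C, converged)


def fit_all_models(
    ft: FeatureTable,
    em: EssentialityMatrix,
    genes: Sequence[str],
    *,
    l1_ratio: float = 0.25,
    C: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Fit every response gene independently; returns (coefficients, intercepts, failures).

    Coefficients come back as a features x genes matrix.  A gene whose fit is
    impossible (single-class response) is recorded in ``failures`` rather than
    aborting the run; its column is omitted.
    """
    missing = [g for g in genes if g not in set(em.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from essentiality matrix: {missing[:5]}")
    em_vals = em.values[ft.cell_line_ids] if list(em.cell_line_ids) != list(ft.cell_line_ids) else em.values
    cols: dict[str, pd.Series] = {}
    intercepts: dict[str, float] = {}
    failures: dict[str, str] = {}
    for gene in genes:
        try:
            gm = fit_gene_model(
                ft, em_vals.loc[gene].to_numpy(), gene=gene, l1_ratio=l1_ratio, C=C, tol=tol, max_iter=max_iter
            )
        except ValueError as err:
            failures[gene] = str(err)
            continue
        cols[gene] = gm.coefficients
        intercepts[gene] = gm.intercept
    coef = pd.DataFrame(cols, index=pd.Index(ft.feature_names, name="feature"))
    return coef, pd.Series(intercepts, dtype=float), failures


def select_strong_associations(cm: pd.DataFrame, cut: float = 1.2) -> tuple[pd.DataFrame, list[str]]:
    """Flatten a coefficient matrix and keep |coeff| strictly above ``cut``.

    Returns the (feature, gene, coeff) list sorted by |coeff| descending and
    the set of unique features with at least one strong association.
    """
    if cm.size == 0:
        empty = pd.DataFrame(columns=["feature", "gene", "coeff"])
        return empty, []
    long = cm.stack().rename("coeff").reset_index()
    long.columns = ["feature", "gene", "coeff"]
    strong = long[long["coeff"].abs() > cut].copy()
    strong["_a"] = strong["coeff"].abs()
    strong = strong.sort_values(["_a", "feature", "gene"], ascending=[False, True, True], kind="mergesort")
    strong = strong.drop(columns="_a").reset_index(drop=True)
    return strong, sorted(strong["feature"].unique())


def fisher_association(feature: np.ndarray | pd.Series, essential: np.ndarray | pd.Series) -> AssociationResult:
    """Two-sided Fisher exact test between a lesion vector and a dependency vector.

    The 2x2 table is [[feature & essential, feature & not], [no-feature &
    essential, neither]].  A degenerate (constant) vector gives P = 1 with a
    flag; the odds ratio uses a 0.5 continuity correction only when a table
    cell is zero, also flagged.
    """
    f = np.asarray(feature).astype(bool)
    e = np.asarray(essential).astype(bool)
    if f.shape != e.shape:
        raise ValueError("feature and essentiality vectors must have equal length")
    a = int(np.sum(f & e))
    b = int(np.sum(f & ~e))
    c = int(np.sum(~f & e))
    d = int(np.sum(~f & ~e))
    table = ((a, b), (c, d))
    if f.all() or (~f).all() or e.all() or (~e).all():
        return AssociationResult("feature", "gene", table, float("nan"), 1.0, degenerate=True)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        odds = a * d / (b * c)
        corrected = False
    return AssociationResult("feature", "gene", table, float(odds), float(p), continuity_corrected=corrected)


class EssentialityRegression:
    """Model: binarized gene essentiality regressed on binary context features.

    Parameters
    ----------
    features : FeatureTable
        Cell-line x feature binary predictors (post filtering/dedup).
    fitness : FitnessMatrix
        Raw (unnormalized) log Bayes Factors; binarized internally.
    bf_threshold : float
        Essentiality call threshold in BF units.
    min_frac, max_frac : float
        Variable-essentiality band for response-gene selection.
    l1_ratio, C : float
        Elastic-net mixing parameter and inverse regularization strength.
    """

    def __init__(
        self,
        features: FeatureTable,
        fitness: FitnessMatrix,
        *,
        bf_threshold: float = 10.0,
        min_frac: float = 0.01,
        max_frac: float = 0.80,
        l1_ratio: float = 0.25,
        C: float = 1.0,
        tol: float = 1e-4,
        max_iter: int = 5000,
    ) -> None:
        shared = [cl for cl in features.cell_line_ids if cl in set(fitness.cell_line_ids)]
        if len(shared) < 2:
            raise ValueError("feature table and fitness matrix share fewer than 2 cell lines")
        discarded = (set(features.cell_line_ids) | set(fitness.cell_line_ids)) - set(shared)
        if discarded:
            warnings.warn(
                f"restricting to the {len(shared)}-line intersection; discarding {sorted(discarded)[:5]}...",
                stacklevel=2,
            )
        self.features = features.select(features.feature_names) if not discarded else FeatureTable(
            features.values.loc[shared], features.categories
        )
        self.fitness = fitness.with_values(fitness.values[shared])
        self.essentiality = binarize_essentiality(self.fitness, bf_threshold)
        self.response_genes = select_response_genes(self.essentiality, min_frac, max_frac)
        self.l1_ratio = l1_ratio
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, genes: Sequence[str] | None = None) -> "EssentialityRegressionResults":
        genes = self.response_genes if genes is None else list(genes)
        coef, intercepts, failures = fit_all_models(
            self.features,
            self.essentiality,
            genes,
            l1_ratio=self.l1_ratio,
            C=self.C,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        return EssentialityRegressionResults(self, coef, intercepts, failures)


@dataclass
class EssentialityRegressionResults:
    """Fitted coefficient matrix plus extraction and diagnostic helpers."""

    model: EssentialityRegression
    coefficients: pd.DataFrame  # features x genes
    intercepts: pd.Series
    failures: dict[str, str] = field(default_factory=dict)

    def strong_associations(self, cut: float = 1.2) -> tuple[pd.DataFrame, list[str]]:
        return select_strong_associations(self.coefficients, cut)

    def background_rates(self) -> pd.Series:
        """Observed essential fraction per fitted gene (the intercept's anchor)."""
        em = self.model.essentiality.values
        return em.loc[self.coefficients.columns].mean(axis=1)

    def intercept_vs_background(self) -> pd.DataFrame:
        """Fitted intercept against logit of the background essentiality rate."""
        rates = self.background_rates()
        return pd.DataFrame(
            {"intercept": self.intercepts, "logit_background": logit(rates.clip(1e-12, 1 - 1e-12))}
        )

    def fisher_tests(self, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
        """Fisher exact P per (feature, gene) pair for concordance checks."""
        rows = []
        em = self.model.essentiality.values
        for feat, gene in pairs:
            res = fisher_association(self.model.features.values[feat], em.loc[gene, self.model.features.cell_line_ids])
            rows.append((feat, gene, res.p_value, res.odds_ratio, res.degenerate))
        return pd.DataFrame(rows, columns=["feature", "gene", "p_value", "odds_ratio", "degenerate"])

    def summary(self, cut: float = 1.2) -> str:
        strong, feats = self.strong_associations(cut)
        nonzero = int((self.coefficients.to_numpy() != 0).sum())
        lines = [
            "Essentiality elastic-net regression",
            "===================================",
            f"cell lines:            {len(self.model.features.cell_line_ids)}",
            f"predictor features:    {self.model.features.n_features}",
            f"response genes fitted: {self.coefficients.shape[1]} (failed: {len(self.failures)})",
            f"l1_ratio / C:          {self.model.l1_ratio} / {self.model.C}",
            f"nonzero coefficients:  {nonzero}",
            f"strong |coeff| > {cut}: {len(strong)} associations over {len(feats)} features",
        ]
        return "\n".join(lines)
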