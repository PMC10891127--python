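"""The five-step clonal-signature filter chain and its evaluation battery.

Discovery runs, in order: (1) drop the lower half of genes by median
expression in the discovery cohort; (2) keep genes univariably associated
with survival (Cox p < 0.01); (3) intersect with the Q4 (clonal) genes of
the multi-region cohort; (4) keep genes with clustering concordance
coefficient > 0.2; (5) select a sparse core by lasso-Cox at a fixed
penalty and refit the selected genes unpenalized for final coefficients.
A sample's risk score is the dot product S = sum_i c_i * x_i over
signature genes (x_i = log2 expression); cohorts are stratified into
score tertiles for Kaplan-Meier / log-rank evaluation, with univariable
and covariate-adjusted Cox models on the continuous score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import concordance_coefficients, concordance_filter
from .expression import ExpressionMatrix, MultiRegionCohort, SurvivalCohort
from .heterogeneity import classify_q4, intertumor_scores, intratumor_scores
from .survival import (
    CoxFit,
    KMResult,
    cox_multivariable,
    cox_screen,
    cox_univariable,
    km_logrank,
    lasso_cox,
)

logger = logging.getLogger(__name__)

FILTER_STEPS = ("input", "expression_filter", "prognostic", "q4", "concordance", "lasso")


@dataclass
class DiscoveryParams:
    p_cutoff: float = 0.01
    concordance_cutoff: float = 0.2
    lam: float = 0.06
    B: int = 100
    n_restarts: int = 10
    seed: int = 0
    k_range: range | None = None


@dataclass
class Signature:
    """An ordered gene list with per-gene weights and filter provenance."""

    genes: list
    coefficients: pd.Series  # unpenalized refit on selected genes (log2 scale)
    penalized_coefficients: pd.Series  # the lasso solution, original scale
    provenance: dict  # step name -> gene count surviving that step
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficients.to_numpy()).all():
            raise ValueError("signature coefficients must be finite")
        if (self.coefficients == 0).any():
            raise ValueError("signature coefficients must be nonzero")
        counts = [self.provenance[s] for s in FILTER_STEPS if s in self.provenance]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("provenance counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.coefficients, "penalized": self.penalized_coefficients}
        ).loc[self.genes]


@dataclass
class RiskStratification:
    scores: pd.Series
    groups: pd.Series  # low / intermediate / high
    km: KMResult | None
    logrank_p: float | None
    cox_univariable: CoxFit | None
    cox_multivariable: CoxFit | None


def run_discovery(
    multiregion: MultiRegionCohort,
    discovery: SurvivalCohort,
    params: DiscoveryParams | None = None,
) -> Signature:
    """Execute the full filter chain and return the signature."""
    params = params or DiscoveryParams()
    expr = discovery.expression
    if expr.scale_tag != "log2":
        raise ValueError("discovery cohort expression must be log2-scaled")
    genes = expr.gene_ids
    provenance = {"input": len(genes)}

    # (1) expression filter: drop the floor(G/2) lowest-median genes
    med = expr.values.median(axis=1)
    n_drop = len(genes) // 2
    keep = med.sort_values(kind="stable", ascending=False).index[: len(genes) - n_drop]
    genes = [g for g in genes if g in set(keep)]
    provenance["expression_filter"] = len(genes)
    _require_nonempty(genes, "expression_filter")

    # (2) univariable Cox screen
    screen = cox_screen(
        expr.values.loc[genes].T, discovery.time, discovery.event
    )
    genes = screen.index[screen["p"] < params.p_cutoff].tolist()
    provenance["prognostic"] = len(genes)
    _require_nonempty(genes, "prognostic")

    # (3) intersect with Q4 genes of the multi-region cohort
    intra = intratumor_scores(multiregion)
    inter = intertumor_scores(multiregion, B=params.B, seed=params.seed)
    q4 = classify_q4(intra, inter)
    q4_genes = set(q4.index[q4])
    genes = [g for g in genes if g in q4_genes]
    provenance["q4"] = len(genes)
    _require_nonempty(genes, "q4")

    # (4) clustering concordance filter on the multi-region cohort
    conc = concordance_coefficients(
        multiregion,
        genes=genes,
        k_range=params.k_range,
        n_restarts=params.n_restarts,
        seed=params.seed,
    )
    genes = concordance_filter(conc, cutoff=params.concordance_cutoff)
    provenance["concordance"] = len(genes)
    _require_nonempty(genes, "concordance")

    # (5) lasso-Cox selection at fixed penalty, then unpenalized refit
    X = expr.values.loc[genes].T
    path = lasso_cox(X, discovery.time, discovery.event, lam=params.lam)
    selected = path.selected
    provenance["lasso"] = len(selected)
    _require_nonempty(selected, "lasso")
    refit = cox_multivariable(X[selected], discovery.time, discovery.event)
    coefficients = refit.summary["coef"].rename("coefficient")
    logger.info(
        "discovery chain: %s",
        " -> ".join(f"{s}:{provenance[s]}" for s in FILTER_STEPS),
    )
    return Signature(
        genes=list(selected),
        coefficients=coefficients,
        penalized_coefficients=path.coefficients[selected],
        provenance=provenance,
        lam=params.lam,
    )


def _require_nonempty(genes, step: str) -> None:
    if len(genes) == 0:
        raise ValueError(f"filter step {step!r} left no genes")


def score_samples(
    sig: Signature, m: ExpressionMatrix, impute_missing: str | None = None
) -> pd.Series:
    """Per-sample risk score S = sum_i c_i * x_i over signature genes.

    Missing signature genes are a hard error unless ``impute_missing="mean"``,
    in which case a missing gene's expression is imputed per sample as the
    mean log2 expression over all genes present in the matrix (a documented
    escape hatch for cross-platform validation cohorts).
    """
    if m.scale_tag != "log2":
        raise ValueError("risk scores require a log2-scaled matrix")
    missing = [g for g in sig.genes if g not in m.gene_ids]
    if missing and impute_missing is None:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    if missing:
        if impute_missing != "mean":
            raise ValueError(f"unknown imputation mode {impute_missing!r}")
        warnings.warn(f"mean-imputing {len(missing)} missing signature genes")
    present = [g for g in sig.genes if g not in missing]
    X = m.values.loc[present]
    scores = sig.coefficients[present] @ X
    if missing:
        fill = m.values.mean(axis=0)  # per-sample mean over available genes
        scores = scores + sig.coefficients[missing].sum() * fill
    return pd.Series(scores, index=m.sample_ids, name="score")


def tertile_stratify(scores: pd.Series) -> pd.Series:
    """Split samples into low/intermediate/high score tertiles by rank.

    Group sizes follow the rank split at the 1/3 and 2/3 boundaries and
    differ by at most one when scores are untied (remainders go to the
    lower groups); ties are broken by stable sample order.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 samples for tertiles")
    if scores.nunique() == 1:
        warnings.warn("all scores identical; assigning a single tertile group")
        return pd.Series("intermediate", index=scores.index, name="tertile")
    order = np.argsort(scores.to_numpy(), kind="stable")
    sizes = [len(a) for a in np.array_split(np.arange(n), 3)]
    labels = np.empty(n, dtype=object)
    bounds = np.cumsum([0] + sizes)
    for name, lo, hi in zip(("low", "intermediate", "high"), bounds[:-1], bounds[1:]):
        labels[order[lo:hi]] = name
    return pd.Series(labels, index=scores.index, name="tertile")


def evaluate(
    sig: Signature,
    cohort: SurvivalCohort,
    covariates: list[str] | None = None,
    impute_missing: str | None = None,
) -> RiskStratification:
    """Score a cohort, stratify into tertiles, and run the survival battery."""
    scores = score_samples(sig, cohort.expression, impute_missing=impute_missing)
    groups = tertile_stratify(scores)
    if groups.nunique() >= 2:
        km = km_logrank(groups, cohort.time, cohort.event)
        logrank_p = km.p
    else:
        km, logrank_p = None, None
    uni = cox_univariable(scores.rename("score"), cohort.time, cohort.event)

    multi = None
    if covariates:
        avail = []
        for c in covariates:
            if c not in cohort.clinical.table.columns:
                warnings.warn(f"covariate {c!r} absent; skipped")
                continue
            col = cohort.clinical.table[c]
            if col.nunique() <= 1:
                warnings.warn(f"covariate {c!r} is constant; dropped")
                continue
            avail.append(c)
        design = cohort.clinical.table[avail].copy()
        design.insert(0, "score", scores)
        multi = cox_multivariable(design, cohort.time, cohort.event)
    return RiskStratification(
        scores=scores,
        groups=groups,
        km=km,
        logrank_p=logrank_p,
        cox_univariable=uni,
        cox_multivariable=multi,
    )


def compare_score_by_group(
    scores: pd.Series,
    labels: pd.Series,
    test: str = "t",
    adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sided comparisons of scores between groups.

    ``test="t"`` is Welch's t test; ``test="wilcoxon"`` is the two-sample
    rank-sum (Mann-Whitney) test. Benjamini-Hochberg adjustment is off by
    default.
    """
    labels = pd.Series(labels).reindex(scores.index)
    groups = sorted(pd.unique(labels.dropna()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa = scores[labels == a].to_numpy()
            xb = scores[labels == b].to_numpy()
            if test == "t":
                stat, p = stats.ttest_ind(xa, xb, equal_var=False)
            elif test == "wilcoxon":
                stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append({"group_a": a, "group_b": b, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    return out
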