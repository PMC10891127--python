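"""Per-gene intratumor and intertumor heterogeneity scores and Q4 calls.

The intratumor score of a gene is the median, across patients, of the
sample standard deviation of its log2 expression over that patient's tumor
regions: low values mean the gene is expressed consistently within a tumor
(clonally). The intertumor score is a resampled cross-patient SD: one
region is drawn at random per patient, the SD of the resulting
single-region cohort is taken, and the draw is repeated B times (default
100) and averaged. Q4 genes sit in the quadrant with above-median
intertumor score but at-or-below-median intratumor score — high signal
between tumors, low sampling noise within a tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import MultiRegionCohort

logger = logging.getLogger(__name__)


@dataclass
class HeterogeneityProfile:
    """Per-gene scores and quadrant calls for one multi-region cohort."""

    table: pd.DataFrame  # index gene; columns intra, inter, q4
    B: int
    seed: int


def _patient_sample_indices(cohort: MultiRegionCohort) -> list[np.ndarray]:
    """Column indices of each patient's region samples, patients in cohort order."""
    cols = cohort.expression.sample_ids
    groups = []
    for p in cohort.patients:
        samples = cohort.sample_map.regions_of(p)
        idx = np.array([cols.get_loc(s) for s in samples])
        if len(idx) < 2:
            raise ValueError(f"patient {p!r} has fewer than 2 regions")
        groups.append(idx)
    return groups


def intratumor_scores(cohort: MultiRegionCohort) -> pd.Series:
    """Median over patients of the per-patient regional SD (ddof=1)."""
    if cohort.expression.scale_tag != "log2":
        raise ValueError("heterogeneity scores require log2-scaled expression")
    groups = _patient_sample_indices(cohort)
    X = cohort.expression.values.to_numpy()
    sds = np.column_stack([X[:, idx].std(axis=1, ddof=1) for idx in groups])
    return pd.Series(
        np.median(sds, axis=1), index=cohort.expression.gene_ids, name="intra"
    )


def intertumor_scores(
    cohort: MultiRegionCohort, B: int = 100, seed: int = 0
) -> pd.Series:
    """Mean over B random single-region cohorts of the cross-patient SD.

    Within an iteration the same region draw is shared by all genes, so
    cross-gene correlation structure is preserved.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if cohort.expression.scale_tag != "log2":
        raise ValueError("heterogeneity scores require log2-scaled expression")
    groups = _patient_sample_indices(cohort)
    X = cohort.expression.values.to_numpy()
    rng = np.random.default_rng(seed)
    total = np.zeros(X.shape[0])
    for _ in range(B):
        picked = np.array([idx[rng.integers(len(idx))] for idx in groups])
        total += X[:, picked].std(axis=1, ddof=1)
    return pd.Series(total / B, index=cohort.expression.gene_ids, name="inter")


def intertumor_scores_exact(cohort: MultiRegionCohort) -> pd.Series:
    """Exact expectation of the resampled intertumor score.

    Enumerates every combination of one region per patient (R^P cohorts)
    and averages the cross-patient SD. Feasible only for small cohorts;
    used as the closed-form reference for the Monte-Carlo estimator.
    """
    import itertools

    groups = _patient_sample_indices(cohort)
    X = cohort.expression.values.to_numpy()
    total = np.zeros(X.shape[0])
    n = 0
    for combo in itertools.product(*groups):
        total += X[:, list(combo)].std(axis=1, ddof=1)
        n += 1
    return pd.Series(total / n, index=cohort.expression.gene_ids, name="inter_exact")


def classify_q4(intra: pd.Series, inter: pd.Series) -> pd.Series:
    """Median-split quadrant call: inter > median AND intra <= median.

    Medians are taken over the gene set passed in, so the caller chooses
    the universe (all detected genes, or a filtered subset).
    """
    if not intra.index.equals(inter.index):
        raise ValueError("intra and inter score vectors are not aligned")
    flag = (inter > inter.median()) & (intra <= intra.median())
    return flag.rename("q4")


def heterogeneity_profile(
    cohort: MultiRegionCohort, B: int = 100, seed: int = 0
) -> HeterogeneityProfile:
    """Convenience wrapper: both scores plus the Q4 flag in one table."""
    intra = intratumor_scores(cohort)
    inter = intertumor_scores(cohort, B=B, seed=seed)
    q4 = classify_q4(intra, inter)
    table = pd.concat([intra, inter, q4], axis=1)
    logger.info(
        "heterogeneity: %d genes, %d Q4 (%.2f%%)",
        len(table), int(q4.sum()), 100 * q4.mean(),
    )
    return HeterogeneityProfile(table=table, B=B, seed=seed)
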