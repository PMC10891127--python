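"""Per-gene clustering concordance coefficient.

For one gene, all region samples are clustered on its expression value
alone (one-dimensional k-means). For each cluster count k the concordance
is the fraction of patients whose regions all land in the same cluster;
the coefficient is the mean concordance over k = 2..k_max (k_max defaults
to the number of patients). A clonally expressed gene keeps each tumor's
regions together at every granularity, so its coefficient is near 1.

The k-means here is a compact vectorized Lloyd's iteration specialized to
one dimension (best of ``n_restarts`` random starts by within-cluster sum
of squares); tests pin it against an exact dynamic-programming 1-D k-means
and against a general-purpose k-means implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import MultiRegionCohort

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Per-gene coefficient plus the per-k concordance values behind it."""

    coefficients: pd.Series  # gene -> mean concordance over k_range
    per_k: pd.DataFrame  # genes x k
    k_range: tuple[int, ...]
    n_restarts: int
    seed: int


def kmeans_1d(
    x: np.ndarray, k: int, n_restarts: int = 10, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Lloyd's k-means on a 1-D vector; returns labels of the best restart.

    The first restart starts from evenly spaced quantiles of the distinct
    values; the rest use k-means++-style weighted sampling. If fewer than k
    distinct values exist, all of them become centers (some clusters stay
    empty — every point still gets the nearest surviving center).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    best_labels, best_inertia = None, np.inf
    for restart in range(n_restarts):
        if len(uniq) <= k:
            centers = uniq.copy().astype(float)
        elif restart == 0:
            qs = (np.arange(k) + 0.5) / k
            centers = np.unique(np.quantile(uniq, qs))
            if len(centers) < k:  # quantile collisions; pad with extremes
                pad = np.setdiff1d(uniq, centers)
                centers = np.sort(
                    np.concatenate([centers, pad[: k - len(centers)]])
                )
        else:
            centers = _kpp_init(uniq, k, rng)
        for _ in range(300):
            labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
            new_centers = centers.copy()
            for j in range(len(centers)):
                pts = x[labels == j]
                if len(pts):
                    new_centers[j] = pts.mean()
            if np.array_equal(new_centers, centers):
                break
            centers = new_centers
        inertia = float(((x - centers[labels]) ** 2).sum())
        if inertia < best_inertia - 1e-12:
            best_inertia, best_labels = inertia, labels
        if len(uniq) <= k:
            break  # deterministic start; restarts are identical
    return best_labels


def _kpp_init(uniq: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding over the distinct values."""
    centers = [rng.choice(uniq)]
    for _ in range(k - 1):
        d2 = np.min(np.abs(uniq[:, None] - np.array(centers)[None, :]), axis=1) ** 2
        total = d2.sum()
        if total == 0:
            remaining = np.setdiff1d(uniq, centers)
            centers.append(rng.choice(remaining) if len(remaining) else centers[0])
        else:
            centers.append(rng.choice(uniq, p=d2 / total))
    return np.array(centers, dtype=float)


def _patient_groups(cohort: MultiRegionCohort) -> list[np.ndarray]:
    cols = cohort.expression.sample_ids
    groups = []
    for p in cohort.patients:
        samples = cohort.sample_map.regions_of(p)
        if len(samples) < 2:
            raise ValueError(f"patient {p!r} has fewer than 2 regions")
        groups.append(np.array([cols.get_loc(s) for s in samples]))
    return groups


def concordance_from_labels(labels: np.ndarray, groups: list[np.ndarray]) -> float:
    """Fraction of patients whose region samples all share one cluster label."""
    ok = sum(1 for idx in groups if len(set(labels[idx])) == 1)
    return ok / len(groups)


def concordance_coefficients(
    cohort: MultiRegionCohort,
    genes=None,
    k_range: range | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> ConcordanceResult:
    """Concordance coefficient for each requested gene.

    ``k_range`` defaults to 2..min(26, n_patients); k is additionally
    capped at the number of samples.
    """
    if cohort.expression.scale_tag != "log2":
        raise ValueError("concordance requires log2-scaled expression")
    genes = list(cohort.expression.gene_ids if genes is None else genes)
    groups = _patient_groups(cohort)
    n_samples = cohort.expression.shape[1]
    if k_range is None:
        k_range = range(2, min(26, len(groups)) + 1)
    ks = [k for k in k_range if 2 <= k <= n_samples]
    if not ks:
        raise ValueError("empty k range after capping at the sample count")
    X = cohort.expression.subset_genes(genes).values.to_numpy()
    rng = np.random.default_rng(seed)
    per_k = np.empty((len(genes), len(ks)))
    for gi in range(len(genes)):
        x = X[gi]
        n_uniq = len(np.unique(x))
        for ki, k in enumerate(ks):
            if k > n_uniq:
                logger.debug(
                    "gene %s: k=%d exceeds %d distinct values; empty clusters allowed",
                    genes[gi], k, n_uniq,
                )
            labels = kmeans_1d(x, k, n_restarts=n_restarts, rng=rng)
            per_k[gi, ki] = concordance_from_labels(labels, groups)
    coef = pd.Series(per_k.mean(axis=1), index=pd.Index(genes), name="concordance")
    return ConcordanceResult(
        coefficients=coef,
        per_k=pd.DataFrame(per_k, index=pd.Index(genes), columns=ks),
        k_range=tuple(ks),
        n_restarts=n_restarts,
        seed=seed,
    )


def concordance_filter(result: ConcordanceResult, cutoff: float = 0.2) -> list:
    """Genes whose coefficient strictly exceeds the cutoff (default 0.2)."""
    kept = result.coefficients.index[result.coefficients > cutoff].tolist()
    logger.info(
        "concordance filter (> %.3g): kept %d / %d genes",
        cutoff, len(kept), len(result.coefficients),
    )
    return kept
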