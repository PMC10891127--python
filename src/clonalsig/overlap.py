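"""Gene-set overlap enrichment and copy-number frequency profiles.

The overlap test asks whether two gene sets drawn from a common universe
share more members than chance under the hypergeometric distribution. The
tail sum is computed with log-space binomial coefficients, so p-values
remain exact far below double underflow of individual terms. Both tail
conventions are reported: ``p`` includes the observed overlap
(P(X >= k)), while ``p_phyper`` is the strict tail P(X > k) that R's
``phyper(k, ..., lower.tail=FALSE)`` returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


@dataclass
class OverlapTest:
    N: int  # universe size
    K: int  # size of set A
    n: int  # size of set B
    k: int  # observed overlap
    p: float  # P(X >= k)
    p_phyper: float  # P(X > k)
    enrichment_ratio: float  # k / (K * n / N)


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _upper_tail(N: int, K: int, n: int, k_from: int) -> float:
    """P(X >= k_from) for X ~ Hypergeometric(N, K, n), in log space."""
    hi = min(K, n)
    if k_from > hi:
        return 0.0
    ks = np.arange(k_from, hi + 1)
    logp = _log_choose(K, ks) + _log_choose(N - K, n - ks) - _log_choose(N, n)
    return float(np.exp(logsumexp(logp)))


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Exact one-sided (enrichment) hypergeometric overlap test."""
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(K, n):
        raise ValueError(f"overlap {k} exceeds min(K, n) = {min(K, n)}")
    if k < max(0, K + n - N):
        raise ValueError(f"overlap {k} below the minimum possible {max(0, K + n - N)}")
    p = min(_upper_tail(N, K, n, k), 1.0)
    p_strict = min(_upper_tail(N, K, n, k + 1), p)
    expected = K * n / N
    ratio = k / expected if expected > 0 else 0.0
    logger.info(
        "overlap test: N=%d K=%d n=%d k=%d -> p=%.4g (ratio %.3g)", N, K, n, k, p, ratio
    )
    return OverlapTest(N=N, K=K, n=n, k=k, p=p, p_phyper=p_strict, enrichment_ratio=ratio)


def overlap_from_sets(universe, set_a, set_b) -> OverlapTest:
    """Overlap test from explicit gene collections (restricted to the universe)."""
    uni = set(universe)
    a = set(set_a) & uni
    b = set(set_b) & uni
    return hypergeometric_overlap(len(uni), len(a), len(b), len(a & b))


@dataclass
class CnvFrequencyProfile:
    """Per-feature amplification/deletion frequencies in one cohort."""

    table: pd.DataFrame  # index gene or band; columns amp_freq, del_freq
    n_samples: int


def cnv_frequencies(
    cnv: pd.DataFrame, amp_threshold: float = 0.3, del_threshold: float = -0.3
) -> CnvFrequencyProfile:
    """Fraction of samples amplified / deleted per gene.

    Accepts either discrete calls in {-1, 0, +1} or real-valued scores;
    with the default thresholds (+0.3 / -0.3) the two representations
    agree on pre-thresholded data.
    """
    if not del_threshold < 0 < amp_threshold:
        raise ValueError("thresholds must satisfy del < 0 < amp")
    V = cnv.to_numpy(dtype=float)
    if not np.isfinite(V).all():
        raise ValueError("CNV matrix contains non-finite entries")
    n = cnv.shape[1]
    amp = (V >= amp_threshold).mean(axis=1)
    dele = (V <= del_threshold).mean(axis=1)
    table = pd.DataFrame({"amp_freq": amp, "del_freq": dele}, index=cnv.index)
    return CnvFrequencyProfile(table=table, n_samples=n)


def band_aggregate(
    profile: CnvFrequencyProfile, band_map: pd.Series
) -> CnvFrequencyProfile:
    """Aggregate gene-level frequencies to chromosome bands (unweighted mean)."""
    mapped = profile.table.index.intersection(band_map.index)
    unmapped = len(profile.table) - len(mapped)
    if unmapped:
        logger.info("band aggregation: %d unmapped genes excluded", unmapped)
    sub = profile.table.loc[mapped]
    bands = band_map.loc[mapped]
    agg = sub.groupby(bands.to_numpy()).mean()
    agg.index.name = "band"
    return CnvFrequencyProfile(table=agg, n_samples=profile.n_samples)


def correlate_profiles(
    a: pd.Series, b: pd.Series, method: str = "spearman"
) -> tuple[float, float]:
    """Rank correlation of two frequency profiles over their shared keys."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared keys to correlate")
    if method == "spearman":
        r, p = stats.spearmanr(a.loc[shared], b.loc[shared])
    elif method == "pearson":
        r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
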