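"""Synthetic cohorts with known ground truth.

The generator emulates the study design the pipeline targets: a small
multi-region cohort (P patients, R anatomical regions each) in which a
fraction of genes is *clonal* — expression set once per tumor, so the
between-patient spread dominates the within-patient spread — a fraction is
*subclonal* (the reverse), and the rest is null noise. A separate
single-region survival cohort draws times from an exponential-baseline Cox
model driven by a planted subset of the clonal genes plus clinical
covariates, so every filter in the discovery chain has ground truth to
recover.

All values are generated directly on the log2 expression scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import (
    ClinicalTable,
    ExpressionMatrix,
    MultiRegionCohort,
    SampleMap,
    SurvivalCohort,
)

logger = logging.getLogger(__name__)

GENE_CLASSES = ("clonal", "subclonal", "null")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the target design: 26 patients with 3 tumor regions
    each. ``sigma_b`` and ``sigma_w`` are the between-patient and
    within-patient standard deviations of log2 expression per gene class;
    clonal genes have ``sigma_w << sigma_b`` and subclonal genes the
    reverse. ``beta_scale`` is the log-hazard per unit log2 expression for
    each of the ``n_prognostic_clonal`` planted prognostic genes.
    """

    n_patients: int = 26
    regions_per_patient: int = 3
    n_genes: int = 2000
    class_fractions: dict = field(
        default_factory=lambda: {"clonal": 0.2, "subclonal": 0.2, "null": 0.6}
    )
    sigma_b: dict = field(
        default_factory=lambda: {"clonal": 1.5, "subclonal": 0.1, "null": 0.3}
    )
    sigma_w: dict = field(
        default_factory=lambda: {"clonal": 0.1, "subclonal": 1.5, "null": 0.3}
    )
    mean_low: float = 2.0
    mean_high: float = 10.0
    n_prognostic_clonal: int = 20
    beta_scale: float = 0.5
    baseline_hazard: float = 1.0 / 365.0
    censoring_rate: float = 0.3
    covariate_betas: dict = field(default_factory=dict)  # e.g. {"age": 0.02}
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        if set(self.class_fractions) != set(GENE_CLASSES):
            raise ValueError(f"class fractions must cover {GENE_CLASSES}")
        for d in (self.sigma_b, self.sigma_w):
            if any(v < 0 for v in d.values()):
                raise ValueError("sigma values must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        if self.regions_per_patient < 2:
            raise ValueError("regions_per_patient must be >= 2")


@dataclass
class GroundTruth:
    """What the generator planted: per-gene class, per-gene beta, gene means."""

    gene_class: pd.Series  # gene -> {clonal, subclonal, null}
    beta: pd.Series  # gene -> true log-hazard coefficient (0 for non-prognostic)
    gene_mean: pd.Series  # gene -> mu_g
    linear_predictor: pd.Series | None = None  # per-sample, set by the survival draw

    def __post_init__(self) -> None:
        if not self.gene_class.index.equals(self.beta.index):
            raise ValueError("class labels and betas must cover the same genes")

    @property
    def prognostic_genes(self) -> list:
        return self.beta.index[self.beta != 0].tolist()

    def genes_of_class(self, cls: str) -> list:
        return self.gene_class.index[self.gene_class == cls].tolist()


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    counts = {c: int(round(cfg.class_fractions[c] * cfg.n_genes)) for c in GENE_CLASSES}
    # rounding drift goes to the null class
    counts["null"] += cfg.n_genes - sum(counts.values())
    labels = np.concatenate([[c] * counts[c] for c in GENE_CLASSES])
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    return pd.Series(labels, index=genes, name="gene_class")


def simulate_multiregion(cfg: SimulationConfig) -> tuple[MultiRegionCohort, GroundTruth]:
    """Draw a multi-region cohort with planted clonal/subclonal/null genes.

    For gene g of class c, sample s of patient p:
    ``x[g, s] = mu_g + a[g, p] + e[g, s]`` with ``a ~ N(0, sigma_b[c]^2)``
    per patient and ``e ~ N(0, sigma_w[c]^2)`` per region sample.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = _assign_classes(cfg, rng)
    mu = pd.Series(
        rng.uniform(cfg.mean_low, cfg.mean_high, size=cfg.n_genes),
        index=classes.index,
        name="gene_mean",
    )
    P, R, G = cfg.n_patients, cfg.regions_per_patient, cfg.n_genes
    sb = classes.map(cfg.sigma_b).to_numpy(dtype=float)[:, None]
    sw = classes.map(cfg.sigma_w).to_numpy(dtype=float)[:, None]
    patient_eff = rng.standard_normal((G, P)) * sb  # (G, P)
    region_noise = rng.standard_normal((G, P * R)) * sw
    values = mu.to_numpy()[:, None] + np.repeat(patient_eff, R, axis=1) + region_noise

    patients = [f"P{i:03d}" for i in range(P)]
    region_names = (
        ["superior", "lateral", "inferior"]
        if R == 3
        else [f"region{j}" for j in range(R)]
    )
    sample_ids = [f"{p}_{r}" for p in patients for r in region_names]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=classes.index, columns=sample_ids), "log2"
    )
    sm = SampleMap(
        pd.DataFrame(
            {
                "patient_id": np.repeat(patients, R),
                "region": region_names * P,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # prognostic genes are planted among *expressed* clonal genes (above-median
    # mean), so the low-expression filter strips noise rather than ground truth
    clonal = classes.index[(classes == "clonal") & (mu > mu.median())]
    if len(clonal) == 0:
        clonal = classes.index[classes == "clonal"]
    n_prog = min(cfg.n_prognostic_clonal, len(clonal))
    prog = rng.choice(clonal, size=n_prog, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_prog)
    beta = pd.Series(0.0, index=classes.index, name="beta")
    beta.loc[prog] = signs * cfg.beta_scale
    truth = GroundTruth(gene_class=classes, beta=beta, gene_mean=mu)
    logger.info(
        "simulated multiregion cohort: %d patients x %d regions, %d genes "
        "(%d clonal, %d prognostic)",
        P, R, G, (classes == "clonal").sum(), n_prog,
    )
    return MultiRegionCohort(expr, sm), truth


def simulate_survival_cohort(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_samples: int = 300,
    seed: int | None = None,
) -> SurvivalCohort:
    """Draw a single-region cohort with Cox-model survival times.

    Expression of gene g in a sample is ``N(mu_g, sigma_b^2 + sigma_w^2)``
    for its class (one region of an unseen tumor). The hazard is
    ``lambda0 * exp(sum_g beta_g (x_g - mu_g) + covariate effects)``;
    centring at mu_g keeps the baseline hazard interpretable. Censoring is
    an independent exponential time whose rate is set from
    ``censoring_rate`` c as ``lambda0 * c / (1 - c)`` (the exact censored
    fraction under the null model).
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genes = truth.gene_class.index
    sd = np.sqrt(
        truth.gene_class.map(cfg.sigma_b).to_numpy(dtype=float) ** 2
        + truth.gene_class.map(cfg.sigma_w).to_numpy(dtype=float) ** 2
    )
    X = (
        truth.gene_mean.to_numpy()[:, None]
        + rng.standard_normal((len(genes), n_samples)) * sd[:, None]
    )
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=sample_ids), "log2")

    beta = truth.beta.to_numpy()
    eta = beta @ (X - truth.gene_mean.to_numpy()[:, None])  # (n_samples,)

    cov = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    cov["age"] = np.round(rng.uniform(40, 80, size=n_samples), 1)
    cov["sex"] = rng.choice(["male", "female"], size=n_samples, p=[0.7, 0.3])
    cov["stage"] = rng.choice(["I", "II", "III"], size=n_samples, p=[0.45, 0.35, 0.2])
    cov["histology"] = rng.choice(
        ["epithelioid", "biphasic", "sarcomatoid"], size=n_samples, p=[0.6, 0.3, 0.1]
    )
    for name, b in cfg.covariate_betas.items():
        col = cov[name]
        if col.dtype == object:
            ref = sorted(col.unique())[0]
            eta = eta + b * (col != ref).to_numpy(dtype=float)
        else:
            eta = eta + b * (col - col.mean()).to_numpy(dtype=float)

    hazard = cfg.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        cens_rate = cfg.baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=n_samples)
    else:
        cens_time = np.full(n_samples, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    if event.sum() == 0:
        warnings.warn("all survival times censored under this configuration")

    clin = cov.copy()
    clin.insert(0, "time", time)
    clin.insert(1, "event", event)
    truth.linear_predictor = pd.Series(eta, index=expr.sample_ids, name="eta")
    logger.info(
        "simulated survival cohort: %d samples, %d events (%.0f%% censored)",
        n_samples, event.sum(), 100 * (1 - event.mean()),
    )
    return SurvivalCohort(expr, ClinicalTable(clin))


def simulate_cnv(
    n_genes: int,
    band_map: pd.Series,
    amp_rates: dict,
    del_rates: dict,
    n_samples: int,
    seed: int,
) -> pd.DataFrame:
    """Draw a gene x sample copy-number call matrix in {-1, 0, +1}.

    Amplification and deletion are Bernoulli per (band, sample) and shared
    by all genes of the band; a sample drawing both is resolved
    amplification-first.
    """
    if len(band_map) != n_genes:
        raise ValueError("band_map must assign a band to every gene")
    bands = band_map.unique()
    for rates in (amp_rates, del_rates):
        for b, r in rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"rate out of [0, 1] for band {b!r}")
    rng = np.random.default_rng(seed)
    calls = pd.DataFrame(
        0,
        index=band_map.index,
        columns=[f"S{i:04d}" for i in range(n_samples)],
        dtype=int,
    )
    n_conflicts = 0
    for b in bands:
        amp = rng.random(n_samples) < amp_rates.get(b, 0.0)
        dele = rng.random(n_samples) < del_rates.get(b, 0.0)
        n_conflicts += int((amp & dele).sum())
        band_call = np.where(amp, 1, np.where(dele, -1, 0))
        calls.loc[band_map.index[band_map == b], :] = np.broadcast_to(
            band_call, (int((band_map == b).sum()), n_samples)
        )
    if n_conflicts:
        logger.info("resolved %d amp/del conflicts amplification-first", n_conflicts)
    return calls
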