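"""Expression, clinical and sample-map tables: reading, validation, normalization.

Expression matrices are genes x samples. Upstream quantification (counts,
FPKM or RSEM) is taken as given; this module library-size-normalizes each
sample to the cohort-median total and applies a log2(x+1) transform, the
scale on which all heterogeneity and survival analysis downstream operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TAGS = ("counts", "fpkm", "rsem", "log2")


@dataclass
class ExpressionMatrix:
    """A validated genes x samples expression table.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples.
    scale_tag : str
        One of ``counts``, ``fpkm``, ``rsem`` (linear, non-negative) or
        ``log2`` (after :func:`normalize_and_log`).
    """

    values: pd.DataFrame
    scale_tag: str = "counts"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale_tag != "log2" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values in a {self.scale_tag}-scale matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale_tag)


@dataclass
class SampleMap:
    """Maps each multi-region sample to its (patient, region)."""

    table: pd.DataFrame  # index: sample_id; columns: patient_id, region

    def __post_init__(self) -> None:
        required = {"patient_id", "region"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"sample map needs columns {sorted(required)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample map")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def patients(self) -> list:
        return self.table["patient_id"].unique().tolist()

    def regions_of(self, patient) -> pd.Index:
        return self.table.index[self.table["patient_id"] == patient]

    def require_min_regions(self, k: int = 2) -> None:
        counts = self.table.groupby("patient_id").size()
        bad = counts[counts < k]
        if len(bad):
            raise ValueError(
                f"patients with fewer than {k} regions: {bad.index.tolist()}"
            )


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional covariates.

    ``table`` is indexed by sample id and must carry ``time`` (days, > 0)
    and ``event`` (0 censored / 1 event). Any further columns are treated
    as covariates (age, sex, stage, histology, asbestos, smoking, ...).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        t = self.table["time"].to_numpy(dtype=float)
        if not (t > 0).all():
            raise ValueError("survival times must be strictly positive")
        ev = self.table["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]


@dataclass
class MultiRegionCohort:
    """Log2 expression plus the sample -> (patient, region) map."""

    expression: ExpressionMatrix
    sample_map: SampleMap

    def __post_init__(self) -> None:
        missing = self.sample_map.sample_ids.difference(self.expression.sample_ids)
        if len(missing):
            raise ValueError(f"mapped samples absent from expression: {missing.tolist()}")
        # restrict expression to mapped samples, in map order
        self.expression = ExpressionMatrix(
            self.expression.values[self.sample_map.sample_ids],
            self.expression.scale_tag,
        )

    @property
    def patients(self) -> list:
        return self.sample_map.patients


@dataclass
class SurvivalCohort:
    """Single-region expression joined to survival outcomes, sample-aligned."""

    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if not self.expression.sample_ids.equals(self.clinical.table.index):
            raise ValueError("expression and clinical tables are not sample-aligned")

    @property
    def n_samples(self) -> int:
        return len(self.clinical.table)

    @property
    def time(self) -> np.ndarray:
        return self.clinical.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical.table["event"].to_numpy(dtype=int)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, scale_tag: str = "counts") -> ExpressionMatrix:
    """Read a delimited genes-in-rows expression table.

    Duplicate gene ids are collapsed by keeping the row with the highest
    median expression; duplicate sample ids are an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in raw.columns:
        bad = pd.to_numeric(raw[col], errors="coerce")
        mask = bad.isna() & raw[col].notna()
        if mask.any():
            row = raw.index[mask.to_numpy().argmax()]
            raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r}")
        raw[col] = bad
    if raw.isna().any().any():
        raise ValueError(f"missing values in {path}")
    if raw.index.duplicated().any():
        orig_order = raw.index.unique()
        med = raw.median(axis=1)
        n_before = len(raw)
        raw = raw.iloc[np.argsort(-med.to_numpy(), kind="stable")]
        raw = raw[~raw.index.duplicated(keep="first")].loc[orig_order]
        logger.info("collapsed %d duplicate gene rows by max median", n_before - len(raw))
    m = ExpressionMatrix(raw, scale_tag)
    logger.info("read expression %s: %d genes x %d samples", path, *m.shape)
    return m


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep=_sep_for(path))
    logger.info("wrote expression %s: %d genes x %d samples", path, *m.shape)


def read_sample_map(path) -> SampleMap:
    t = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return SampleMap(t)


def write_sample_map(sm: SampleMap, path) -> None:
    sm.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_clinical(path) -> ClinicalTable:
    t = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ClinicalTable(t)


def write_clinical(ct: ClinicalTable, path) -> None:
    ct.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def normalize_and_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-library-size normalization followed by log2(x + 1).

    Each sample column is rescaled so that its total equals the cohort
    median total; after rescaling every column of the pre-log matrix sums
    to the median library size. A pseudocount of 1 keeps zeros at zero.
    """
    if m.scale_tag == "log2":
        raise ValueError("matrix is already log2-scaled")
    sums = m.values.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total expression: {zero}")
    factors = sums.median() / sums
    scaled = m.values * factors
    logged = np.log2(scaled + 1.0)
    logger.info(
        "normalized %d samples to median library size %.6g", m.shape[1], sums.median()
    )
    return ExpressionMatrix(logged, "log2")


def align_cohort(
    m: ExpressionMatrix,
    clin: ClinicalTable,
    exclude_short_survivors_days: Optional[float] = None,
) -> SurvivalCohort:
    """Intersect expression and clinical samples into an aligned cohort.

    If ``exclude_short_survivors_days`` is given, samples with survival
    below that many days are dropped (used for discovery cohorts where
    perioperative deaths are excluded).
    """
    shared = [s for s in m.sample_ids if s in clin.table.index]
    if not shared:
        raise ValueError("no samples shared between expression and clinical tables")
    clin_sub = clin.table.loc[shared]
    if exclude_short_survivors_days is not None:
        keep = clin_sub["time"] >= exclude_short_survivors_days
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "excluded %d samples with survival < %s days",
                dropped,
                exclude_short_survivors_days,
            )
        clin_sub = clin_sub[keep]
        if clin_sub.empty:
            raise ValueError("all samples excluded by the short-survivor filter")
    expr = ExpressionMatrix(m.values[clin_sub.index.tolist()], m.scale_tag)
    logger.info("aligned cohort: %d samples, %d genes", len(clin_sub), expr.shape[0])
    return SurvivalCohort(expr, ClinicalTable(clin_sub))
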