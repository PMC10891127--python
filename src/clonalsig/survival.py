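"""Survival-analysis contracts: Cox PH fits, lasso-Cox selection, KM, log-rank.

Univariable/multivariable Cox fits go through lifelines (Efron tie
handling, Wald p-values). Two performance-critical pieces are implemented
directly on the Breslow partial likelihood: a vectorized per-gene
univariable screen (Newton, all genes at once) and the L1-penalized fit
(FISTA with soft-thresholding) used for signature selection at a fixed
penalty. With continuous survival times Breslow and Efron coincide; tests
pin the screen against lifelines and the penalized fit against an
independent coordinate-descent implementation and the KKT conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CoxFit:
    """Per-covariate estimates from a proportional-hazards fit."""

    summary: pd.DataFrame  # index covariate; columns coef, hr, hr_lower, hr_upper, p
    log_likelihood: float
    n: int
    n_events: int


@dataclass
class LassoPath:
    """L1-penalized Cox solution at one penalty value.

    Coefficients are reported on the original covariate scale; the penalty
    applies on the standardized (unit-SD) scale, glmnet-style, with the
    smooth part of the objective being -(1/n) x Breslow log partial
    likelihood.
    """

    lam: float
    coefficients: pd.Series  # original scale; zero = not selected
    coefficients_std: pd.Series  # standardized scale (the penalized solution)
    selected: list
    standardized: bool = True
    n_iter: int = 0
    kkt_residual: float = np.nan


# ---------------------------------------------------------------------------
# Breslow partial-likelihood core


def _risk_set_starts(time_sorted: np.ndarray) -> np.ndarray:
    """For each index i (ascending times), first index of the risk set R(t_i)."""
    return np.searchsorted(time_sorted, time_sorted, side="left")


def breslow_loglik_and_grad(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray]:
    """Breslow log partial likelihood and its gradient.

    X is (n, p); ties share the full risk set. Returns the *unscaled* sum
    log-likelihood (callers divide by n for the glmnet-style objective).
    """
    order = np.argsort(time, kind="stable")
    X = np.asarray(X, float)[order]
    ev = np.asarray(event)[order].astype(bool)
    t = np.asarray(time, float)[order]
    starts = _risk_set_starts(t)
    eta = X @ beta
    eta_max = eta.max()
    w = np.exp(eta - eta_max)
    S0 = np.cumsum(w[::-1])[::-1]  # S0[j] = sum_{l >= j} w_l
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]  # (n, p)
    ev_starts = starts[ev]
    ll = float(eta[ev].sum() - (np.log(S0[ev_starts]) + eta_max).sum())
    grad = X[ev].sum(axis=0) - (S1[ev_starts] / S0[ev_starts, None]).sum(axis=0)
    return ll, grad


def cox_score_test(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    """Cox score test of beta = 0 for a single covariate.

    Returns (chi-square statistic, p on 1 df). For a binary covariate this
    statistic is the log-rank statistic for the induced two-group split.
    """
    x = np.asarray(x, float)
    order = np.argsort(time, kind="stable")
    xs = x[order]
    ev = np.asarray(event)[order].astype(bool)
    t = np.asarray(time, float)[order]
    starts = _risk_set_starts(t)
    # at beta = 0 all weights are 1
    n = len(xs)
    S0 = np.arange(n, 0, -1, dtype=float)  # |R(t_j)| for start index j
    S1 = np.cumsum(xs[::-1])[::-1]
    S2 = np.cumsum((xs**2)[::-1])[::-1]
    s0 = S0[starts[ev]]
    m = S1[starts[ev]] / s0
    U = float((xs[ev] - m).sum())
    I = float((S2[starts[ev]] / s0 - m**2).sum())
    if I <= 0:
        raise ValueError("degenerate covariate: zero score-test information")
    chi2 = U**2 / I
    return chi2, float(stats.chi2.sf(chi2, df=1))


def cox_screen(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray, max_iter: int = 25
) -> pd.DataFrame:
    """Univariable Cox fit of every column of X, vectorized across columns.

    X is samples x genes. Newton iterations on the Breslow partial
    likelihood run for all genes simultaneously; returns a per-gene table
    (coef, hr, se, p) with Wald p-values. Genes whose information is
    degenerate (constant columns) get NaN.
    """
    order = np.argsort(time, kind="stable")
    V = X.to_numpy(dtype=float)[order]  # (n, G)
    ev = np.asarray(event)[order].astype(bool)
    t = np.asarray(time, float)[order]
    starts = _risk_set_starts(t)
    ev_starts = starts[ev]
    n, G = V.shape
    beta = np.zeros(G)
    const = V.std(axis=0) == 0
    for _ in range(max_iter):
        eta = V * beta  # (n, G)
        eta -= eta.max(axis=0, keepdims=True)
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1], axis=0)[::-1]
        S1 = np.cumsum((w * V)[::-1], axis=0)[::-1]
        S2 = np.cumsum((w * V * V)[::-1], axis=0)[::-1]
        s0 = S0[ev_starts]
        m = S1[ev_starts] / s0
        U = (V[ev] - m).sum(axis=0)
        I = (S2[ev_starts] / s0 - m**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I > 0, U / I, 0.0)
        step = np.clip(step, -2.0, 2.0)  # damped for stability far from optimum
        beta = beta + step
        active = ~const
        if not active.any() or np.max(np.abs(step[active])) < 1e-10:
            break
    # final information for standard errors
    eta = V * beta
    eta -= eta.max(axis=0, keepdims=True)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1], axis=0)[::-1]
    S1 = np.cumsum((w * V)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w * V * V)[::-1], axis=0)[::-1]
    s0 = S0[ev_starts]
    m = S1[ev_starts] / s0
    I = (S2[ev_starts] / s0 - m**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(I > 0, 1.0 / np.sqrt(I), np.nan)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"coef": beta, "hr": np.exp(beta), "se": se, "p": p}, index=X.columns
    )
    out.loc[const, ["coef", "hr", "se", "p"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# lifelines-backed single fits


def _check_surv(time: np.ndarray, event: np.ndarray) -> None:
    event = np.asarray(event)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")


def _coxfit_from_lifelines(cph: CoxPHFitter) -> CoxFit:
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower": np.exp(s["coef lower 95%"]),
            "hr_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=int(cph._n_examples),
        n_events=int(cph.event_observed.sum()),
    )


def cox_univariable(x: pd.Series, time: np.ndarray, event: np.ndarray) -> CoxFit:
    """Single-covariate Cox PH fit (Efron ties, Wald p)."""
    _check_surv(time, event)
    if np.std(np.asarray(x, float)) == 0:
        raise ValueError(f"degenerate covariate {getattr(x, 'name', 'x')!r}")
    name = x.name if isinstance(x, pd.Series) and x.name else "x"
    df = pd.DataFrame({name: np.asarray(x, float), "time": time, "event": event})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return _coxfit_from_lifelines(cph)


def encode_covariates(X: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical columns against the first (sorted) level."""
    out = {}
    for col in X.columns:
        s = X[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            for lev in levels[1:]:
                out[f"{col}[{lev}]"] = (s == lev).astype(float)
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=X.index)


def _check_collinear(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name a minimal offending column: one predictable from the others
        for j, col in enumerate(X.columns):
            others = np.delete(A, j, axis=1)
            resid = A[:, j] - others @ np.linalg.lstsq(others, A[:, j], rcond=None)[0]
            if np.abs(resid).max() < 1e-8 * (np.abs(A[:, j]).max() + 1):
                raise ValueError(f"collinear covariate column {col!r}")
        raise ValueError("collinear covariate matrix")


def cox_multivariable(X: pd.DataFrame, time: np.ndarray, event: np.ndarray) -> CoxFit:
    """Joint Cox PH fit on an encoded covariate matrix."""
    _check_surv(time, event)
    if X.shape[1] == 0:
        raise ValueError("empty covariate set")
    Xe = encode_covariates(X)
    if len(Xe) <= Xe.shape[1]:
        raise ValueError("more covariates than samples")
    _check_collinear(Xe)
    df = Xe.copy()
    df["time"] = np.asarray(time, float)
    df["event"] = np.asarray(event)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return _coxfit_from_lifelines(cph)


# ---------------------------------------------------------------------------
# L1-penalized Cox (FISTA on the Breslow likelihood)


def _soft(z: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)


def lasso_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    lam: float,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> LassoPath:
    """L1-penalized Cox partial-likelihood fit at a fixed penalty.

    Minimizes ``-(1/n) loglik(beta) + lam * ||beta||_1`` over standardized
    predictors by FISTA with backtracking; convergence is declared on the
    KKT subgradient residual. ``lam = 0`` reduces to the unpenalized fit.
    """
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    _check_surv(time, event)
    V = X.to_numpy(dtype=float)
    n, p = V.shape
    mu, sd = V.mean(axis=0), V.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = X.columns[sd == 0].tolist()
        raise ValueError(f"constant predictor columns: {bad}")
    Z = (V - mu) / sd

    def smooth(beta):
        ll, grad = breslow_loglik_and_grad(beta, Z, time, event)
        return -ll / n, -grad / n

    beta = np.zeros(p)
    y = beta.copy()
    t_mom = 1.0
    step = 1.0
    f_y, g_y = smooth(y)
    n_iter = 0
    kkt = np.inf
    for n_iter in range(1, max_iter + 1):
        while True:
            cand = _soft(y - step * g_y, step * lam)
            f_cand, _ = smooth(cand)
            d = cand - y
            if f_cand <= f_y + g_y @ d + (d @ d) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                break
        beta_new = cand
        t_new = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        y = beta_new + ((t_mom - 1) / t_new) * (beta_new - beta)
        beta, t_mom = beta_new, t_new
        f_y, g_y = smooth(y)
        if n_iter % 10 == 0 or n_iter == max_iter:
            _, g_b = smooth(beta)
            kkt = _kkt_residual(beta, g_b, lam)
            if kkt < tol:
                break
    _, g_b = smooth(beta)
    kkt = _kkt_residual(beta, g_b, lam)
    coef_std = pd.Series(beta, index=X.columns, name="coef_std")
    coef = pd.Series(beta / sd, index=X.columns, name="coef")
    selected = X.columns[np.abs(beta) > 0].tolist()
    logger.info(
        "lasso-Cox at lam=%.4g: %d/%d selected (kkt %.2e, %d iters)",
        lam, len(selected), p, kkt, n_iter,
    )
    return LassoPath(
        lam=lam,
        coefficients=coef,
        coefficients_std=coef_std,
        selected=selected,
        n_iter=n_iter,
        kkt_residual=kkt,
    )


def _kkt_residual(beta: np.ndarray, grad_smooth: np.ndarray, lam: float) -> float:
    """Max violation of the L1 subgradient optimality conditions."""
    active = beta != 0
    r = np.where(
        active,
        np.abs(grad_smooth + lam * np.sign(beta)),
        np.maximum(np.abs(grad_smooth) - lam, 0.0),
    )
    return float(r.max()) if len(r) else 0.0


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    statistic: float
    p: float
    df: int


def km_logrank(groups: pd.Series, time: np.ndarray, event: np.ndarray) -> KMResult:
    """Kaplan-Meier curves per group plus the k-group log-rank test."""
    groups = pd.Series(groups, name="group").reset_index(drop=True)
    if isinstance(groups.dtype, pd.CategoricalDtype):
        empty = [
            g for g in groups.cat.categories if (groups == g).sum() == 0
        ]
        if empty:
            raise ValueError(f"empty groups: {empty}")
        groups = groups.astype(object)
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    curves = {}
    for g in labels:
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(time, float)[mask], np.asarray(event)[mask])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(
        np.asarray(time, float), groups.to_numpy(), np.asarray(event)
    )
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=len(labels) - 1,
    )
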