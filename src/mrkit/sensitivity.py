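"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q and I-squared quantify heterogeneity among the per-SNP Wald
ratios; the MR-Egger intercept tests for directional pleiotropy; MR-PRESSO
builds a simulated null distribution of the residual sum of squares to give a
global pleiotropy p-value and per-SNP outlier calls; leave-one-out refits the
IVW estimate excluding each SNP in turn.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HarmonizedInstrumentSet, SensitivityReport
from .estimators import EggerRegression, IVWEstimator
from .exceptions import InsufficientInstrumentsError


@dataclass
class QResult:
    """Cochran's Q with its chi-square reference and the I^2 percentage."""

    q: float
    df: int
    pvalue: float
    i2: float
    contributions: np.ndarray = field(repr=False)


def cochran_q(hset: HarmonizedInstrumentSet) -> QResult:
    """Cochran's Q over the per-SNP Wald ratios around the fixed-effect IVW.

    Q = sum_j w_j (theta_j - theta_IVW)^2 with ratio weights
    w_j = gamma_j^2 / sigma_Yj^2; the p-value refers Q to chi-square(J-1) and
    I^2 = max(0, (Q - (J-1)) / Q) * 100.
    """
    J = hset.n_snps
    if J < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 SNPs, got {J}")
    g = hset.beta_exposure
    G = hset.beta_outcome
    sy = hset.se_outcome
    theta_fixed = IVWEstimator(effects_model="fixed").fit_set(hset).effect_
    ratios = G / g
    w = (g / sy) ** 2
    contrib = w * (ratios - theta_fixed) ** 2
    q = float(np.sum(contrib))
    df = J - 1
    pvalue = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return QResult(q=q, df=df, pvalue=pvalue, i2=i2, contributions=contrib)


def egger_intercept_test(hset: HarmonizedInstrumentSet) -> tuple[float, float, float]:
    """(intercept, se, two-sided p from t(J-2)) of the MR-Egger fit."""
    fit = EggerRegression().fit_set(hset)
    return fit.intercept_, fit.intercept_se_, fit.intercept_pvalue_


def _loo_thetas(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW estimates excluding each SNP in turn (vectorized)."""
    w = 1.0 / sy**2
    s1 = np.sum(w * g * G)
    s2 = np.sum(w * g * g)
    return (s1 - w * g * G) / (s2 - w * g * g)


@dataclass
class PressoResult:
    """MR-PRESSO global test and outlier calls.

    ``status`` is "ok" or "insufficient_instruments"; in the latter case the
    numeric fields are NaN, mirroring how reports print NA for pairs with too
    few SNPs.
    """

    rss_obs: float
    global_pvalue: float
    n_sim: int
    outlier_ids: list[str]
    per_snp_pvalues: pd.Series | None = field(default=None, repr=False)
    status: str = "ok"


def mr_presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_significance: float = 0.05,
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with per-SNP outlier detection.

    The observed statistic is RSSobs = sum_j w_j (Gamma_j - gamma_j
    theta_{-j})^2, with theta_{-j} the leave-one-out fixed-effect IVW estimate
    and w_j = 1/sigma_Yj^2. The null distribution is built from ``n_sim``
    parametric simulations drawing gamma* ~ N(gamma_j, sigma_Xj) and
    Gamma* ~ N(gamma_j theta_{-j}, sigma_Yj) and recomputing the statistic;
    the global p uses the add-one estimator (never exactly zero). Per-SNP
    outlier p-values come from each SNP's simulated residual distribution,
    Bonferroni-adjusted across the J SNPs.

    Requires J >= 4; smaller sets return an NA-filled result with
    ``status="insufficient_instruments"``.
    """
    J = hset.n_snps
    if J < 4:
        return PressoResult(
            rss_obs=float("nan"),
            global_pvalue=float("nan"),
            n_sim=n_sim,
            outlier_ids=[],
            status="insufficient_instruments",
        )
    g = hset.beta_exposure
    G = hset.beta_outcome
    sx = hset.se_exposure
    sy = hset.se_outcome
    w = 1.0 / sy**2

    theta_minus = _loo_thetas(g, G, sy)
    obs_res = w * (G - g * theta_minus) ** 2
    rss_obs = float(np.sum(obs_res))

    rng = np.random.default_rng(seed)
    g_sim = g[None, :] + sx[None, :] * rng.standard_normal((n_sim, J))
    G_sim = (g * theta_minus)[None, :] + sy[None, :] * rng.standard_normal((n_sim, J))

    # leave-one-out IVW per simulation, vectorized across the n_sim rows
    s1 = np.sum(w[None, :] * g_sim * G_sim, axis=1, keepdims=True)
    s2 = np.sum(w[None, :] * g_sim * g_sim, axis=1, keepdims=True)
    theta_minus_sim = (s1 - w * g_sim * G_sim) / (s2 - w * g_sim * g_sim)
    sim_res = w[None, :] * (G_sim - g_sim * theta_minus_sim) ** 2
    rss_sim = sim_res.sum(axis=1)

    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    per_snp = (1 + np.sum(sim_res >= obs_res[None, :], axis=0)) / (n_sim + 1)
    adjusted = np.minimum(1.0, per_snp * J)
    ids = np.asarray(hset.variant_ids)
    outliers = [str(v) for v in ids[adjusted < outlier_significance]]
    return PressoResult(
        rss_obs=rss_obs,
        global_pvalue=float(global_p),
        n_sim=n_sim,
        outlier_ids=outliers,
        per_snp_pvalues=pd.Series(adjusted, index=ids, name="presso_outlier_p"),
    )


def leave_one_out(
    hset: HarmonizedInstrumentSet, effects_model: str = "multiplicative_random"
) -> pd.DataFrame:
    """IVW estimates excluding one SNP at a time, one row per excluded id."""
    J = hset.n_snps
    if J < 2:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 2 SNPs, got {J}")
    rows = []
    for vid in hset.variant_ids:
        fit = IVWEstimator(effects_model=effects_model).fit_set(hset.drop(vid))
        rows.append(
            {
                "excluded_id": vid,
                "theta": fit.effect_,
                "se": fit.se_,
                "pvalue": fit.pvalue_,
                "n_snps": fit.n_snps_,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_report(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_significance: float = 0.05,
) -> SensitivityReport:
    """Run every diagnostic the instrument count allows; NaN for the rest."""
    report = SensitivityReport(exposure=hset.exposure_name, outcome=hset.outcome_name)
    if hset.n_snps >= 2:
        qr = cochran_q(hset)
        report.q, report.q_df, report.q_pvalue, report.i2 = qr.q, qr.df, qr.pvalue, qr.i2
        report.loo = leave_one_out(hset)
    if hset.n_snps >= 3:
        icpt, icpt_se, icpt_p = egger_intercept_test(hset)
        report.egger_intercept = icpt
        report.egger_intercept_se = icpt_se
        report.egger_intercept_pvalue = icpt_p
    presso = mr_presso(
        hset, n_sim=n_sim, seed=seed, outlier_significance=outlier_significance
    )
    report.presso_rss_obs = presso.rss_obs
    report.presso_global_pvalue = presso.global_pvalue
    report.presso_n_sim = presso.n_sim
    report.presso_outlier_ids = presso.outlier_ids
    return report
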