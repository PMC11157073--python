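"""Core record types shared across the pipeline.

The in-memory containers are thin dataclass wrappers around pandas DataFrames
with fixed column schemas, so every stage of the pipeline (reading, instrument
selection, harmonization, estimation, diagnostics) exchanges plain tabular
data that serializes losslessly to TSV.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

#: Allele alphabet accepted throughout (biallelic SNVs only).
VALID_ALLELES = frozenset("ACGT")

#: Watson-Crick complement; used for the palindromic-pair test.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order of a summary-statistics table.
SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: Canonical column order of a harmonized instrument set.
HARMONIZED_COLUMNS = [
    "variant_id", "beta_exposure", "se_exposure",
    "beta_outcome", "se_outcome", "f_stat",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class VariantAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate (log odds ratio for binary
    traits), ``se`` its standard error, ``pvalue`` the two-sided p-value.
    ``eaf`` (effect-allele frequency) and ``n`` (sample size) are optional.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in VALID_ALLELES:
            raise InputError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise InputError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise InputError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if not self.se > 0:
            raise InputError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise InputError(
                f"{self.variant_id}: p-value must be in (0, 1], got {self.pvalue}"
            )
        if self.pos < 1:
            raise InputError(f"{self.variant_id}: position must be >= 1")
        if self.eaf is not None and not math.isnan(self.eaf):
            if not (0 <= self.eaf <= 1):
                raise InputError(f"{self.variant_id}: eaf outside [0, 1]")


@dataclass
class SummaryStatsTable:
    """GWAS summary statistics for one trait, keyed by unique ``variant_id``."""

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise InputError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"summary table missing columns: {missing}")
        if self.data["variant_id"].duplicated().any():
            raise InputError(f"{self.trait_name}: duplicate variant ids")
        self.data = self.data.reset_index(drop=True)[SUMMARY_COLUMNS]

    @classmethod
    def from_associations(
        cls, trait_name: str, trait_type: str, rows: list[VariantAssociation]
    ) -> "SummaryStatsTable":
        records = [dataclasses.asdict(r) for r in rows]
        df = pd.DataFrame.from_records(records)
        df["eaf"] = df["eaf"].astype(float) if "eaf" in df else np.nan
        df["n"] = df["n"].astype(float) if "n" in df else np.nan
        return cls(trait_name, trait_type, df[SUMMARY_COLUMNS])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return self.data["variant_id"].tolist()

    def subset(self, variant_ids: list[str]) -> "SummaryStatsTable":
        keep = self.data[self.data["variant_id"].isin(set(variant_ids))]
        return SummaryStatsTable(self.trait_name, self.trait_type, keep.copy())


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effect pairs ready for MR.

    Per SNP j the columns hold the instrument-exposure association
    ``beta_exposure`` (gamma_j) with ``se_exposure`` (sigma_Xj), the
    instrument-outcome association ``beta_outcome`` (Gamma_j) with
    ``se_outcome`` (sigma_Yj), and the instrument-strength F statistic
    beta_exposure^2 / se_exposure^2. Both effects are expressed per copy of
    the same (exposure) effect allele; palindromic SNPs have been removed.
    """

    exposure_name: str
    outcome_name: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"harmonized set missing columns: {missing}")
        if (self.data["se_exposure"] <= 0).any() or (self.data["se_outcome"] <= 0).any():
            raise InputError("harmonized set contains non-positive standard errors")
        self.data = self.data.reset_index(drop=True)[HARMONIZED_COLUMNS]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return self.data["variant_id"].tolist()

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.data["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.data["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.data["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.data["se_outcome"].to_numpy(float)

    @property
    def f_stat(self) -> np.ndarray:
        return self.data["f_stat"].to_numpy(float)

    def drop(self, variant_id: str) -> "HarmonizedInstrumentSet":
        """Return a copy with one SNP removed (leave-one-out support)."""
        keep = self.data[self.data["variant_id"] != variant_id]
        return HarmonizedInstrumentSet(self.exposure_name, self.outcome_name, keep.copy())

    def subset_by_index(self, idx) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            self.exposure_name, self.outcome_name, self.data.iloc[idx].copy()
        )


@dataclass
class MREstimate:
    """One method's causal estimate for an exposure/outcome pair.

    ``theta`` is on the beta (log-odds for binary outcomes) scale with
    normal-theory 95% confidence bounds; ``or_value`` and its bounds are the
    exponentiated equivalents. ``extra`` carries method-specific fields
    (Egger intercept record, heterogeneity Q, bootstrap settings).
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_low: float
    or_high: float
    pvalue: float
    n_snps: int
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        method: str,
        theta: float,
        se: float,
        n_snps: int,
        *,
        pvalue: float | None = None,
        df: int | None = None,
        extra: dict[str, Any] | None = None,
    ) -> "MREstimate":
        """Assemble an estimate from (theta, se).

        The p-value defaults to a two-sided normal test of theta = 0, or a
        t-test with ``df`` degrees of freedom when given. The 95% CI is
        normal-theory on the beta scale and exponentiated for the OR bounds.
        """
        theta = float(theta)
        se = float(se)
        if pvalue is None:
            if se > 0:
                z = abs(theta) / se
                pvalue = float(
                    2 * stats.t.sf(z, df) if df is not None else 2 * stats.norm.sf(z)
                )
            else:
                pvalue = math.nan
        half = _Z975 * se
        ci_low, ci_high = theta - half, theta + half
        return cls(
            method=method,
            theta=theta,
            se=se,
            ci_low=ci_low,
            ci_high=ci_high,
            or_value=math.exp(theta),
            or_low=math.exp(ci_low),
            or_high=math.exp(ci_high),
            pvalue=float(pvalue),
            n_snps=int(n_snps),
            extra=dict(extra or {}),
        )


@dataclass
class SensitivityReport:
    """Heterogeneity and pleiotropy diagnostics for one instrument set.

    Fields that cannot be computed at the available instrument count are NaN
    (e.g. the MR-PRESSO block needs at least four SNPs); ``loo`` holds the
    leave-one-out IVW table with one row per excluded SNP.
    """

    exposure: str
    outcome: str
    q: float = math.nan
    q_df: float = math.nan
    q_pvalue: float = math.nan
    i2: float = math.nan
    egger_intercept: float = math.nan
    egger_intercept_se: float = math.nan
    egger_intercept_pvalue: float = math.nan
    presso_rss_obs: float = math.nan
    presso_global_pvalue: float = math.nan
    presso_n_sim: float = math.nan
    presso_outlier_ids: list[str] = field(default_factory=list)
    loo: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict[str, Any]:
        """Flatten to one TSV-ready row (outlier ids comma-joined)."""
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "Q": self.q,
            "Q_df": self.q_df,
            "Q_p": self.q_pvalue,
            "I2": self.i2,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_pvalue,
            "RSSobs": self.presso_rss_obs,
            "presso_global_p": self.presso_global_pvalue,
            "presso_n_sim": self.presso_n_sim,
            "outlier_ids": ",".join(self.presso_outlier_ids),
        }


@dataclass
class MediationResult:
    """Two-step MR mediation decomposition.

    ``indirect = beta1 * beta2`` with a Sobel standard error;
    ``proportion = indirect / beta3`` (NaN when beta3 = 0). ``gate_passed``
    records whether the exposure-to-mediator step was significant, the
    precondition for claiming mediation.
    """

    exposure: str
    mediator: str
    outcome: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    indirect: float
    indirect_se: float
    proportion: float
    gate_passed: bool

    def to_row(self) -> dict[str, Any]:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "beta3": self.beta3,
            "se3": self.se3,
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "proportion": self.proportion,
            "gate_passed": self.gate_passed,
        }
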