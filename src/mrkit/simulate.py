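"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator follows a linear structural model on standardized traits. For
each instrument SNP j with minor-allele frequency f_j, the per-allele
standard errors are the usual summary-statistic approximations
sigma_X = 1/sqrt(2 f (1-f) n_exposure) and sigma_Y likewise with n_outcome.
True exposure effects gamma_j are drawn from N(0, gamma_sd^2), oriented to
the exposure-increasing allele (each SNP's effect allele is defined as the
one that raises the exposure, so gamma_j >= 0 — the usual reporting
convention, and one every estimator here is invariant to), and rescaled once
so the expected instrument F statistic (gamma^2 / sigma_X^2) averages
``mean_f``; observed effects add sampling noise scaled by ``noise_scale``
(zero gives the deterministic Gamma = theta * gamma regime). The SNP-outcome
effect is theta * gamma_j plus a per-SNP pleiotropic effect alpha_j whose
distribution is controlled by ``pleiotropy_mode`` and applied to a random
``pleiotropy_frac`` subset of the instruments (default: all of them):

* ``none`` — alpha = 0 (all instruments valid);
* ``balanced`` — alpha ~ N(0, tau^2), zero on average (InSiDE holds);
* ``directional`` — alpha ~ N(mu, tau^2) with nonzero mean (biases IVW,
  detectable by the Egger intercept);
* ``inside_violating`` — alpha correlated with gamma (breaks the
  instrument-strength-independent-of-direct-effect assumption).

Optional features: decoy SNPs whose exposure p-value is above any selection
threshold by construction; outcome-specific SNPs (instruments for the
outcome trait, used to exercise reverse MR; ``theta_reverse`` sets their
effect on the exposure); compound-symmetric LD blocks emitted as an LD
matrix so clumping has something to prune; a fraction of palindromic SNPs
and of allele-swapped outcome rows so harmonization is exercised end to end.

Randomness is organized as one child stream per dataset component, derived
from the master seed by fixed spawn indices, so enabling one feature never
perturbs the draws of another.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SUMMARY_COLUMNS, SummaryStatsTable
from .exceptions import ConfigurationError
from .instruments import LDMatrix

#: Non-palindromic ordered allele pairs used for generated SNPs.
_SAFE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
               ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class MediationSpec:
    """True coefficients of an exposure -> mediator -> outcome chain."""

    beta1: float = 0.3
    beta2: float = 0.5
    direct_effect: float = 0.15
    n_mediator: int = 20_000
    n_mediator_snps: int = 50

    @property
    def total_effect(self) -> float:
        return self.direct_effect + self.beta1 * self.beta2

    @property
    def proportion(self) -> float:
        return self.beta1 * self.beta2 / self.total_effect


@dataclass
class SimConfig:
    """Generating parameters for a synthetic two-sample MR dataset.

    Defaults describe the reference desk-scale scenario: 50 instruments,
    20,000 samples per trait, causal effect theta = 0.2, strong instruments
    (mean F = 100), no pleiotropy, no LD.
    """

    n_snps: int = 50
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    theta: float = 0.2
    pleiotropy_mode: str = "none"  # none|balanced|directional|inside_violating
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    inside_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_null_snps: int = 0
    decoy_p_min: float = 1e-4
    ld_blocks: list[tuple[int, float]] | None = None
    gamma_sd: float = 0.05
    mean_f: float = 100.0
    noise_scale: float = 1.0
    n_outcome_snps: int = 0
    theta_reverse: float = 0.0
    palindromic_frac: float = 0.0
    swapped_allele_frac: float = 0.0
    mediation: MediationSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_exposure < 1 or self.n_outcome < 1:
            raise ConfigurationError("n_snps and sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ConfigurationError("pleiotropy_frac must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        if self.ld_blocks is not None:
            if sum(size for size, _ in self.ld_blocks) != self.n_snps:
                raise ConfigurationError("ld_blocks sizes must sum to n_snps")
            for _, r2 in self.ld_blocks:
                if not (0 <= r2 <= 1):
                    raise ConfigurationError("ld block r2 outside [0,1]")


@dataclass
class SimTruth:
    """Generating parameters echoed alongside every dataset."""

    config: dict
    variant_ids: list[str]
    gamma: list[float]
    alpha: list[float]
    maf: list[float]
    proportion_mediated: float | None = None
    delta_outcome: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedPair:
    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    ld: LDMatrix
    truth: SimTruth
    mediator: SummaryStatsTable | None = None


def _streams(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _positions(n: int, blocks: list[tuple[int, float]] | None):
    """(chrom, pos) per SNP: blocks share a tight locus; blocks are far apart."""
    if blocks is None:
        blocks = [(1, 0.0)] * n
    chroms, poss, block_of = [], [], []
    for b, (size, _r2) in enumerate(blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 50_000_000
        for k in range(size):
            chroms.append(chrom)
            poss.append(base + 1_000 * k)
            block_of.append(b)
    return np.array(chroms), np.array(poss, dtype=np.int64), np.array(block_of)


def _ld_from_blocks(ids: np.ndarray, block_of: np.ndarray,
                    blocks: list[tuple[int, float]] | None) -> LDMatrix:
    ld = LDMatrix()
    if blocks is None:
        return ld
    r2s = [r2 for _size, r2 in blocks]
    for b in np.unique(block_of):
        members = np.nonzero(block_of == b)[0]
        r2 = r2s[int(b)]
        if r2 == 0:
            continue
        for i in range(members.size):
            for j in range(i + 1, members.size):
                ld.set(str(ids[members[i]]), str(ids[members[j]]), r2)
    return ld


def _alleles(rng: np.random.Generator, n: int, palindromic_frac: float):
    idx = rng.integers(0, len(_SAFE_PAIRS), size=n)
    ea = np.array([_SAFE_PAIRS[i][0] for i in idx])
    oa = np.array([_SAFE_PAIRS[i][1] for i in idx])
    if palindromic_frac > 0:
        pal = rng.random(n) < palindromic_frac
        pidx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
        ea = np.where(pal, [_PALINDROMIC_PAIRS[i][0] for i in pidx], ea)
        oa = np.where(pal, [_PALINDROMIC_PAIRS[i][1] for i in pidx], oa)
    return ea, oa


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_alpha(cfg: SimConfig, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    J = gamma.size
    mode = cfg.pleiotropy_mode
    if mode == "none":
        return np.zeros(J)
    if mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, J)
    elif mode == "directional":
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, J)
    else:
        # inside_violating: pleiotropy correlated with instrument strength
        gs = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
        z = rng.standard_normal(J)
        rho = cfg.inside_rho
        alpha = cfg.pleiotropy_mean + cfg.pleiotropy_sd * (
            rho * gs + np.sqrt(max(0.0, 1 - rho**2)) * z
        )
    if cfg.pleiotropy_frac < 1.0:
        affected = rng.random(J) < cfg.pleiotropy_frac
        alpha = np.where(affected, alpha, 0.0)
    return alpha


def _rescale_gamma(gamma: np.ndarray, sigma_x: np.ndarray, mean_f: float) -> np.ndarray:
    """Orient to the trait-increasing allele and scale so mean true F = mean_f."""
    gamma = np.abs(gamma)
    current = np.mean(gamma**2 / sigma_x**2)
    if current <= 0:
        return gamma
    return gamma * np.sqrt(mean_f / current)


def _table(trait: str, trait_type: str, ids, chrom, pos, ea, oa, eaf, beta, se, n) -> SummaryStatsTable:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _pvalues(np.asarray(beta), np.asarray(se)),
            "n": float(n),
        }
    )
    return SummaryStatsTable(trait, trait_type, df[SUMMARY_COLUMNS])


def _swap_outcome_alleles(table: SummaryStatsTable, frac: float, rng) -> SummaryStatsTable:
    """Report a fraction of outcome rows on the opposite allele orientation."""
    if frac <= 0:
        return table
    df = table.data.copy()
    swap = rng.random(len(df)) < frac
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    df.loc[swap, "effect_allele"] = oa[swap]
    df.loc[swap, "other_allele"] = ea[swap]
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    return SummaryStatsTable(table.trait_name, table.trait_type, df)


def simulate_pair(config: SimConfig) -> SimulatedPair:
    """Generate exposure and outcome summary tables plus the generating truth."""
    cfg = config
    (rng_truth, rng_x, rng_y, rng_decoy, rng_rev, _rng_med,
     rng_alleles, rng_swap) = _streams(cfg.seed)

    J = cfg.n_snps
    maf = rng_truth.uniform(*cfg.maf_range, J)
    sx = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure)
    sy = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_outcome)
    gamma = _rescale_gamma(rng_truth.normal(0.0, cfg.gamma_sd, J), sx, cfg.mean_f)
    alpha = _draw_alpha(cfg, gamma, rng_truth)

    gamma_hat = gamma + cfg.noise_scale * sx * rng_x.standard_normal(J)
    Gamma_hat = (
        cfg.theta * gamma + alpha + cfg.noise_scale * sy * rng_y.standard_normal(J)
    )

    chrom, pos, block_of = _positions(J, cfg.ld_blocks)
    ids = np.array([f"rs{i + 1}" for i in range(J)])
    ld = _ld_from_blocks(ids, block_of, cfg.ld_blocks)
    ea, oa = _alleles(rng_alleles, J, cfg.palindromic_frac)

    all_ids = [ids]
    all_chrom = [chrom]
    all_pos = [pos]
    all_ea, all_oa = [ea], [oa]
    all_maf = [maf]
    bx, sxl = [gamma_hat], [sx]
    by, syl = [Gamma_hat], [sy]

    # decoy SNPs: exposure p above decoy_p_min by construction, no true effect
    if cfg.n_null_snps > 0:
        K = cfg.n_null_snps
        dmaf = rng_decoy.uniform(*cfg.maf_range, K)
        dsx = 1.0 / np.sqrt(2 * dmaf * (1 - dmaf) * cfg.n_exposure)
        dsy = 1.0 / np.sqrt(2 * dmaf * (1 - dmaf) * cfg.n_outcome)
        p_u = rng_decoy.uniform(cfg.decoy_p_min, 1.0, K)
        sign = rng_decoy.choice([-1.0, 1.0], K)
        dbx = sign * stats.norm.isf(p_u / 2) * dsx
        dby = cfg.noise_scale * dsy * rng_decoy.standard_normal(K)
        dids = np.array([f"rsnull{i + 1}" for i in range(K)])
        dch = np.array([str(i % 22 + 1) for i in range(K)])
        dpos = np.array([200_000_000 + (i // 22) * 50_000_000 for i in range(K)], dtype=np.int64)
        dea, doa = _alleles(rng_decoy, K, 0.0)
        all_ids.append(dids); all_chrom.append(dch); all_pos.append(dpos)
        all_ea.append(dea); all_oa.append(doa); all_maf.append(dmaf)
        bx.append(dbx); sxl.append(dsx); by.append(dby); syl.append(dsy)

    # outcome-specific SNPs: instruments for the outcome trait (reverse MR)
    delta = np.array([])
    if cfg.n_outcome_snps > 0:
        K = cfg.n_outcome_snps
        rmaf = rng_rev.uniform(*cfg.maf_range, K)
        rsx = 1.0 / np.sqrt(2 * rmaf * (1 - rmaf) * cfg.n_exposure)
        rsy = 1.0 / np.sqrt(2 * rmaf * (1 - rmaf) * cfg.n_outcome)
        delta = _rescale_gamma(rng_rev.normal(0.0, cfg.gamma_sd, K), rsy, cfg.mean_f)
        rby = delta + cfg.noise_scale * rsy * rng_rev.standard_normal(K)
        rbx = cfg.theta_reverse * delta + cfg.noise_scale * rsx * rng_rev.standard_normal(K)
        rids = np.array([f"rsout{i + 1}" for i in range(K)])
        rch = np.array([str(i % 22 + 1) for i in range(K)])
        rpos = np.array([400_000_000 + (i // 22) * 50_000_000 for i in range(K)], dtype=np.int64)
        rea, roa = _alleles(rng_rev, K, 0.0)
        all_ids.append(rids); all_chrom.append(rch); all_pos.append(rpos)
        all_ea.append(rea); all_oa.append(roa); all_maf.append(rmaf)
        bx.append(rbx); sxl.append(rsx); by.append(rby); syl.append(rsy)

    ids_all = np.concatenate(all_ids)
    chrom_all = np.concatenate(all_chrom)
    pos_all = np.concatenate(all_pos)
    ea_all = np.concatenate(all_ea)
    oa_all = np.concatenate(all_oa)
    maf_all = np.concatenate(all_maf)

    exposure = _table(
        "exposure", "continuous", ids_all, chrom_all, pos_all, ea_all, oa_all,
        maf_all, np.concatenate(bx), np.concatenate(sxl), cfg.n_exposure,
    )
    outcome = _table(
        "outcome", "binary", ids_all, chrom_all, pos_all, ea_all, oa_all,
        maf_all, np.concatenate(by), np.concatenate(syl), cfg.n_outcome,
    )
    outcome = _swap_outcome_alleles(outcome, cfg.swapped_allele_frac, rng_swap)

    truth = SimTruth(
        config={k: v for k, v in dataclasses.asdict(cfg).items() if k != "mediation"},
        variant_ids=[str(v) for v in ids],
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        maf=maf.tolist(),
        delta_outcome=delta.tolist(),
    )
    return SimulatedPair(exposure=exposure, outcome=outcome, ld=ld, truth=truth)


def simulate_mediation_chain(config: SimConfig) -> SimulatedPair:
    """Generate exposure, mediator and outcome tables for a mediation chain.

    The exposure's instruments affect the mediator through beta1 and the
    outcome through direct_effect + beta1*beta2 (the total effect); the
    mediator's own instruments affect the outcome through beta2 and the
    exposure not at all. The truth records the analytic proportion mediated
    beta1*beta2 / (direct_effect + beta1*beta2).
    """
    cfg = config
    if cfg.mediation is None:
        raise ConfigurationError("simulate_mediation_chain requires config.mediation")
    med = cfg.mediation
    (rng_truth, rng_x, rng_y, _rng_decoy, _rng_rev, rng_med,
     rng_alleles, _rng_swap) = _streams(cfg.seed)

    J = cfg.n_snps
    maf = rng_truth.uniform(*cfg.maf_range, J)
    sx = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure)
    sm = 1.0 / np.sqrt(2 * maf * (1 - maf) * med.n_mediator)
    sy = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_outcome)
    gamma = _rescale_gamma(rng_truth.normal(0.0, cfg.gamma_sd, J), sx, cfg.mean_f)
    alpha = _draw_alpha(cfg, gamma, rng_truth)
    total = med.total_effect

    K = med.n_mediator_snps
    mmaf = rng_med.uniform(*cfg.maf_range, K)
    msx = 1.0 / np.sqrt(2 * mmaf * (1 - mmaf) * cfg.n_exposure)
    msm = 1.0 / np.sqrt(2 * mmaf * (1 - mmaf) * med.n_mediator)
    msy = 1.0 / np.sqrt(2 * mmaf * (1 - mmaf) * cfg.n_outcome)
    m_eff = _rescale_gamma(rng_med.normal(0.0, cfg.gamma_sd, K), msm, cfg.mean_f)

    ns = cfg.noise_scale
    # exposure instruments (rs*) and mediator instruments (rsmed*)
    gamma_hat = gamma + ns * sx * rng_x.standard_normal(J)
    x_on_med_snps = 0.0 * m_eff + ns * msx * rng_x.standard_normal(K)
    med_hat = med.beta1 * gamma + ns * sm * rng_med.standard_normal(J)
    m_eff_hat = m_eff + ns * msm * rng_med.standard_normal(K)
    out_hat = total * gamma + alpha + ns * sy * rng_y.standard_normal(J)
    out_on_med_snps = med.beta2 * m_eff + ns * msy * rng_y.standard_normal(K)

    chrom, pos, block_of = _positions(J, cfg.ld_blocks)
    ids = np.array([f"rs{i + 1}" for i in range(J)])
    ld = _ld_from_blocks(ids, block_of, cfg.ld_blocks)
    ea, oa = _alleles(rng_alleles, J, cfg.palindromic_frac)
    mids = np.array([f"rsmed{i + 1}" for i in range(K)])
    mch = np.array([str(i % 22 + 1) for i in range(K)])
    mpos = np.array([600_000_000 + (i // 22) * 50_000_000 for i in range(K)], dtype=np.int64)
    mea, moa = _alleles(rng_alleles, K, 0.0)

    ids_all = np.concatenate([ids, mids])
    chrom_all = np.concatenate([chrom, mch])
    pos_all = np.concatenate([pos, mpos])
    ea_all = np.concatenate([ea, mea])
    oa_all = np.concatenate([oa, moa])
    maf_all = np.concatenate([maf, mmaf])

    exposure = _table(
        "exposure", "continuous", ids_all, chrom_all, pos_all, ea_all, oa_all,
        maf_all, np.concatenate([gamma_hat, x_on_med_snps]),
        np.concatenate([sx, msx]), cfg.n_exposure,
    )
    mediator = _table(
        "mediator", "continuous", ids_all, chrom_all, pos_all, ea_all, oa_all,
        maf_all, np.concatenate([med_hat, m_eff_hat]),
        np.concatenate([sm, msm]), med.n_mediator,
    )
    outcome = _table(
        "outcome", "binary", ids_all, chrom_all, pos_all, ea_all, oa_all,
        maf_all, np.concatenate([out_hat, out_on_med_snps]),
        np.concatenate([sy, msy]), cfg.n_outcome,
    )
    truth = SimTruth(
        config=dataclasses.asdict(cfg),
        variant_ids=[str(v) for v in ids],
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        maf=maf.tolist(),
        proportion_mediated=med.proportion,
    )
    return SimulatedPair(
        exposure=exposure, outcome=outcome, ld=ld, truth=truth, mediator=mediator
    )
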