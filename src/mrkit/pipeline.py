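"""Study orchestration: forward MR screens, FDR, reverse MR, eQTL mode.

``run_forward`` drives the full exposure x outcome grid: class-appropriate
instrument selection (microbiome p < 1e-5, cytokine p < 5e-6, otherwise
genome-wide 5e-8), harmonization, the five estimators, and the sensitivity
suite, with Benjamini-Hochberg FDR applied to the IVW p-values within each
(outcome, exposure-class) family. Pairs that fail selection or harmonization
are logged skips, never fatal, so one degenerate exposure cannot abort a
large screen. ``run_reverse`` swaps roles for the nominally significant
forward pairs; ``run_eqtl_mode`` is the forward screen with cis-eQTL
conventions (clumping at r^2 = 0.1, one gene per exposure) plus a
directionality-consistency flag across methods. ``run_pipeline`` is the
file-driven entry point used by the CLI.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .datatypes import MREstimate, SummaryStatsTable
from .exceptions import (
    ConfigurationError,
    HarmonizationError,
    InputError,
    MRKitError,
    SelectionError,
)
from .estimators import run_all_methods
from .instruments import LDMatrix, SelectionConfig, select_instruments
from .mediation import two_step_mediation
from .sensitivity import sensitivity_report
from .summary_io import harmonize, read_summary_stats

log = logging.getLogger("mrkit.pipeline")

RESULT_COLUMNS = [
    "exposure", "exposure_class", "outcome", "direction", "method", "n_snps",
    "beta", "se", "ci_low", "ci_high", "or", "or_low", "or_high", "pval",
    "p_fdr", "egger_intercept", "egger_intercept_p",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TraitSpec:
    """One trait table plus its class label for threshold selection."""

    path: str
    name: str
    trait_class: str = "default"  # microbiome|cytokine|eqtl|disease|default
    trait_type: str = "continuous"


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run (YAML-loadable)."""

    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    ld_path: str | None = None
    selection_overrides: dict[str, dict] = field(default_factory=dict)
    fdr_alpha: float = 0.05
    reverse_p_threshold: float = 5e-8
    reverse: bool = True
    mediators: list[TraitSpec] = field(default_factory=list)
    gate_alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0
    out_dir: str = "mr_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        def specs(key):
            return [TraitSpec(**d) for d in raw.pop(key, [])]
        exposures = specs("exposures")
        outcomes = specs("outcomes")
        mediators = specs("mediators")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(exposures=exposures, outcomes=outcomes, mediators=mediators, **raw)

    def validate(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")
        for spec in [*self.exposures, *self.outcomes, *self.mediators]:
            if not Path(spec.path).exists():
                raise ConfigurationError(f"trait file not found: {spec.path}")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            raise ConfigurationError(f"LD file not found: {self.ld_path}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an explicit integer")


@dataclass
class PairOutcome:
    """Everything computed for one exposure/outcome pair."""

    exposure: str
    outcome: str
    estimates: list[MREstimate]
    skipped_methods: list[dict]
    sensitivity: "object"
    n_snps: int


@dataclass
class ForwardResult:
    results: pd.DataFrame
    sensitivity: pd.DataFrame
    skipped_pairs: list[dict] = field(default_factory=list)


def _estimate_rows(
    exposure: str, exposure_class: str, outcome: str, direction: str,
    estimates: list[MREstimate],
) -> list[dict]:
    rows = []
    for est in estimates:
        rows.append(
            {
                "exposure": exposure,
                "exposure_class": exposure_class,
                "outcome": outcome,
                "direction": direction,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "or": est.or_value,
                "or_low": est.or_low,
                "or_high": est.or_high,
                "pval": est.pvalue,
                "p_fdr": np.nan,
                "egger_intercept": est.extra.get("intercept", np.nan),
                "egger_intercept_p": est.extra.get("intercept_pvalue", np.nan),
            }
        )
    return rows


def _pair_seed(master: int, index: int) -> int:
    return int(
        np.random.SeedSequence(master, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def analyse_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    selection: SelectionConfig,
    *,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> PairOutcome:
    """Select instruments, harmonize, run all estimators and diagnostics."""
    chosen = select_instruments(exposure, ld, selection)
    hset = harmonize(exposure, outcome, chosen.ids)
    estimates, skipped = run_all_methods(hset, n_boot=n_boot, seed=seed)
    sens = sensitivity_report(hset, n_sim=presso_n_sim, seed=seed)
    return PairOutcome(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        estimates=estimates,
        skipped_methods=skipped,
        sensitivity=sens,
        n_snps=hset.n_snps,
    )


def _apply_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust IVW p-values within each (outcome, exposure class) family."""
    results = results.copy()
    ivw_mask = results["method"] == "ivw"
    for (_outcome, _cls), idx in results[ivw_mask].groupby(
        ["outcome", "exposure_class"]
    ).groups.items():
        results.loc[idx, "p_fdr"] = bh_fdr(results.loc[idx, "pval"].to_numpy())
    return results


def run_forward(
    exposures: list[tuple[SummaryStatsTable, str]],
    outcomes: list[SummaryStatsTable],
    ld: LDMatrix,
    *,
    selection_overrides: dict[str, dict] | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
    direction: str = "forward",
) -> ForwardResult:
    """MR of every exposure against every outcome, with per-family FDR.

    ``exposures`` pairs each table with its class label; selection thresholds
    come from :meth:`SelectionConfig.for_trait_class` plus any per-class
    overrides. Failed pairs are recorded in ``skipped_pairs``.
    """
    overrides = selection_overrides or {}
    rows: list[dict] = []
    sens_rows: list[dict] = []
    skipped: list[dict] = []
    pair_index = 0
    for exp_table, trait_class in exposures:
        selection = SelectionConfig.for_trait_class(
            trait_class, **overrides.get(trait_class, {})
        )
        for out_table in outcomes:
            pair_seed = _pair_seed(seed, pair_index)
            pair_index += 1
            try:
                pair = analyse_pair(
                    exp_table, out_table, ld, selection,
                    seed=pair_seed, n_boot=n_boot, presso_n_sim=presso_n_sim,
                )
            except (SelectionError, HarmonizationError) as exc:
                log.warning(
                    "skip %s -> %s: %s", exp_table.trait_name, out_table.trait_name, exc
                )
                skipped.append(
                    {
                        "exposure": exp_table.trait_name,
                        "outcome": out_table.trait_name,
                        "reason": str(exc),
                    }
                )
                continue
            rows.extend(
                _estimate_rows(
                    pair.exposure, trait_class, pair.outcome, direction, pair.estimates
                )
            )
            sens_rows.append(pair.sensitivity.to_row())
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not results.empty:
        results = _apply_fdr(results)
    sensitivity = pd.DataFrame(sens_rows)
    return ForwardResult(results=results, sensitivity=sensitivity, skipped_pairs=skipped)


def significant_forward_pairs(
    forward: ForwardResult, alpha: float = 0.05
) -> list[tuple[str, str]]:
    """(exposure, outcome) pairs with nominal IVW p < alpha."""
    res = forward.results
    ivw = res[(res["method"] == "ivw") & (res["pval"] < alpha)]
    return list(ivw[["exposure", "outcome"]].itertuples(index=False, name=None))


def run_reverse(
    forward: ForwardResult,
    exposures: dict[str, SummaryStatsTable],
    outcomes: dict[str, SummaryStatsTable],
    ld: LDMatrix,
    *,
    reverse_p_threshold: float = 5e-8,
    significance: float = 0.05,
    selection_overrides: dict[str, dict] | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> ForwardResult:
    """Reverse MR: outcomes become exposures for each significant forward pair.

    Disease instruments are selected at ``reverse_p_threshold`` with the same
    clumping; a reverse IVW p < 0.05 flags potential reverse causality
    (column ``reverse_significant`` on the IVW rows).
    """
    overrides = dict(selection_overrides or {})
    disease_over = dict(overrides.get("disease", {}))
    disease_over.setdefault("p_threshold", reverse_p_threshold)
    pairs = significant_forward_pairs(forward, significance)
    reverse_pairs: list[tuple[SummaryStatsTable, str]] = []
    seen = set()
    rows = []
    sens_rows = []
    skipped = []
    pair_index = 10_000  # distinct stream block from the forward run
    for exp_name, out_name in pairs:
        key = (out_name, exp_name)
        if key in seen:
            continue
        seen.add(key)
        disease = outcomes[out_name]
        gm = exposures[exp_name]
        selection = SelectionConfig.for_trait_class("disease", **disease_over)
        pair_seed = _pair_seed(seed, pair_index)
        pair_index += 1
        try:
            pair = analyse_pair(
                disease, gm, ld, selection,
                seed=pair_seed, n_boot=n_boot, presso_n_sim=presso_n_sim,
            )
        except (SelectionError, HarmonizationError) as exc:
            log.warning("reverse skip %s -> %s: %s", out_name, exp_name, exc)
            skipped.append({"exposure": out_name, "outcome": exp_name, "reason": str(exc)})
            continue
        rows.extend(
            _estimate_rows(out_name, "disease", exp_name, "reverse", pair.estimates)
        )
        sens_rows.append(pair.sensitivity.to_row())
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if not results.empty:
        ivw = results["method"] == "ivw"
        results["reverse_significant"] = np.nan
        results.loc[ivw, "reverse_significant"] = (
            results.loc[ivw, "pval"] < 0.05
        ).astype(float)
    else:
        results["reverse_significant"] = pd.Series(dtype=float)
    return ForwardResult(results=results, sensitivity=pd.DataFrame(sens_rows), skipped_pairs=skipped)


def run_eqtl_mode(
    gene_exposures: list[SummaryStatsTable],
    outcomes: list[SummaryStatsTable],
    ld: LDMatrix,
    *,
    selection_overrides: dict[str, dict] | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> ForwardResult:
    """Transcriptomic MR: one gene per exposure, clumping at r^2 = 0.1.

    Adds a per-pair ``direction_consistent`` flag (1.0 when every computed
    method agrees on the sign of the effect) and BH FDR across genes within
    each outcome.
    """
    forward = run_forward(
        [(g, "eqtl") for g in gene_exposures],
        outcomes,
        ld,
        selection_overrides=selection_overrides,
        seed=seed,
        n_boot=n_boot,
        presso_n_sim=presso_n_sim,
    )
    res = forward.results
    if res.empty:
        res["direction_consistent"] = pd.Series(dtype=float)
        return forward
    res["direction_consistent"] = np.nan
    for (_exp, _out), idx in res.groupby(["exposure", "outcome"]).groups.items():
        signs = np.sign(res.loc[idx, "beta"].to_numpy())
        consistent = float(np.all(signs == signs[0]))
        ivw_idx = [i for i in idx if res.loc[i, "method"] == "ivw"]
        res.loc[ivw_idx, "direction_consistent"] = consistent
    forward.results = res
    return forward


def run_mediation(
    forward: ForwardResult,
    exposures: dict[str, SummaryStatsTable],
    mediators: list[tuple[SummaryStatsTable, str]],
    outcomes: dict[str, SummaryStatsTable],
    ld: LDMatrix,
    *,
    selection_overrides: dict[str, dict] | None = None,
    gate_alpha: float = 0.05,
    significance: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Two-step mediation for every significant forward pair x mediator.

    beta1 instruments the exposure against the mediator, beta2 instruments
    the mediator against the outcome, beta3 is the forward (total) IVW.
    """
    overrides = selection_overrides or {}
    res = forward.results
    rows = []
    pair_index = 20_000
    for exp_name, out_name in significant_forward_pairs(forward, significance):
        total_row = res[
            (res["exposure"] == exp_name)
            & (res["outcome"] == out_name)
            & (res["method"] == "ivw")
        ].iloc[0]
        total = MREstimate.build(
            "ivw", total_row["beta"], total_row["se"], int(total_row["n_snps"]),
            pvalue=total_row["pval"],
        )
        exp_class = str(total_row["exposure_class"])
        exp_table = exposures[exp_name]
        out_table = outcomes[out_name]
        for med_table, med_class in mediators:
            sel_exp = SelectionConfig.for_trait_class(
                exp_class, **overrides.get(exp_class, {})
            )
            sel_med = SelectionConfig.for_trait_class(
                med_class, **overrides.get(med_class, {})
            )
            try:
                step1_ids = select_instruments(exp_table, ld, sel_exp).ids
                h1 = harmonize(exp_table, med_table, step1_ids)
                est1, _ = run_all_methods(
                    h1, n_boot=n_boot, seed=_pair_seed(seed, pair_index)
                )
                step2_ids = select_instruments(med_table, ld, sel_med).ids
                h2 = harmonize(med_table, out_table, step2_ids)
                est2, _ = run_all_methods(
                    h2, n_boot=n_boot, seed=_pair_seed(seed, pair_index + 1)
                )
            except (SelectionError, HarmonizationError) as exc:
                log.warning(
                    "mediation skip %s -> %s -> %s: %s",
                    exp_name, med_table.trait_name, out_name, exc,
                )
                pair_index += 2
                continue
            pair_index += 2
            step1 = next(e for e in est1 if e.method == "ivw")
            step2 = next(e for e in est2 if e.method == "ivw")
            result = two_step_mediation(
                step1, step2, total, gate_alpha,
                exposure=exp_name, mediator=med_table.trait_name, outcome=out_name,
            )
            rows.append(result.to_row())
    columns = [
        "exposure", "mediator", "outcome", "beta1", "se1", "beta2", "se2",
        "beta3", "se3", "indirect", "indirect_se", "proportion", "gate_passed",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """File-driven forward + reverse (+ mediation) run; writes TSV outputs.

    Writes ``results.tsv``, ``sensitivity.tsv`` and ``mediation.tsv`` under
    ``config.out_dir`` and attaches a ``run.log`` capturing skip decisions.
    Identical config and seed give byte-identical outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mrkit")
    root.addHandler(handler)
    prior_level = root.level
    root.setLevel(min(root.level or logging.INFO, logging.INFO))
    try:
        ld = LDMatrix.from_file(config.ld_path) if config.ld_path else LDMatrix.identity()
        exposures = [
            (
                read_summary_stats(s.path, trait_name=s.name, trait_type=s.trait_type),
                s.trait_class,
            )
            for s in config.exposures
        ]
        outcomes = [
            read_summary_stats(s.path, trait_name=s.name, trait_type=s.trait_type)
            for s in config.outcomes
        ]
        mediators = [
            (
                read_summary_stats(s.path, trait_name=s.name, trait_type=s.trait_type),
                s.trait_class,
            )
            for s in config.mediators
        ]
        forward = run_forward(
            exposures, outcomes, ld,
            selection_overrides=config.selection_overrides,
            seed=config.seed, n_boot=config.n_boot, presso_n_sim=config.presso_n_sim,
        )
        results = forward.results
        sensitivity = forward.sensitivity
        if config.reverse:
            reverse = run_reverse(
                forward,
                {t.trait_name: t for t, _ in exposures},
                {t.trait_name: t for t in outcomes},
                ld,
                reverse_p_threshold=config.reverse_p_threshold,
                selection_overrides=config.selection_overrides,
                seed=config.seed, n_boot=config.n_boot,
                presso_n_sim=config.presso_n_sim,
            )
            if not reverse.results.empty:
                results = pd.concat([results, reverse.results], ignore_index=True)
            if not reverse.sensitivity.empty:
                sensitivity = pd.concat(
                    [sensitivity, reverse.sensitivity], ignore_index=True
                )
        mediation = run_mediation(
            forward,
            {t.trait_name: t for t, _ in exposures},
            mediators,
            {t.trait_name: t for t in outcomes},
            ld,
            selection_overrides=config.selection_overrides,
            gate_alpha=config.gate_alpha,
            seed=config.seed, n_boot=config.n_boot,
        )
        results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        sensitivity.to_csv(out_dir / "sensitivity.tsv", sep="\t", index=False)
        mediation.to_csv(out_dir / "mediation.tsv", sep="\t", index=False)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prior_level)
    return {"results": results, "sensitivity": sensitivity, "mediation": mediation}
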