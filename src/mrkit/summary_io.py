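"""Read, validate and write GWAS summary statistics; harmonize pairs.

Input tables are delimited text with a header row. Column names default to
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n`` and can
be remapped via ``column_map``. Rows violating basic contracts (unparseable
numbers, se <= 0, identical or non-ACGT alleles, p outside (0, 1]) are dropped
and counted in the log rather than aborting the read.

Harmonization aligns the outcome association onto the exposure's effect-allele
frame: matched-orientation SNPs pass through, swapped-allele SNPs get their
outcome beta sign flipped (and eaf complemented), palindromic (A/T, C/G) SNPs
are removed unconditionally because strand cannot be resolved from alleles
alone, and anything matching neither orientation is dropped.
"""
from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .datatypes import (
    COMPLEMENT,
    HARMONIZED_COLUMNS,
    SUMMARY_COLUMNS,
    VALID_ALLELES,
    HarmonizedInstrumentSet,
    SummaryStatsTable,
)
from .exceptions import ConfigurationError, HarmonizationError, InputError

log = logging.getLogger("mrkit.summary_io")

#: Standard-field -> file-column defaults.
DEFAULT_COLUMN_MAP = {
    "variant_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

_MANDATORY = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
)


def read_summary_stats(
    path,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a summary-statistics table, dropping and logging invalid rows."""
    colmap = dict(DEFAULT_COLUMN_MAP)
    colmap.update(column_map or {})
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for std in _MANDATORY:
        if colmap[std] not in raw.columns:
            raise ConfigurationError(
                f"{path}: missing mandatory column {colmap[std]!r} (field {std!r})"
            )

    df = pd.DataFrame(index=raw.index)
    df["variant_id"] = raw[colmap["variant_id"]].astype(str).str.strip()
    df["chrom"] = raw[colmap["chrom"]].astype(str).str.strip()
    df["pos"] = pd.to_numeric(raw[colmap["pos"]], errors="coerce")
    for a in ("effect_allele", "other_allele"):
        df[a] = raw[colmap[a]].astype(str).str.strip().str.upper()
    for f in ("beta", "se", "pvalue"):
        df[f] = pd.to_numeric(raw[colmap[f]], errors="coerce")
    df["eaf"] = (
        pd.to_numeric(raw[colmap["eaf"]], errors="coerce")
        if colmap["eaf"] in raw.columns
        else np.nan
    )
    df["n"] = (
        pd.to_numeric(raw[colmap["n"]], errors="coerce")
        if colmap["n"] in raw.columns
        else np.nan
    )

    checks = [
        ("unparseable", df[["beta", "se", "pvalue", "pos"]].isna().any(axis=1)),
        ("bad_position", df["pos"].notna() & (df["pos"] < 1)),
        (
            "non_snp_allele",
            ~(
                df["effect_allele"].isin(VALID_ALLELES)
                & df["other_allele"].isin(VALID_ALLELES)
            ),
        ),
        ("identical_alleles", df["effect_allele"] == df["other_allele"]),
        ("nonpositive_se", df["se"].notna() & (df["se"] <= 0)),
        (
            "pvalue_range",
            df["pvalue"].notna() & ((df["pvalue"] <= 0) | (df["pvalue"] > 1)),
        ),
        ("eaf_range", df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))),
    ]
    drops = Counter()
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks:
        drops[reason] += int((mask & ~bad).sum())
        bad = bad | mask
    drops = Counter({k: v for k, v in drops.items() if v})

    df = df[~bad].copy()
    dup = df["variant_id"].duplicated()
    if dup.any():
        drops["duplicate_id"] += int(dup.sum())
        df = df[~dup]
    if drops:
        log.warning("%s: dropped rows %s", path, dict(drops))
    if df.empty:
        raise InputError(f"{path}: no valid rows after filtering")
    df["pos"] = df["pos"].astype(np.int64)
    name = trait_name if trait_name is not None else str(path)
    return SummaryStatsTable(name, trait_type, df.reset_index(drop=True)[SUMMARY_COLUMNS])


def write_summary_stats(table: SummaryStatsTable, path, sep: str = "\t") -> None:
    """Write a table back out under the default column names."""
    out = table.data.rename(
        columns={"variant_id": "snp", "chrom": "chr", "pvalue": "pval"}
    )
    out.to_csv(path, sep=sep, index=False)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the pair is strand-ambiguous, i.e. {A,T} or {C,G}."""
    ea = str(effect_allele).upper()
    oa = str(other_allele).upper()
    for a in (ea, oa):
        if a not in VALID_ALLELES:
            raise InputError(f"allele {a!r} outside A/C/G/T")
    return COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    snp_ids: list[str] | None = None,
) -> HarmonizedInstrumentSet:
    """Align exposure and outcome associations onto one effect-allele frame.

    Parameters
    ----------
    exposure, outcome:
        Summary tables for the two traits.
    snp_ids:
        Candidate instruments (drawn from the exposure table). Defaults to
        every exposure SNP.

    Returns
    -------
    HarmonizedInstrumentSet with per-SNP (gamma, sigma_X, Gamma, sigma_Y, F).

    Raises
    ------
    HarmonizationError
        When zero SNPs survive.
    """
    ids = list(snp_ids) if snp_ids is not None else exposure.variant_ids
    exp = exposure.data.set_index("variant_id")
    out = outcome.data.set_index("variant_id")

    records = []
    drops = Counter()
    for vid in ids:
        if vid not in exp.index:
            drops["missing_exposure"] += 1
            continue
        if vid not in out.index:
            drops["missing_outcome"] += 1
            continue
        e = exp.loc[vid]
        o = out.loc[vid]
        if is_palindromic(e["effect_allele"], e["other_allele"]):
            drops["palindromic"] += 1
            continue
        if (o["effect_allele"], o["other_allele"]) == (e["effect_allele"], e["other_allele"]):
            beta_out = float(o["beta"])
        elif (o["effect_allele"], o["other_allele"]) == (e["other_allele"], e["effect_allele"]):
            beta_out = -float(o["beta"])
        else:
            drops["allele_mismatch"] += 1
            continue
        gamma = float(e["beta"])
        sx = float(e["se"])
        records.append(
            {
                "variant_id": vid,
                "beta_exposure": gamma,
                "se_exposure": sx,
                "beta_outcome": beta_out,
                "se_outcome": float(o["se"]),
                "f_stat": (gamma / sx) ** 2,
            }
        )
    if drops:
        log.info(
            "harmonize %s -> %s: dropped %s",
            exposure.trait_name, outcome.trait_name, dict(drops),
        )
    if not records:
        raise HarmonizationError(
            f"no SNPs survived harmonization for {exposure.trait_name!r} -> "
            f"{outcome.trait_name!r} (drops: {dict(drops)})"
        )
    df = pd.DataFrame.from_records(records)[HARMONIZED_COLUMNS]
    return HarmonizedInstrumentSet(exposure.trait_name, outcome.trait_name, df)


def write_harmonized(hset: HarmonizedInstrumentSet, path, sep: str = "\t") -> None:
    out = hset.data.copy()
    out.insert(0, "exposure", hset.exposure_name)
    out.insert(1, "outcome", hset.outcome_name)
    out.to_csv(path, sep=sep, index=False)


def read_harmonized(path, sep: str = "\t") -> HarmonizedInstrumentSet:
    df = pd.read_csv(path, sep=sep)
    exposure = str(df["exposure"].iloc[0])
    outcome = str(df["outcome"].iloc[0])
    return HarmonizedInstrumentSet(exposure, outcome, df[HARMONIZED_COLUMNS].copy())
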