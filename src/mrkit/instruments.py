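"""Instrument selection: p-value thresholding, greedy LD clumping, F screen.

The clumping algorithm is the standard greedy one: repeatedly promote the
smallest-p unclaimed SNP to index status, then claim every unclaimed SNP on
the same chromosome within the window whose r-squared with the index exceeds
the cutoff. Ties on p are broken by (chrom, pos, variant_id) so the result is
deterministic. Weak instruments are screened by F = beta^2 / se^2; values at
or below ``f_min`` (default 10) are dropped or flagged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import SummaryStatsTable, VariantAssociation
from .exceptions import ConfigurationError, InputError, SelectionError

log = logging.getLogger("mrkit.instruments")


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults follow common practice for genome-wide significant instruments;
    ``for_trait_class`` supplies the relaxed thresholds used for microbiome
    taxa (p < 1e-5) and circulating cytokines (p < 5e-6), where few SNPs reach
    5e-8, and the looser clumping (r^2 < 0.1) used for cis-eQTL instruments.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    f_action: str = "drop"  # "drop" | "flag"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigurationError(f"clump_r2 must be in [0,1], got {self.clump_r2}")
        if not self.clump_window_kb > 0:
            raise ConfigurationError("clump_window_kb must be > 0")
        if self.f_action not in ("drop", "flag"):
            raise ConfigurationError(f"f_action must be drop|flag, got {self.f_action!r}")

    _PRESETS = {
        "microbiome": {"p_threshold": 1e-5},
        "cytokine": {"p_threshold": 5e-6},
        "eqtl": {"clump_r2": 0.1},
        "disease": {},
        "default": {},
    }

    @classmethod
    def for_trait_class(cls, trait_class: str | None, **overrides) -> "SelectionConfig":
        """Class-specific defaults, overridable field by field."""
        key = trait_class if trait_class is not None else "default"
        if key not in cls._PRESETS:
            raise ConfigurationError(
                f"unknown trait class {trait_class!r}; expected one of "
                f"{sorted(k for k in cls._PRESETS if k != 'default')}"
            )
        params = dict(cls._PRESETS[key])
        params.update(overrides)
        return cls(**params)

    def replace(self, **overrides) -> "SelectionConfig":
        return replace(self, **overrides)


class LDMatrix:
    """Sparse symmetric pairwise r-squared lookup.

    Absent pairs are treated as r^2 = 0 and the diagonal is 1. Two text
    dialects are accepted: whitespace-delimited ``id_a id_b r2`` triplets, or
    a square matrix with an id header row and id first column; ``from_file``
    auto-detects which.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not (0 <= r2 <= 1):
            raise InputError(f"r2({a},{b}) = {r2} outside [0,1]")
        if a == b:
            return  # diagonal is implicit
        self._pairs[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def identity(cls) -> "LDMatrix":
        """All pairs unlinked."""
        return cls()

    @classmethod
    def from_file(cls, path) -> "LDMatrix":
        with open(path) as fh:
            first = ""
            for line in fh:
                if line.strip():
                    first = line
                    break
        tokens = first.split()
        is_triplet = False
        if len(tokens) == 3:
            try:
                float(tokens[2])
                is_triplet = True
            except ValueError:
                is_triplet = False
        if is_triplet:
            ld = cls()
            with open(path) as fh:
                for line in fh:
                    parts = line.split()
                    if not parts:
                        continue
                    if len(parts) != 3:
                        raise InputError(f"{path}: malformed LD triplet line {line!r}")
                    ld.set(parts[0], parts[1], float(parts[2]))
            return ld
        df = pd.read_csv(path, sep=r"\s+", index_col=0)
        if list(df.index) != list(df.columns):
            raise InputError(f"{path}: square LD matrix ids differ between rows and columns")
        arr = df.to_numpy(float)
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise InputError(f"{path}: LD matrix is not symmetric")
        ld = cls()
        ids = list(df.index.astype(str))
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if arr[i, j] != 0.0:
                    ld.set(a, ids[j], arr[i, j])
        return ld

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (a, b), r2 in sorted(self._pairs.items()):
                fh.write(f"{a}\t{b}\t{r2:.6g}\n")


def f_statistic(beta, se):
    """Instrument-strength F statistic, beta^2 / se^2 (vectorized)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InputError("se must be > 0 for the F statistic")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def _candidate_frame(candidates) -> pd.DataFrame:
    if isinstance(candidates, SummaryStatsTable):
        return candidates.data[["variant_id", "chrom", "pos", "pvalue"]].copy()
    if isinstance(candidates, pd.DataFrame):
        return candidates[["variant_id", "chrom", "pos", "pvalue"]].copy()
    rows = [
        {"variant_id": c.variant_id, "chrom": c.chrom, "pos": c.pos, "pvalue": c.pvalue}
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "pvalue"])


def clump(candidates, ld: LDMatrix, config: SelectionConfig) -> list[str]:
    """Greedy LD clumping; returns retained (index) SNP ids in selection order.

    A SNP is claimed by an index SNP when it lies on the same chromosome
    within ``clump_window_kb`` (inclusive, positions 1-based) and its r^2
    with the index exceeds ``clump_r2``.
    """
    df = _candidate_frame(candidates)
    if df.empty:
        return []
    df = df.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = config.clump_window_kb * 1000.0
    ids = df["variant_id"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(float)
    claimed = np.zeros(len(df), dtype=bool)
    retained: list[str] = []
    for i in range(len(df)):
        if claimed[i]:
            continue
        claimed[i] = True
        retained.append(str(ids[i]))
        near = (~claimed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.nonzero(near)[0]:
            if ld.r2(str(ids[i]), str(ids[j])) > config.clump_r2:
                claimed[j] = True
    return retained


@dataclass
class InstrumentSelection:
    """Outcome of select_instruments: ids kept, their F values, and a tally."""

    ids: list[str]
    f_stats: pd.Series = field(repr=False)
    weak_ids: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def select_instruments(
    exposure: SummaryStatsTable, ld: LDMatrix, config: SelectionConfig
) -> InstrumentSelection:
    """Threshold on p, clump, and screen by F, logging counts at each stage."""
    df = exposure.data
    sig = df[df["pvalue"] < config.p_threshold]
    counts = {"candidates": len(df), "significant": len(sig)}
    if sig.empty:
        raise SelectionError(
            f"{exposure.trait_name!r}: no SNP passes p < {config.p_threshold:g}"
        )
    kept = clump(sig, ld, config)
    counts["post_clump"] = len(kept)
    sub = sig.set_index("variant_id").loc[kept]
    f = pd.Series(f_statistic(sub["beta"], sub["se"]), index=sub.index, name="f_stat")
    weak = [vid for vid in kept if f[vid] <= config.f_min]
    if config.f_action == "drop":
        kept = [vid for vid in kept if vid not in set(weak)]
    counts["weak"] = len(weak)
    counts["selected"] = len(kept)
    log.info("select %s: %s", exposure.trait_name, counts)
    if not kept:
        raise SelectionError(
            f"{exposure.trait_name!r}: no instrument survives the F > {config.f_min:g} screen"
        )
    return InstrumentSelection(
        ids=kept, f_stats=f.loc[kept], weak_ids=weak, counts=counts
    )
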