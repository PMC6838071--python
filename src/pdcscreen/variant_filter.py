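"""Post-calling somatic variant filter chain and mutation-spectrum summaries.

Candidates arrive from upstream callers as a MAF-like table with tumor/normal
depths and allele fractions, strand counts, a population allele frequency and
an effect-class annotation.  The filter chain retains a candidate only when
it clears every criterion; decisions record *all* violated criteria so the
per-criterion attrition can be logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: effect classes recognised in the ``effect_class`` column
EFFECT_CLASSES = (
    "missense",
    "stopgain",
    "stoploss",
    "splice",
    "frameshift_ins",
    "frameshift_del",
    "nonframeshift_ins",
    "nonframeshift_del",
    "synonymous",
    "other",
)

#: columns a candidate table must carry
REQUIRED_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "tumor_depth",
    "tumor_alt_reads",
    "tumor_vaf",
    "normal_vaf",
    "strand_bias",
    "population_freq",
    "effect_class",
    "near_repeat",
)

#: criterion names emitted in FilterDecision.failed_criteria
CRITERIA = (
    "min_tumor_depth",
    "max_normal_vaf",
    "min_vaf_diff",
    "max_strand_bias",
    "min_alt_reads",
    "max_population_freq",
    "effect_class",
    "near_repeat",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter chain.

    Boundary semantics follow the wording "minimum/maximum ... is X":
    depth >= 30, normal VAF <= 0.03, tumor-normal VAF difference >= 0.05
    (signed, tumor minus normal), strand bias <= 0.9, alt reads >= 5.  The
    population filter removes strictly > 0.015.
    """

    min_tumor_depth: int = 30
    max_normal_vaf: float = 0.03
    min_vaf_diff: float = 0.05
    max_strand_bias: float = 0.9
    min_alt_reads: int = 5
    max_population_freq: float = 0.015
    retained_effect_classes: tuple[str, ...] = field(
        default_factory=lambda: tuple(c for c in EFFECT_CLASSES if c != "other")
    )
    drop_near_repeat: bool = True

    def __post_init__(self) -> None:
        for name in ("min_tumor_depth", "max_normal_vaf", "min_vaf_diff",
                     "max_strand_bias", "min_alt_reads", "max_population_freq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("max_normal_vaf", "min_vaf_diff", "max_strand_bias",
                     "max_population_freq"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} is a fraction and must be <= 1")
        unknown = set(self.retained_effect_classes) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")


def _validate_candidates(candidates: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    for col in ("tumor_vaf", "normal_vaf", "strand_bias", "population_freq"):
        vals = candidates[col].to_numpy(float)
        bad = np.flatnonzero(~((vals >= 0) & (vals <= 1)))
        if bad.size:
            raise ValueError(f"row {bad[0]}: {col} outside [0, 1]")
    alt = candidates["tumor_alt_reads"].to_numpy()
    depth = candidates["tumor_depth"].to_numpy()
    bad = np.flatnonzero(alt > depth)
    if bad.size:
        raise ValueError(f"row {bad[0]}: tumor_alt_reads exceeds tumor_depth")


def apply_filters(
    candidates: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the filter chain; return (retained table, per-candidate decisions).

    The decision table is indexed like ``candidates`` and has one boolean
    column per criterion (True = violated), a ``pass`` column, and a
    ``failed_criteria`` column holding a comma-joined list of violated
    criterion names (empty string for passing candidates).
    """
    cfg = cfg or FilterConfig()
    _validate_candidates(candidates)

    fails = pd.DataFrame(index=candidates.index)
    fails["min_tumor_depth"] = candidates["tumor_depth"] < cfg.min_tumor_depth
    fails["max_normal_vaf"] = candidates["normal_vaf"] > cfg.max_normal_vaf
    fails["min_vaf_diff"] = (
        candidates["tumor_vaf"] - candidates["normal_vaf"] < cfg.min_vaf_diff
    )
    fails["max_strand_bias"] = candidates["strand_bias"] > cfg.max_strand_bias
    fails["min_alt_reads"] = candidates["tumor_alt_reads"] < cfg.min_alt_reads
    fails["max_population_freq"] = (
        candidates["population_freq"] > cfg.max_population_freq
    )
    fails["effect_class"] = ~candidates["effect_class"].isin(
        cfg.retained_effect_classes
    )
    if cfg.drop_near_repeat:
        fails["near_repeat"] = candidates["near_repeat"].astype(bool)
    else:
        fails["near_repeat"] = False

    decisions = fails.copy()
    decisions["pass"] = ~fails.any(axis=1)
    decisions["failed_criteria"] = [
        ",".join(c for c in CRITERIA if row[c]) for _, row in fails.iterrows()
    ]
    retained = candidates.loc[decisions["pass"]].copy()
    return retained, decisions


def mark_near_repeat(
    candidates: pd.DataFrame, repeats: pd.DataFrame, margin: int = 5
) -> pd.DataFrame:
    """Set the ``near_repeat`` flag from a repeat-region BED table.

    ``repeats`` has BED columns (chrom, start, end), 0-based half-open.  A
    variant at 1-based position p is near a repeat when the interval
    [p-1-margin, p+margin) intersects a repeat on the same chromosome.
    """
    out = candidates.copy()
    flags = np.zeros(len(out), dtype=bool)
    by_chrom = {c: g for c, g in repeats.groupby(repeats.columns[0])}
    for i, (_, row) in enumerate(out.iterrows()):
        reg = by_chrom.get(row["chrom"])
        if reg is None:
            continue
        lo = row["pos"] - 1 - margin
        hi = row["pos"] + margin
        starts = reg.iloc[:, 1].to_numpy()
        ends = reg.iloc[:, 2].to_numpy()
        flags[i] = bool(np.any((starts < hi) & (ends > lo)))
    out["near_repeat"] = flags
    return out


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def classify_substitution(ref: str, alt: str) -> str:
    """Collapse a single-base substitution to the pyrimidine-reference class.

    Returns one of C>A, C>G, C>T, T>A, T>C, T>G, or ``not_snv`` for indels
    and multi-base alleles.  Purine-reference substitutions are
    reverse-complemented (G>A -> C>T etc.).
    """
    ref, alt = ref.upper(), alt.upper()
    if not set(ref) <= set("ACGT") or not set(alt) <= set("ACGT"):
        raise ValueError(f"non-nucleotide allele: {ref!r}>{alt!r}")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return "not_snv"
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def summarize_spectrum(retained: pd.DataFrame) -> dict[str, pd.Series]:
    """Proportions of retained variants by effect class and substitution class.

    Substitution proportions are computed over SNVs only.  Each family of
    proportions sums to 1 (empty input yields empty series, not a crash).
    """
    if len(retained) == 0:
        return {
            "effect_class": pd.Series(dtype=float),
            "substitution": pd.Series(dtype=float),
        }
    effect = retained["effect_class"].value_counts(normalize=True).sort_index()
    subs = retained.apply(
        lambda r: classify_substitution(r["ref"], r["alt"]), axis=1
    )
    snv = subs[subs != "not_snv"]
    substitution = (
        snv.value_counts(normalize=True).sort_index()
        if len(snv)
        else pd.Series(dtype=float)
    )
    return {"effect_class": effect, "substitution": substitution}
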