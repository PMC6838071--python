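"""Drug x gene-alteration sensitivity screen.

Every (drug, alteration event) pair splits the panel's IC50s into carrier
("mut") and non-carrier ("wt") groups and is scored with a two-sided
unpaired t-test; Benjamini-Hochberg FDR is applied over the tested family.
Group-size rules: pairs with both groups >= 2 are tested; pairs where one
group has exactly 1 line keep their record but their FDR is forced to 1 and
they do not enter the BH family; pairs with an empty group are untested and
excluded from output ranking.  Candidate selection looks for the largest
multiplicative gap in the sorted FDR sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_FLOOR = 1e-300


def test_association(
    ic50s_mut: np.ndarray,
    ic50s_wt: np.ndarray,
    scale: str = "raw",
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided unpaired t-test of carrier vs non-carrier IC50s.

    ``scale='log10'`` tests log10-transformed values.  Default is the
    pooled-variance Student's t; ``welch=True`` drops the equal-variance
    assumption.  Degenerate zero-variance inputs: equal means -> (0, 1);
    unequal means -> (inf-signed t, p -> 0).
    """
    x = np.asarray(ic50s_mut, float)
    y = np.asarray(ic50s_wt, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 values for a t-test")
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log10 scale requires positive IC50s")
        x, y = np.log10(x), np.log10(y)
    elif scale != "raw":
        raise ValueError(f"unknown scale: {scale}")

    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        t = np.inf if np.mean(x) > np.mean(y) else -np.inf
        return float(t), FDR_FLOOR
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenConfig:
    scale: str = "raw"                # raw | log10
    welch: bool = False
    censored_policy: str = "bound"    # substitute censoring bound, flagged


def screen(
    ic50: pd.DataFrame,
    matrix: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the full drug x event screen.

    Parameters
    ----------
    ic50
        Table with columns line, drug, ic50_uM; optionally censored and
        max_conc_uM/min_conc_uM (censored IC50s are substituted by the
        censoring bound and flagged in ``n_censored_used``).
    matrix
        Binary lines x events DataFrame; event columns are "GENE:kind" with
        kind in {snv_indel, gain, loss}.

    Returns one AssociationRecord row per (drug, event) with a nonempty
    carrier and non-carrier group, sorted by (drug, event).  Untested pairs
    (an empty group) are excluded.
    """
    config = config or ScreenConfig()
    lines_ic50 = set(ic50["line"])
    lines_matrix = set(matrix.index)
    if lines_ic50 != lines_matrix:
        raise ValueError(
            f"line mismatch between IC50 table and cohort matrix: "
            f"{sorted(lines_ic50 ^ lines_matrix)}"
        )

    values = ic50.copy()
    n_censored_used = 0
    if "censored" in values.columns:
        cens = values["censored"].fillna("none") != "none"
        if cens.any():
            if config.censored_policy != "bound":
                raise ValueError(f"unknown censored_policy: {config.censored_policy}")
            bound = np.where(
                values.loc[cens, "censored"] == "above_max",
                values.loc[cens, "max_conc_uM"],
                values.loc[cens, "min_conc_uM"],
            )
            values.loc[cens, "ic50_uM"] = bound
            n_censored_used = int(cens.sum())

    pivot = values.pivot(index="line", columns="drug", values="ic50_uM")
    pivot = pivot.loc[sorted(pivot.index)]

    records = []
    for event in sorted(matrix.columns):
        carrier = matrix[event].astype(bool)
        for drug in sorted(pivot.columns):
            vals = pivot[drug]
            mut = vals[carrier.reindex(vals.index).to_numpy()].dropna()
            wt = vals[~carrier.reindex(vals.index).to_numpy()].dropna()
            n_mut, n_wt = len(mut), len(wt)
            if n_mut == 0 or n_wt == 0:
                continue  # untested: absent from output and the BH family
            mean_mut, mean_wt = float(mut.mean()), float(wt.mean())
            ratio = mean_mut / mean_wt if mean_wt > 0 else np.inf
            rec = {
                "drug": drug,
                "event": event,
                "n_mut": n_mut,
                "n_wt": n_wt,
                "mean_ic50_mut": mean_mut,
                "mean_ic50_wt": mean_wt,
                "effect_ratio": ratio,
                "t": np.nan,
                "p": np.nan,
                "fdr": np.nan,
                "tested": False,
                "direction": "sensitive" if ratio < 1 else "resistant",
            }
            if n_mut >= 2 and n_wt >= 2:
                t, p = test_association(mut.to_numpy(), wt.to_numpy(),
                                        scale=config.scale, welch=config.welch)
                rec.update(t=t, p=p, tested=True)
            else:
                # one singleton group: record kept, FDR forced to 1,
                # excluded from the BH family
                rec["fdr"] = 1.0
            records.append(rec)

    out = pd.DataFrame(records)
    if len(out) == 0:
        return out
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "fdr"] = adjust_bh(out.loc[tested, "p"].to_numpy())
    out.attrs["n_censored_used"] = n_censored_used
    return out.sort_values(["drug", "event"]).reset_index(drop=True)


def rank_and_select(
    records: pd.DataFrame, k_max: int = 10
) -> tuple[pd.DataFrame, int]:
    """Sort tested records by FDR and pick candidates before the largest gap.

    Records are sorted ascending by FDR, ties broken by |log10 effect_ratio|
    descending then by (drug, event).  ``gap_index`` is the position i
    (1-based, i < k_max) maximizing fdr[i+1]/fdr[i]; the first i records are
    the candidates.  All-equal FDRs yield gap_index 0 (no candidates).
    """
    tested = records[records["tested"]].copy()
    if len(tested) < 2:
        raise ValueError("need >= 2 tested records to rank")
    with np.errstate(divide="ignore"):
        tested["_effect_mag"] = np.abs(
            np.log10(np.clip(tested["effect_ratio"], FDR_FLOOR, None))
        )
    ranked = tested.sort_values(
        ["fdr", "_effect_mag", "drug", "event"],
        ascending=[True, False, True, True],
    ).drop(columns="_effect_mag").reset_index(drop=True)

    fdr = np.clip(ranked["fdr"].to_numpy(), FDR_FLOOR, None)
    n = len(fdr)
    if np.allclose(fdr, fdr[0], rtol=0, atol=0):
        warnings.warn("all FDRs equal; no candidates selected")
        return ranked, 0
    limit = min(k_max, n - 1)
    ratios = fdr[1:limit + 1] / fdr[:limit]
    gap_index = int(np.argmax(ratios)) + 1
    return ranked, gap_index


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: effect ratio, -log10 FDR, point size = n_mut."""
    tested = records[records["tested"]]
    return pd.DataFrame(
        {
            "drug": tested["drug"],
            "event": tested["event"],
            "effect_ratio": tested["effect_ratio"],
            "neg_log10_fdr": -np.log10(np.clip(tested["fdr"], FDR_FLOOR, None)),
            "n_mut": tested["n_mut"],
            "direction": tested["direction"],
        }
    ).reset_index(drop=True)
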