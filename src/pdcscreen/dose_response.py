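"""Four-parameter logistic dose-response fitting and IC50 derivation.

The model on concentration c (µM) is

    v(c) = bottom + (top - bottom) / (1 + (c / ec50)**hill)

so with hill > 0 viability falls from ``top`` at low dose to ``bottom`` at
high dose.  The reported IC50 is *absolute*: the concentration at which the
fitted curve crosses 50% of untreated-control viability (0.5 on the
normalized fraction scale), not the curve midpoint.  IC50s whose crossing
falls outside the tested concentration range, or does not exist, are
censored rather than extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class FourPLParams:
    bottom: float
    top: float
    hill: float
    ec50: float
    rss: float = float("nan")
    converged: bool = False

    def canonicalize(self) -> "FourPLParams":
        """Enforce top >= bottom by swapping asymptotes and flipping hill."""
        if self.top < self.bottom:
            return FourPLParams(self.top, self.bottom, -self.hill, self.ec50,
                                self.rss, self.converged)
        return self

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(conc, float), self.bottom, self.top,
                       self.hill, self.ec50)


@dataclass
class IC50Result:
    ic50: float                      # µM; NaN when censored
    censored: str                    # none | above_max | below_min
    rss: float = float("nan")
    converged: bool = False

    @property
    def value_or_bound(self) -> float:
        """IC50, or the censoring bound for off-scale results (set by caller)."""
        return self.ic50


def four_pl(conc: np.ndarray, bottom: float, top: float, hill: float,
            ec50: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)


def dilution_series(top_dose: float, n: int = 10, fold: float = 3.3) -> np.ndarray:
    """Descending n-point dilution series: top, top/fold, top/fold^2, ..."""
    return top_dose / fold ** np.arange(n)


def fit_4pl(conc: np.ndarray, viability: np.ndarray) -> FourPLParams:
    """Least-squares 4PL fit on log-concentration with multi-start.

    Requires >= 4 distinct concentrations.  Non-convergence is reported via
    the ``converged`` flag; best-effort parameters are still returned.
    """
    conc = np.asarray(conc, float)
    viability = np.asarray(viability, float)
    if conc.shape != viability.shape:
        raise ValueError("conc and viability must have the same shape")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct concentrations to fit a 4PL")

    logc = np.log(conc)
    vmin, vmax = float(viability.min()), float(viability.max())
    spread = max(vmax - vmin, 1e-6)

    def residuals(p: np.ndarray) -> np.ndarray:
        bottom, top, hill, log_ec50 = p
        with np.errstate(over="ignore"):
            pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - log_ec50)))
        return pred - viability

    def jacobian(p: np.ndarray) -> np.ndarray:
        bottom, top, hill, log_ec50 = p
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(hill * (logc - log_ec50)))
        ds = s * (1.0 - s)
        return np.column_stack(
            [1.0 - s, s, -(top - bottom) * ds * (logc - log_ec50),
             (top - bottom) * ds * hill]
        )

    # midpoint guess: concentration where viability is closest to the middle
    mid = (vmin + vmax) / 2
    c_mid = float(logc[np.argmin(np.abs(viability - mid))])
    starts = [
        (vmin, vmax, h, c0)
        for h in (1.0, 0.5, 2.0, -1.0)
        for c0 in (c_mid, float(np.median(logc)))
    ]
    # extra starts matter only when the primary start lands in a poor local
    # optimum; a fit whose RMS residual is under 10% of the data spread is
    # accepted immediately
    good_enough = 0.5 * (0.10 * spread) ** 2 * len(viability)
    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, jac=jacobian, method="lm",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.success and best.cost <= good_enough:
            break
    if best is None:
        return FourPLParams(vmin, vmax, 1.0, float(np.exp(c_mid)),
                            rss=float("inf"), converged=False)

    bottom, top, hill, log_ec50 = best.x
    rss = float(2 * best.cost)
    # degenerate: essentially flat data cannot identify hill/ec50
    flat = spread < 1e-6 or abs(top - bottom) < 1e-9
    params = FourPLParams(float(bottom), float(top), float(hill),
                          float(np.exp(log_ec50)), rss=rss,
                          converged=bool(best.success and not flat))
    return params.canonicalize()


def derive_ic50(params: FourPLParams, conc_range: tuple[float, float],
                control: float = 1.0) -> IC50Result:
    """Absolute IC50: where the fitted curve crosses ``0.5 * control``.

    ``conc_range`` is (min, max) tested concentration.  When the crossing
    lies above the tested range (or the curve never falls to the level) the
    result is censored ``above_max``; below the range, ``below_min``.
    """
    p = params.canonicalize()
    level = 0.5 * control
    lo, hi = conc_range
    if lo > hi:
        raise ValueError("conc_range must be (min, max)")

    # crossing exists only if level lies strictly between the asymptotes
    if not (p.bottom < level < p.top) or p.hill == 0:
        # curve never reaches the level within (bottom, top)
        v_hi = float(p.predict(np.array([hi]))[0])
        censored = "above_max" if v_hi > level else "below_min"
        return IC50Result(float("nan"), censored, p.rss, p.converged)

    # level = bottom + (top-bottom)/(1+(c/ec50)^hill)
    x = (p.top - level) / (level - p.bottom)
    ic50 = p.ec50 * x ** (1.0 / p.hill)
    if ic50 > hi:
        return IC50Result(float("nan"), "above_max", p.rss, p.converged)
    if ic50 < lo:
        return IC50Result(float("nan"), "below_min", p.rss, p.converged)
    return IC50Result(float(ic50), "none", p.rss, p.converged)


@dataclass
class AggregatedIC50:
    mean: float              # NaN when all replicated experiments censored
    sd: float
    n_uncensored: int
    n_censored: int
    censored: str            # none, or the modal censoring direction


def aggregate_ic50(results: list[IC50Result]) -> AggregatedIC50:
    """Mean and sample SD of uncensored IC50s across independent experiments.

    Censored results are excluded from the mean and surfaced as a count;
    when every experiment is censored the aggregate is censored with no
    numeric mean.
    """
    vals = [r.ic50 for r in results if r.censored == "none"]
    cens = [r.censored for r in results if r.censored != "none"]
    if not vals:
        modal = max(set(cens), key=cens.count) if cens else "none"
        return AggregatedIC50(float("nan"), float("nan"), 0, len(cens), modal)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return AggregatedIC50(mean, sd, len(vals), len(cens), "none")


def fit_viability_table(viability: pd.DataFrame, mode: str = "per_experiment",
                        control: float = 1.0) -> pd.DataFrame:
    """Fit every (line, drug) curve in a viability table and derive IC50s.

    ``viability`` columns: line, drug, concentration_uM, replicate,
    viability.  ``mode='per_experiment'`` fits each replicate separately and
    averages uncensored IC50s (the default); ``mode='pooled'`` fits one
    curve on all replicate points.

    Returns a table with line, drug, ic50_uM, ic50_sd, n_uncensored,
    n_censored, censored, converged.  For fully censored (line, drug) pairs
    ``ic50_uM`` is NaN and ``censored`` names the off-scale direction.
    """
    if mode not in ("per_experiment", "pooled"):
        raise ValueError(f"unknown mode: {mode}")
    rows = []
    for (line, drug), grp in viability.groupby(["line", "drug"], sort=True):
        conc_range = (float(grp["concentration_uM"].min()),
                      float(grp["concentration_uM"].max()))
        if mode == "per_experiment":
            results = []
            for _, rep in grp.groupby("replicate"):
                params = fit_4pl(rep["concentration_uM"].to_numpy(),
                                 rep["viability"].to_numpy())
                results.append(derive_ic50(params, conc_range, control))
        else:
            params = fit_4pl(grp["concentration_uM"].to_numpy(),
                             grp["viability"].to_numpy())
            results = [derive_ic50(params, conc_range, control)]
        agg = aggregate_ic50(results)
        rows.append(
            {
                "line": line,
                "drug": drug,
                "ic50_uM": agg.mean,
                "ic50_sd": agg.sd,
                "n_uncensored": agg.n_uncensored,
                "n_censored": agg.n_censored,
                "censored": agg.censored,
                "min_conc_uM": conc_range[0],
                "max_conc_uM": conc_range[1],
                "converged": all(r.converged for r in results),
            }
        )
    return pd.DataFrame(rows)
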