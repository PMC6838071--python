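"""Synthetic cohort, coverage, viability and survival generators.

Every downstream stage of the pipeline can be exercised on data produced
here, with known ground truth attached: variant candidates carry labels
saying which filter criterion (if any) they were built to violate, coverage
tables carry planted copy-number segments, viability tables carry the true
per-(line, drug) IC50, and survival tables carry their group hazards.

All generators take explicit seeds and are deterministic: the same spec and
seed reproduce byte-identical tables.  There is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dose_response import dilution_series, four_pl
from .variant_filter import EFFECT_CLASSES

# ---------------------------------------------------------------------------
# cohort of tumor/normal samples

#: default per-gene alteration frequencies for a simulated ESCC-like cohort.
#: CNV frequencies follow the recurrently altered genes of such cohorts
#: (CCND1/MCL1/FGF cluster gains; MST1R/CDKN2A/CDKN2B losses); mutation
#: frequencies are realistic for ESCC driver genes.
DEFAULT_GENE_FREQS: dict[str, tuple[str, float]] = {
    "CCND1": ("gain", 0.42),
    "MCL1": ("gain", 0.38),
    "FGF4": ("gain", 0.35),
    "FGF3": ("gain", 0.35),
    "SOX2": ("gain", 0.34),
    "FGF19": ("gain", 0.34),
    "CDKN1B": ("gain", 0.30),
    "MST1R": ("loss", 0.30),
    "CDKN2A": ("loss", 0.26),
    "CDKN2B": ("loss", 0.13),
    "TP53": ("snv_indel", 0.83),
    "KMT2D": ("snv_indel", 0.24),
    "NOTCH1": ("snv_indel", 0.20),
    "PIK3CA": ("snv_indel", 0.12),
}

#: effect-class frequencies of retained somatic mutations (missense-dominant
#: spectrum typical of squamous tumors); sums to 1
DEFAULT_EFFECT_FREQS: dict[str, float] = {
    "missense": 0.57,
    "synonymous": 0.30,
    "stopgain": 0.07,
    "splice": 0.03,
    "frameshift_del": 0.010,
    "frameshift_ins": 0.005,
    "nonframeshift_del": 0.007,
    "nonframeshift_ins": 0.005,
    "stoploss": 0.003,
}

#: substitution-class frequencies with the C>T transition modal
DEFAULT_SUBSTITUTION_FREQS: dict[str, float] = {
    "C>T": 0.40,
    "C>A": 0.15,
    "T>C": 0.15,
    "C>G": 0.10,
    "T>A": 0.10,
    "T>G": 0.10,
}

_SUB_ALLELES = {
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
    "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G"),
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of tumor samples with per-gene alteration probabilities."""

    n_samples: int = 161
    gene_alteration_freqs: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQS)
    )
    mean_variants_per_sample: float = 13.0
    mean_tumor_depth: float = 394.0
    mean_normal_depth: float = 431.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for gene, (kind, p) in self.gene_alteration_freqs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{gene}: probability {p} outside [0, 1]")
            if kind not in ("snv_indel", "gain", "loss"):
                raise ValueError(f"{gene}: unknown alteration kind {kind!r}")


def generate_cohort_matrix(spec: CohortSpec) -> pd.DataFrame:
    """Binary samples x events matrix; events are ``GENE:kind`` columns.

    Each event is an independent Bernoulli draw at its specified frequency.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    events = {
        f"{gene}:{kind}": rng.random(spec.n_samples) < p
        for gene, (kind, p) in sorted(spec.gene_alteration_freqs.items())
    }
    return pd.DataFrame(events, index=samples, dtype=int)


_ARTIFACT_CRITERIA = (
    "min_tumor_depth",
    "max_normal_vaf",
    "min_vaf_diff",
    "max_strand_bias",
    "min_alt_reads",
    "max_population_freq",
    "effect_class",
    "near_repeat",
)


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    classes = list(DEFAULT_SUBSTITUTION_FREQS)
    probs = np.array(list(DEFAULT_SUBSTITUTION_FREQS.values()))
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    ref, alt = _SUB_ALLELES[cls]
    if rng.random() < 0.5:  # report on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _true_variant(rng: np.random.Generator, spec: CohortSpec) -> dict:
    """One candidate guaranteed to clear every filter criterion."""
    depth = max(30, int(rng.poisson(spec.mean_tumor_depth)))
    vaf = rng.uniform(0.10, 0.60)
    # floor keeps alt-read count and VAF-difference criteria satisfiable
    floor = max(5, int(np.ceil(0.055 * depth)))
    alt_reads = min(max(floor, int(rng.binomial(depth, vaf))), depth)
    vaf = alt_reads / depth
    classes = [c for c in DEFAULT_EFFECT_FREQS]
    probs = np.array([DEFAULT_EFFECT_FREQS[c] for c in classes])
    effect = classes[rng.choice(len(classes), p=probs / probs.sum())]
    ref, alt = _draw_alleles(rng)
    return {
        "ref": ref,
        "alt": alt,
        "tumor_depth": depth,
        "tumor_alt_reads": alt_reads,
        "tumor_vaf": vaf,
        "normal_vaf": float(rng.uniform(0.0, min(0.03, vaf - 0.05))),
        "strand_bias": float(rng.uniform(0.5, 0.9)),
        "population_freq": float(rng.uniform(0.0, 0.015)) if rng.random() < 0.3 else 0.0,
        "effect_class": effect,
        "near_repeat": False,
    }


def _make_artifact(rng: np.random.Generator, spec: CohortSpec, criterion: str) -> dict:
    """A candidate violating exactly ``criterion`` and nothing else."""
    v = _true_variant(rng, spec)
    if criterion == "min_tumor_depth":
        depth = int(rng.integers(10, 30))
        vaf = rng.uniform(0.3, 0.6)
        alt = max(5, int(round(depth * vaf)))
        v.update(tumor_depth=depth, tumor_alt_reads=min(alt, depth))
        v["tumor_vaf"] = v["tumor_alt_reads"] / depth
        v["normal_vaf"] = 0.0
    elif criterion == "max_normal_vaf":
        v["normal_vaf"] = float(rng.uniform(0.031, 0.30))
        target = max(v["tumor_vaf"], v["normal_vaf"] + 0.05)
        # ceil keeps the VAF difference >= 0.05 after integer rounding
        v["tumor_alt_reads"] = min(int(np.ceil(target * v["tumor_depth"])),
                                   v["tumor_depth"])
        v["tumor_vaf"] = v["tumor_alt_reads"] / v["tumor_depth"]
    elif criterion == "min_vaf_diff":
        depth = max(300, v["tumor_depth"])
        vaf = rng.uniform(0.035, 0.045)
        alt = int(round(depth * vaf))
        v.update(tumor_depth=depth, tumor_alt_reads=alt,
                 tumor_vaf=alt / depth, normal_vaf=0.0)
    elif criterion == "max_strand_bias":
        v["strand_bias"] = float(rng.uniform(0.901, 1.0))
    elif criterion == "min_alt_reads":
        alt = int(rng.integers(2, 5))
        # cap depth so the VAF difference criterion stays satisfied
        depth = int(rng.integers(30, min(20 * alt, 80) + 1))
        v.update(tumor_depth=depth, tumor_alt_reads=alt,
                 tumor_vaf=alt / depth, normal_vaf=0.0)
    elif criterion == "max_population_freq":
        v["population_freq"] = float(rng.uniform(0.0151, 0.5))
    elif criterion == "effect_class":
        v["effect_class"] = "other"
    elif criterion == "near_repeat":
        v["near_repeat"] = True
    else:
        raise ValueError(f"unknown criterion: {criterion}")
    return v


def generate_variant_candidates(
    spec: CohortSpec, artifact_rate: float = 0.0
) -> pd.DataFrame:
    """Caller-like variant candidates with truth labels.

    True somatic variants satisfy every filter criterion by construction;
    at ``artifact_rate`` (fraction of all emitted candidates) artifacts are
    added, each violating exactly one criterion named in its
    ``violated_criterion`` column (empty for true variants).
    """
    if not 0 <= artifact_rate <= 1:
        raise ValueError(f"artifact_rate {artifact_rate} outside [0, 1]")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_samples):
        sample = f"S{i + 1:03d}"
        n_var = int(rng.poisson(spec.mean_variants_per_sample))
        for _ in range(n_var):
            is_artifact = rng.random() < artifact_rate
            if is_artifact:
                criterion = _ARTIFACT_CRITERIA[
                    int(rng.integers(len(_ARTIFACT_CRITERIA)))
                ]
                v = _make_artifact(rng, spec, criterion)
            else:
                criterion = ""
                v = _true_variant(rng, spec)
            rows.append(
                {
                    "sample": sample,
                    "chrom": f"chr{int(rng.integers(1, 23))}",
                    "pos": int(rng.integers(1, 250_000_000)),
                    **v,
                    "is_artifact": is_artifact,
                    "violated_criterion": criterion,
                }
            )
    cols = ["sample", "chrom", "pos", "ref", "alt", "tumor_depth",
            "tumor_alt_reads", "tumor_vaf", "normal_vaf", "strand_bias",
            "population_freq", "effect_class", "near_repeat", "is_artifact",
            "violated_criterion"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# binned tumor/normal coverage with planted copy-number segments


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Unimodal coverage bias peaking at 45% GC (capped at 20% loss)."""
    return np.clip(1.0 - 2.0 * (np.asarray(gc) - 0.45) ** 2, 0.8, None)


@dataclass(frozen=True)
class CoverageSimSpec:
    """Binned coverage simulation with planted log2-ratio segments."""

    n_bins: int = 2000
    bin_width: int = 1000
    planted_segments: tuple[tuple[int, int, float], ...] = ()
    depth_mean: float = 100.0
    gc_profile: tuple[float, ...] | None = None  # default: drawn Beta(5, 5)
    gc_bias_curve: Callable[[np.ndarray], np.ndarray] = default_gc_bias
    noise: str = "poisson"  # poisson | none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model: {self.noise}")
        segs = sorted(self.planted_segments)
        for (s, e, _lr) in segs:
            if not (0 <= s < e <= self.n_bins):
                raise ValueError(f"segment ({s}, {e}) outside [0, {self.n_bins})")
        for (_, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError("planted segments overlap")


def generate_coverage(spec: CoverageSimSpec) -> pd.DataFrame:
    """Paired tumor/normal bin counts on one simulated chromosome.

    Normal counts are Poisson around ``depth_mean x gc_bias``; tumor counts
    additionally scale by ``2**log2_ratio`` inside planted segments.  The
    same GC bias multiplies both members of a pair.  ``noise='none'`` emits
    the expected counts directly (real-valued).

    Output columns: chrom, start, end, gc, normal_count, tumor_count,
    true_log2_ratio (the planted truth).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.gc_profile is not None:
        gc = np.asarray(spec.gc_profile, float)
        if len(gc) != spec.n_bins:
            raise ValueError("gc_profile length must equal n_bins")
    else:
        gc = rng.beta(5, 5, size=spec.n_bins)

    true_lr = np.zeros(spec.n_bins)
    for s, e, lr in spec.planted_segments:
        true_lr[s:e] = lr

    bias = spec.gc_bias_curve(gc)
    mu_normal = spec.depth_mean * bias
    mu_tumor = mu_normal * 2.0 ** true_lr
    if spec.noise == "poisson":
        normal = rng.poisson(mu_normal).astype(float)
        tumor = rng.poisson(mu_tumor).astype(float)
    else:
        normal, tumor = mu_normal, mu_tumor

    starts = np.arange(spec.n_bins) * spec.bin_width
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": starts + spec.bin_width,
            "gc": gc,
            "normal_count": normal,
            "tumor_count": tumor,
            "true_log2_ratio": true_lr,
        }
    )


def exon_table(genes: dict[str, Sequence[tuple[int, int]]],
               chrom: str = "chrS") -> pd.DataFrame:
    """Exon model table (gene, chrom, start, end) from a dict of intervals."""
    rows = [
        {"gene": g, "chrom": chrom, "start": s, "end": e}
        for g, exons in sorted(genes.items())
        for s, e in sorted(exons)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drug panel viability


@dataclass(frozen=True)
class PanelSpec:
    """A drug screening panel over patient-derived lines.

    ``planted_effects`` lists (drug, event, ic50 fold change) triples: a
    carrier of ``event`` has its true IC50 for ``drug`` multiplied by the
    fold change (< 1 = sensitizing).  ``event_carrier_counts`` fixes how
    many lines carry each event (the headline 5-of-8 split by default).
    """

    n_lines: int = 8
    drugs: tuple[str, ...] = tuple(
        ["palbociclib", "ribociclib", "azathioprine", "MM-102"]
        + [f"drug{i:02d}" for i in range(5, 47)]
    )
    planted_effects: tuple[tuple[str, str, float], ...] = (
        ("palbociclib", "CDKN2AB:loss", 0.05),
        ("ribociclib", "CDKN2AB:loss", 0.05),
        ("azathioprine", "RAC1:gain", 8.0),
        ("MM-102", "KMT2D:snv_indel", 0.1),
    )
    event_carrier_counts: dict[str, int] = field(
        default_factory=lambda: {
            "CDKN2AB:loss": 5,
            "TP53:snv_indel": 7,
            "CCND1:gain": 4,
            "KMT2D:snv_indel": 3,
            "NOTCH1:snv_indel": 2,
            "PIK3CA:snv_indel": 2,
            "RAC1:gain": 2,
            "MCL1:gain": 3,
            "SOX2:gain": 3,
            "MST1R:loss": 2,
            "FGF19:gain": 3,
            "EP300:snv_indel": 1,
        }
    )
    base_ic50: float = 5.0          # µM, per drug before planted effects
    line_spread_sd: float = 0.0     # optional per-(line,drug) log10 IC50 scatter
    cv_noise: float = 0.05          # relative SD of viability readings
    hill: float = 1.0
    top_dose: float = 10.0          # µM, top of the dilution series
    n_concentrations: int = 10
    dilution_fold: float = 3.3
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        for drug, event, fold in self.planted_effects:
            if fold <= 0:
                raise ValueError(f"fold change must be > 0 ({drug}, {event})")
            if drug not in self.drugs:
                raise ValueError(f"planted effect on unknown drug {drug!r}")
            if event not in self.event_carrier_counts:
                raise ValueError(f"planted effect on unknown event {event!r}")
        for event, k in self.event_carrier_counts.items():
            if not 0 <= k <= self.n_lines:
                raise ValueError(f"{event}: carrier count {k} outside panel")

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(f"PDC{i + 1:02d}" for i in range(self.n_lines))


def generate_panel_alterations(panel: PanelSpec, seed: int = 0) -> pd.DataFrame:
    """Binary lines x events matrix with the spec's per-event carrier counts.

    Carrier sets are drawn without replacement per event, deterministically
    from the seed.
    """
    rng = np.random.default_rng(seed)
    lines = list(panel.lines)
    data = {}
    for event, k in sorted(panel.event_carrier_counts.items()):
        carriers = rng.choice(panel.n_lines, size=k, replace=False)
        col = np.zeros(panel.n_lines, dtype=int)
        col[carriers] = 1
        data[event] = col
    return pd.DataFrame(data, index=lines)


def true_ic50_table(panel: PanelSpec, alterations: pd.DataFrame,
                    seed: int = 0) -> pd.DataFrame:
    """Ground-truth per-(line, drug) IC50s implied by the planted effects.

    A line's IC50 for a drug is ``base_ic50`` times the fold change of every
    planted effect whose event it carries, times a line-specific log-normal
    scatter (``line_spread_sd`` in log10 units).
    """
    rng = np.random.default_rng(seed)
    effects: dict[str, list[tuple[str, float]]] = {}
    for drug, event, fold in panel.planted_effects:
        effects.setdefault(drug, []).append((event, fold))
    rows = []
    for line in panel.lines:
        for drug in panel.drugs:
            ic50 = panel.base_ic50
            for event, fold in effects.get(drug, []):
                if alterations.loc[line, event]:
                    ic50 *= fold
            scatter = 10.0 ** rng.normal(0.0, panel.line_spread_sd)
            rows.append({"line": line, "drug": drug, "true_ic50_uM": ic50 * scatter})
    return pd.DataFrame(rows)


def generate_viability(panel: PanelSpec, alterations: pd.DataFrame,
                       seed: int = 0) -> pd.DataFrame:
    """Per-well viability measurements for the whole panel.

    Ten-point (by default) exact ``dilution_fold`` series from ``top_dose``;
    viability follows a 4PL (bottom 0, top 1, the panel's hill slope) around
    the line's true IC50, with multiplicative log-normal noise of relative
    SD ``cv_noise``, in ``n_replicates`` replicate wells per concentration.

    Output columns: line, drug, concentration_uM, replicate, viability; the
    truth table is attached as ``result.attrs['true_ic50']``.
    """
    rng = np.random.default_rng(seed)
    truth = true_ic50_table(panel, alterations, seed=seed)
    conc = dilution_series(panel.top_dose, panel.n_concentrations,
                           panel.dilution_fold)
    sigma = np.sqrt(np.log1p(panel.cv_noise**2))  # log-normal with given CV
    rows = []
    for _, t in truth.iterrows():
        clean = four_pl(conc, 0.0, 1.0, panel.hill, t["true_ic50_uM"])
        for rep in range(1, panel.n_replicates + 1):
            if panel.cv_noise > 0:
                noise = rng.lognormal(-sigma**2 / 2, sigma, size=len(conc))
            else:
                noise = np.ones(len(conc))
            vals = clean * noise
            for c, v in zip(conc, vals):
                rows.append(
                    {
                        "line": t["line"],
                        "drug": t["drug"],
                        "concentration_uM": float(c),
                        "replicate": rep,
                        "viability": float(v),
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["true_ic50"] = truth
    return out


# ---------------------------------------------------------------------------
# survival


def generate_survival(
    n_per_group: dict[str, int],
    hazards: dict[str, float],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival per group with independent uniform censoring.

    Each subject's event time is Exponential(hazard of its group); with
    probability ``censor_rate`` the record is censored at a uniform time
    before the event.  Output columns: sample, group, time, event.
    """
    if set(n_per_group) != set(hazards):
        raise ValueError("n_per_group and hazards must list the same groups")
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazards must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group in sorted(n_per_group):
        n = n_per_group[group]
        times = rng.exponential(1.0 / hazards[group], size=n)
        censored = rng.random(n) < censor_rate
        obs = np.where(censored, rng.uniform(0, times), times)
        for t, c in zip(obs, censored):
            i += 1
            rows.append(
                {"sample": f"P{i:04d}", "group": group,
                 "time": float(t), "event": int(not c)}
            )
    return pd.DataFrame(rows)
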