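"""End-to-end orchestration: simulate inputs, run every stage, write artifacts.

``simulate_inputs`` writes the full set of pipeline inputs for one seed;
``run_pipeline`` executes filter -> cnv -> ic50 -> screen -> stats over a
manifest of input paths, logging record counts per stage, and writes all
stage outputs plus a JSON run report.  Reruns with the same config and
inputs are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cnv, cohort_stats, synthetic
from .association import rank_and_select, screen, volcano_table
from .config import PipelineConfig
from .dose_response import fit_viability_table
from .io import read_table, write_table
from .variant_filter import apply_filters, summarize_spectrum

log = logging.getLogger("pdcscreen")

MANIFEST_KEYS = ("variants", "coverage", "exons", "viability", "panel_events",
                 "clinical")


def simulate_inputs(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    seed = config.seed
    h = config.hash()

    cohort = synthetic.CohortSpec(n_samples=sim.n_samples, seed=seed)
    variants = synthetic.generate_variant_candidates(cohort, sim.artifact_rate)

    cov_spec = synthetic.CoverageSimSpec(
        n_bins=sim.n_coverage_bins,
        depth_mean=sim.coverage_depth,
        planted_segments=((200, 320, 1.0), (900, 1050, -1.2)),
        seed=seed,
    )
    coverage = synthetic.generate_coverage(cov_spec)
    # gene models: one gene inside each planted segment, one in background
    bw = cov_spec.bin_width
    exons = synthetic.exon_table(
        {
            "GENE_GAIN": [(210 * bw, 212 * bw), (240 * bw, 242 * bw),
                          (300 * bw, 302 * bw)],
            "GENE_LOSS": [(910 * bw, 912 * bw), (1000 * bw, 1002 * bw)],
            "GENE_NEUTRAL": [(1500 * bw, 1502 * bw), (1600 * bw, 1602 * bw)],
        }
    )

    panel = synthetic.PanelSpec(n_lines=sim.n_lines, cv_noise=sim.cv_noise)
    alterations = synthetic.generate_panel_alterations(panel, seed=seed)
    viability = synthetic.generate_viability(panel, alterations, seed=seed)

    clinical = synthetic.generate_survival(
        {"altered": sim.survival_n_per_group, "wild_type": sim.survival_n_per_group},
        {"altered": 1.0 / 12 * sim.survival_hazard_ratio, "wild_type": 1.0 / 12},
        censor_rate=sim.survival_censor_rate,
        seed=seed,
    )

    manifest = {
        "variants": write_table(variants, outdir / "variants.tsv", h),
        "coverage": write_table(coverage, outdir / "coverage.tsv", h),
        "exons": write_table(exons, outdir / "exons.tsv", h),
        "viability": write_table(viability, outdir / "viability.csv", h, sep=","),
        "panel_events": write_table(
            alterations.reset_index(names="line"), outdir / "panel_events.tsv", h
        ),
        "clinical": write_table(clinical, outdir / "clinical.tsv", h),
    }
    truth = viability.attrs["true_ic50"]
    write_table(truth, outdir / "true_ic50.tsv", h)
    return manifest


def run_pipeline(config: PipelineConfig, manifest: dict[str, Path],
                 outdir: str | Path) -> dict:
    """Run all stages over the manifest; returns the run report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [k for k in MANIFEST_KEYS if k not in manifest or not Path(manifest[k]).exists()]
    if missing:
        raise FileNotFoundError(f"manifest missing inputs for stages: {missing}")
    h = config.hash()
    report: dict = {"version": __version__, "config_hash": h, "stages": {}}

    # --- stage 1: somatic filter -------------------------------------------
    candidates = read_table(manifest["variants"])
    retained, decisions = apply_filters(candidates, config.filter)
    spectrum = summarize_spectrum(retained)
    write_table(retained, outdir / "variants.retained.tsv", h)
    write_table(decisions.reset_index(drop=True), outdir / "variants.decisions.tsv", h)
    fail_counts = {
        c: int(decisions[c].sum()) for c in decisions.columns
        if c not in ("pass", "failed_criteria")
    }
    report["stages"]["filter"] = {
        "n_in": len(candidates),
        "n_retained": len(retained),
        "failures_per_criterion": fail_counts,
        "effect_spectrum": {k: round(v, 6) for k, v in
                            spectrum["effect_class"].items()},
        "substitution_spectrum": {k: round(v, 6) for k, v in
                                  spectrum["substitution"].items()},
    }
    log.info("filter: %d -> %d", len(candidates), len(retained))

    # --- stage 2: CNV ------------------------------------------------------
    bins = read_table(manifest["coverage"])
    normed = cnv.normalize_coverage(bins, n_gc_strata=config.cnv.n_gc_strata)
    segments = cnv.segment_log_ratios(normed, penalty=config.cnv.penalty)
    segments = cnv.call_segments(segments, config.cnv.gain_threshold,
                                 config.cnv.loss_threshold)
    exons = read_table(manifest["exons"])
    gene_calls = cnv.call_gene_cnv(exons, segments, config.cnv.gene_exon_fraction)
    write_table(cnv.segments_to_frame(segments), outdir / "segments.seg", h)
    gene_df = pd.DataFrame(
        [{"gene": g.gene, "status": g.status,
          "fraction_exons_overlapping": g.fraction_exons_overlapping}
         for g in gene_calls]
    )
    write_table(gene_df, outdir / "gene_cnv.tsv", h)
    report["stages"]["cnv"] = {
        "n_bins": len(bins),
        "n_segments": len(segments),
        "calls": {c: sum(1 for s in segments if s.call == c)
                  for c in ("gain", "loss", "neutral")},
        "gene_calls": {g.gene: g.status for g in gene_calls},
    }

    # --- stage 3: IC50 -----------------------------------------------------
    viability = read_table(manifest["viability"], sep=",")
    ic50 = fit_viability_table(viability, mode=config.dose_response.mode,
                               control=config.dose_response.control)
    write_table(ic50, outdir / "ic50.tsv", h)
    uncensored = ic50["ic50_uM"].dropna()
    report["stages"]["ic50"] = {
        "n_curves": len(ic50),
        "n_censored": int((ic50["censored"] != "none").sum()),
        "ic50_range_uM": [float(uncensored.min()), float(uncensored.max())]
        if len(uncensored) else None,
    }

    # --- stage 4: association screen ---------------------------------------
    events = read_table(manifest["panel_events"]).set_index("line")
    records = screen(ic50, events, config.screen)
    write_table(records, outdir / "associations.tsv", h)
    ranked, gap = rank_and_select(records)
    write_table(ranked, outdir / "associations.ranked.tsv", h)
    write_table(volcano_table(records), outdir / "volcano.tsv", h)
    candidates_out = ranked.head(gap)[["drug", "event", "fdr", "effect_ratio",
                                       "direction"]]
    report["stages"]["screen"] = {
        "n_pairs": len(records),
        "n_tested": int(records["tested"].sum()),
        "gap_index": gap,
        "candidates": candidates_out.to_dict(orient="records"),
    }

    # --- stage 5: cohort stats ---------------------------------------------
    rec = cohort_stats.recurrence(events)
    write_table(rec, outdir / "recurrence.tsv", h)
    clinical = read_table(manifest["clinical"])
    km = cohort_stats.km_estimate(clinical)
    km_rows = []
    for group, tab in km.items():
        t = tab.copy()
        t.insert(0, "group", group)
        km_rows.append(t)
    write_table(pd.concat(km_rows, ignore_index=True), outdir / "km.tsv", h)
    chi2, p = cohort_stats.logrank_test(clinical)
    report["stages"]["stats"] = {
        "n_events_table": len(rec),
        "logrank_chi2": float(chi2),
        "logrank_p": float(p),
        "logrank_significant": bool(p < 0.05),
    }

    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
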