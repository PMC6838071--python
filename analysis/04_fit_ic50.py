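#!/usr/bin/env python
"""Fit 4PL dose-response curves and derive absolute IC50s for the panel.

Each (line, drug) curve has 10 concentrations in a 3.3-fold dilution from
10 uM, in quadruplicate; replicates are fit separately and uncensored IC50s
averaged.  IC50 is where the fitted curve crosses 50% of untreated-control
viability; crossings outside the tested range are censored.
"""

from pdcscreen.config import PipelineConfig
from pdcscreen.dose_response import fit_viability_table
from pdcscreen.io import read_table, write_table

if __name__ == "__main__":
    cfg = PipelineConfig.from_yaml("results/config.yaml")
    viability = read_table("results/inputs/viability.csv", sep=",")
    ic50 = fit_viability_table(viability, mode=cfg.dose_response.mode,
                               control=cfg.dose_response.control)
    write_table(ic50, "results/ic50.tsv", cfg.hash())

    ok = ic50["ic50_uM"].dropna()
    print(f"fitted {len(ic50)} (line, drug) curves; "
          f"IC50 range {ok.min():.3f}-{ok.max():.3f} uM; "
          f"{int((ic50['censored'] != 'none').sum())} censored off-scale")
    truth = read_table("results/inputs/true_ic50.tsv")
    merged = ic50.merge(truth, on=["line", "drug"]).dropna(subset=["ic50_uM"])
    rel = ((merged["ic50_uM"] - merged["true_ic50_uM"]).abs()
           / merged["true_ic50_uM"])
    print(f"median relative error vs planted truth: {rel.median():.1%}")
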