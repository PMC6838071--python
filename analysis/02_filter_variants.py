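#!/usr/bin/env python
"""Apply the somatic filter chain and summarize the retained spectrum.

Retains candidates clearing all criteria (tumor depth >= 30, normal VAF
<= 0.03, VAF difference >= 0.05, strand bias <= 0.9, >= 5 alt reads,
population frequency <= 0.015, retained effect class, not near a repeat)
and reports per-criterion attrition plus effect-class and substitution
spectra.
"""

from pdcscreen.config import PipelineConfig
from pdcscreen.io import read_table, write_table
from pdcscreen.variant_filter import apply_filters, summarize_spectrum

if __name__ == "__main__":
    cfg = PipelineConfig.from_yaml("results/config.yaml")
    candidates = read_table("results/inputs/variants.tsv")
    retained, decisions = apply_filters(candidates, cfg.filter)
    write_table(retained, "results/variants.retained.tsv", cfg.hash())
    write_table(decisions.reset_index(drop=True),
                "results/variants.decisions.tsv", cfg.hash())

    print(f"retained {len(retained)}/{len(candidates)} candidates")
    spectrum = summarize_spectrum(retained)
    print("\neffect-class spectrum of retained variants:")
    for cls, frac in spectrum["effect_class"].sort_values(ascending=False).items():
        print(f"  {cls:>18}: {frac:6.1%}")
    print("\nsubstitution spectrum (SNVs, pyrimidine convention):")
    for cls, frac in spectrum["substitution"].sort_values(ascending=False).items():
        print(f"  {cls}: {frac:6.1%}")
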