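#!/usr/bin/env python
"""Tumor/normal read-depth CNV calling on the simulated coverage.

Normalizes tumor to matched normal with median centering and GC-decile
correction, segments the log2 ratios by BIC-penalized bottom-up merging,
calls segments at |log2| > 0.7, and derives gene-level calls for genes with
> 75% of exons overlapping called segments.
"""

import pandas as pd

from pdcscreen import cnv
from pdcscreen.config import PipelineConfig
from pdcscreen.io import read_table, write_table

if __name__ == "__main__":
    cfg = PipelineConfig.from_yaml("results/config.yaml")
    bins = read_table("results/inputs/coverage.tsv")
    normed = cnv.normalize_coverage(bins, n_gc_strata=cfg.cnv.n_gc_strata)
    segments = cnv.call_segments(
        cnv.segment_log_ratios(normed, penalty=cfg.cnv.penalty),
        cfg.cnv.gain_threshold, cfg.cnv.loss_threshold,
    )
    genes = read_table("results/inputs/exons.tsv")
    calls = cnv.call_gene_cnv(genes, segments, cfg.cnv.gene_exon_fraction)

    write_table(cnv.segments_to_frame(segments), "results/segments.seg", cfg.hash())
    write_table(pd.DataFrame([vars(c) for c in calls]),
                "results/gene_cnv.tsv", cfg.hash())

    called = [s for s in segments if s.call != "neutral"]
    print(f"{len(segments)} segments, {len(called)} called:")
    for s in called:
        print(f"  {s.chrom}:{s.start}-{s.end} ({s.n_bins} bins) "
              f"log2={s.log_ratio:+.2f} {s.call}")
    print("\ngene-level calls:")
    for c in calls:
        print(f"  {c.gene:>13}: {c.status:>7} "
              f"(exon overlap {c.fraction_exons_overlapping:.0%})")
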