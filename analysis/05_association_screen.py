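#!/usr/bin/env python
"""Drug x gene-alteration association screen with FDR-gap candidate selection.

Pairs with >= 2 lines in both carrier and non-carrier groups get a pooled
two-sided t-test and enter the BH family; singleton-group pairs keep their
record with FDR forced to 1.  Records are ranked by FDR and candidates are
those before the largest multiplicative FDR gap.
"""

from pdcscreen.association import rank_and_select, screen, volcano_table
from pdcscreen.config import PipelineConfig
from pdcscreen.io import read_table, write_table

if __name__ == "__main__":
    cfg = PipelineConfig.from_yaml("results/config.yaml")
    ic50 = read_table("results/ic50.tsv")
    events = read_table("results/inputs/panel_events.tsv").set_index("line")
    records = screen(ic50, events, cfg.screen)
    ranked, gap = rank_and_select(records)
    write_table(records, "results/associations.tsv", cfg.hash())
    write_table(ranked, "results/associations.ranked.tsv", cfg.hash())
    write_table(volcano_table(records), "results/volcano.tsv", cfg.hash())

    print(f"{int(records['tested'].sum())} of {len(records)} pairs tested; "
          f"FDR gap after rank {gap}")
    print("\ntop associations by FDR:")
    for i, row in ranked.head(max(gap, 4)).iterrows():
        marker = "*" if i < gap else " "
        print(f" {marker} {row['drug']:>13} x {row['event']:<16} "
              f"FDR={row['fdr']:.2e} ratio={row['effect_ratio']:.3f} "
              f"({row['direction']}, {row['n_mut']}v{row['n_wt']})")
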