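#!/usr/bin/env python
"""Cross-root DTG summary: union, root-specific sets, down-regulated
fractions — the synthetic analogue of the study's three-way comparison —
plus the published up/down tallies rerun through the same arithmetic
(93.9 % / 63.5 % / 79.2 % down-regulated in PR / CR / SR).
"""

from pathlib import Path

import pandas as pd

from rootdge.root_comparison import down_fraction, summarize, write_summary

OUT = Path("results/analysis")


def main() -> None:
    calls = {root: pd.read_csv(OUT / f"dge_{root}.tsv", sep="\t") for root in ("PR", "CR", "SR")}
    summary = summarize(calls)
    write_summary(summary, OUT / "root_summary.tsv")
    for root, genes in summary.specific_gene_ids.items():
        (OUT / f"specific_{root}.txt").write_text("\n".join(sorted(genes)) + "\n")
    print(f"union of salinity-regulated genes: {summary.union_count}")
    for root in calls:
        print(f"  {root}: {summary.total_count[root]} DTGs "
              f"({summary.up_count[root]} up, {summary.down_count[root]} down), "
              f"{summary.specific_count[root]} specific, "
              f"{summary.down_fraction.get(root, float('nan'))} % down")

    published = {"PR": (13, 199), "CR": (54, 94), "SR": (33, 126)}
    printed = {r: down_fraction(u, d) for r, (u, d) in published.items()}
    print(f"published tallies rerun: {printed} (totals "
          f"{ {r: u + d for r, (u, d) in published.items()} })")


if __name__ == "__main__":
    main()
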