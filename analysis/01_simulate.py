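#!/usr/bin/env python
"""Generate the synthetic six-library study inputs.

Emulates PR/CR/SR roots with and without salt: raw FASTQ with 15 % planted
contamination, count libraries with 30 planted DTGs per root at |log2FC| = 3,
a GO annotation table with one term enriched among the planted DTGs, and the
ground-truth tables the later steps check themselves against.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from rootdge.config import PipelineConfig
from rootdge.expression import write_count_table
from rootdge.pipeline import planted_de_from_config
from rootdge.read_filter import write_fastq
from rootdge.synthetic_data import CountSimSpec, FastqSimSpec, gen_annotations, gen_counts, gen_fastq

OUT = Path("results/analysis")
CFG = PipelineConfig(seed=1)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reads, labels = gen_fastq(FastqSimSpec(seed=CFG.seed + 1, **dataclasses.asdict(CFG.fastq)))
    write_fastq(reads, OUT / "raw_reads.fastq")
    pd.DataFrame({"read_id": [r.read_id for r in reads], "label": labels}).to_csv(
        OUT / "read_truth.tsv", sep="\t", index=False
    )

    libraries, truth = gen_counts(
        CountSimSpec(
            n_genes=CFG.counts.n_genes,
            baseline_mean=CFG.counts.baseline_mean,
            dispersion=CFG.counts.dispersion,
            planted_de=planted_de_from_config(CFG),
            seed=CFG.seed + 2,
        )
    )
    write_count_table(libraries, OUT / "counts.tsv")
    truth.to_csv(OUT / "planted_de.tsv", sep="\t", index=False)

    ann = gen_annotations(
        list(libraries[0].gene_ids),
        n_terms=CFG.annotations.n_terms,
        planted_term=CFG.annotations.planted_term,
        target_gene_set=sorted(truth["gene_id"].unique()),
        odds_ratio=CFG.annotations.odds_ratio,
        baseline_prob=CFG.annotations.baseline_prob,
        seed=CFG.seed + 3,
    )
    ann.to_csv(OUT / "annotations.tsv", sep="\t", index=False)

    totals = {lib.library_id: lib.total_unique for lib in libraries}
    print(f"{len(reads)} reads ({labels.count('clean')} clean by construction)")
    print(f"{CFG.counts.n_genes} genes x 6 libraries; totals: {totals}")
    print(f"{len(truth)} planted DTGs; {ann['term_id'].nunique()} GO terms "
          f"(planted: {CFG.annotations.planted_term})")


if __name__ == "__main__":
    main()
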