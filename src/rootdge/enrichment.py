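"""GO-term over-representation of a DTG set against a background.

One-sided hypergeometric test per term (equivalently one-sided Fisher):
with N background genes of which K are annotated to the term, and n DTGs of
which k are annotated, the raw p is P(X >= k) for X hypergeometric(N, K, n).
Raw p-values go through Bonferroni correction over all terms tested in the
run (terms with at least one annotated background gene); a term is
significantly enriched at corrected p <= 0.05. No GO-graph propagation is
performed: genes count only toward terms they are directly annotated to.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["EnrichmentRecord", "overrep_pvalue", "bonferroni", "enrich", "read_annotations"]


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    k: int  # DTGs annotated to term
    n: int  # DTG set size
    K: int  # background genes annotated to term
    N: int  # background size
    raw_p: float
    corrected_p: float
    significant: bool


def overrep_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k), X ~ draws of n from N with K successes."""
    if k < 0 or n < 0 or K < 0 or N < 0:
        raise ValueError("counts must be non-negative")
    if k > n:
        raise ValueError("annotated DTGs k cannot exceed DTG set size n")
    if K > N:
        raise ValueError("annotated background K cannot exceed background size N")
    if k > K:
        raise ValueError("annotated DTGs k cannot exceed annotated background K")
    if n > N:
        raise ValueError("DTG set size n cannot exceed background size N")
    return float(hypergeom.sf(k - 1, N, K, n))


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni correction over m tests: min(1, raw_p * m)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return min(1.0, raw_p * m)


def enrich(
    dtg_set: Collection[str],
    background_set: Collection[str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every annotated term for over-representation in the DTG set.

    ``annotations`` has columns gene_id, term_id (one pair per row). Only
    annotations of background genes count; a term enters the tested family m
    when at least one background gene carries it. Records are sorted by
    corrected p (ties by term id).
    """
    dtgs = set(dtg_set)
    background = set(background_set)
    stray = dtgs - background
    if stray:
        raise ValueError(f"DTGs not in background: {sorted(stray)[:5]}")
    ann = annotations.loc[annotations["gene_id"].isin(background)]
    term_genes = ann.groupby("term_id")["gene_id"].agg(set)
    m = len(term_genes)
    if m == 0:
        return []
    N, n = len(background), len(dtgs)
    records = []
    for term_id, genes in term_genes.items():
        K = len(genes)
        k = len(genes & dtgs)
        raw = overrep_pvalue(k, n, K, N)
        corr = bonferroni(raw, m)
        records.append(
            EnrichmentRecord(
                term_id=str(term_id),
                k=k,
                n=n,
                K=K,
                N=N,
                raw_p=raw,
                corrected_p=corr,
                significant=corr <= alpha,
            )
        )
    records.sort(key=lambda r: (r.corrected_p, r.term_id))
    return records


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs columns gene_id, term_id")
    return df
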