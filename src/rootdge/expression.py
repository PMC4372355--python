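"""RPKM quantification and mapping-summary arithmetic.

RPKM (reads per kilobase of gene model per million uniquely gene-mapped
reads) for gene X in one library is

    RPKM = 10^6 * C / (N * L / 10^3)

where C is the number of reads uniquely aligned to X, N the total number of
reads uniquely aligned to all genes of the library, and L the gene length in
bases. Mapping summaries mirror the published per-library table: total reads
and reads mapped to reference genes / genome, with percentages at two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountLibrary",
    "MappingSummary",
    "rpkm",
    "rpkm_matrix",
    "mapping_percentages",
    "read_count_table",
    "write_count_table",
]


@dataclass(frozen=True)
class CountLibrary:
    """Per-gene uniquely-mapped read counts for one root-type x condition library.

    ``counts`` and ``gene_lengths`` are pandas Series sharing a gene-id index;
    the library total N is the sum of per-gene counts.
    """

    library_id: str
    counts: pd.Series
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("counts and gene_lengths must share one gene index")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1")

    @property
    def total_unique(self) -> int:
        """N: total reads uniquely aligned to all genes."""
        return int(self.counts.sum())

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


@dataclass(frozen=True)
class MappingSummary:
    """One library's row block of the mapping-summary table."""

    library_id: str
    total_reads: int
    mapped: int
    mapped_pct: float
    unmapped: int
    unmapped_pct: float


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero, the convention of the printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rpkm(C: float, N: float, L: float) -> float:
    """RPKM of one gene: 10^6 * C / (N * L / 10^3)."""
    if N <= 0:
        raise ValueError("library total N must be > 0")
    if L <= 0:
        raise ValueError("gene length L must be >= 1")
    return 1e6 * C / (N * L / 1e3)


def rpkm_matrix(libraries: Sequence[CountLibrary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise RPKM over a shared gene list.

    Returns ``(values, not_expressed)``: a genes x libraries DataFrame of RPKM
    and a same-shaped boolean mask flagging C = 0 cells for downstream "gray"
    (no-expression) handling.
    """
    if not libraries:
        raise ValueError("no libraries given")
    ref = libraries[0]
    for lib in libraries[1:]:
        if not lib.gene_ids.equals(ref.gene_ids):
            raise ValueError(f"gene list of {lib.library_id!r} differs from {ref.library_id!r}")
        if not lib.gene_lengths.equals(ref.gene_lengths):
            raise ValueError(f"gene lengths of {lib.library_id!r} differ from {ref.library_id!r}")
    lengths = ref.gene_lengths.to_numpy(dtype=float)
    values = {}
    zero = {}
    for lib in libraries:
        c = lib.counts.to_numpy(dtype=float)
        n = lib.total_unique
        if n <= 0:
            raise ValueError(f"library {lib.library_id!r} has zero total counts")
        values[lib.library_id] = 1e6 * c / (n * lengths / 1e3)
        zero[lib.library_id] = c == 0
    vals = pd.DataFrame(values, index=ref.gene_ids)
    mask = pd.DataFrame(zero, index=ref.gene_ids)
    return vals, mask


def mapping_percentages(library_id: str, total_reads: int, mapped: int) -> MappingSummary:
    """Mapped/unmapped percentages of a library, at two decimals half-up."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if mapped > total_reads:
        raise ValueError("mapped reads exceed total reads")
    unmapped = total_reads - mapped
    return MappingSummary(
        library_id=library_id,
        total_reads=total_reads,
        mapped=mapped,
        mapped_pct=round_half_up(100.0 * mapped / total_reads, 2),
        unmapped=unmapped,
        unmapped_pct=round_half_up(100.0 * unmapped / total_reads, 2),
    )


# -- count-table TSV I/O ------------------------------------------------------
# Layout: gene_id, length_bp, then one column of counts per library.


def write_count_table(libraries: Sequence[CountLibrary], path: str | Path) -> None:
    ref = libraries[0]
    df = pd.DataFrame({"gene_id": ref.gene_ids, "length_bp": ref.gene_lengths.to_numpy()})
    for lib in libraries:
        df[lib.library_id] = lib.counts.to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> list[CountLibrary]:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("gene_id")
    lengths = df["length_bp"]
    libs = []
    for col in df.columns:
        if col == "length_bp":
            continue
        libs.append(CountLibrary(library_id=col, counts=df[col].astype(np.int64), gene_lengths=lengths))
    return libs
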