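"""Clean-read filtering of raw FASTQ reads.

Three rules are applied in order; a read is removed by the first rule it
violates:

1. the read contains an adaptor sequence (exact contiguous substring);
2. the fraction of unknown bases (N) is strictly greater than 10 %;
3. the fraction of low-quality bases (Phred quality <= 5) is strictly
   greater than 50 %.

Reads are removed whole, never trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequencedRead",
    "FilterPolicy",
    "FilterStats",
    "has_adaptor",
    "n_fraction",
    "low_quality_fraction",
    "filter_reads",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class SequencedRead:
    """One FASTQ record: identifier, bases over {A,C,G,T,N}, per-base Phred qualities."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the three filtering rules.

    Defaults are the published procedure: N fraction > 0.10 removes, a base is
    low-quality at Phred <= 5, and > 50 % low-quality bases removes.
    """

    adaptor_sequences: tuple[str, ...] = ()
    max_n_fraction: float = 0.10
    low_quality_threshold: int = 5
    max_low_quality_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")
        if not 0.0 <= self.max_low_quality_fraction <= 1.0:
            raise ValueError("max_low_quality_fraction must be in [0, 1]")
        if self.low_quality_threshold < 0:
            raise ValueError("low_quality_threshold must be >= 0")


@dataclass
class FilterStats:
    """Per-rule removal tallies; input = retained + sum of removals."""

    input_count: int = 0
    removed_by_adaptor: int = 0
    removed_by_n: int = 0
    removed_by_quality: int = 0
    retained_count: int = 0

    @property
    def removed_total(self) -> int:
        return self.removed_by_adaptor + self.removed_by_n + self.removed_by_quality

    def check(self) -> None:
        if self.input_count != self.retained_count + self.removed_total:
            raise AssertionError("filter stats do not balance")


def has_adaptor(read: SequencedRead, policy: FilterPolicy) -> bool:
    """Rule 1: true iff any adaptor occurs verbatim as a contiguous substring."""
    return any(a and a in read.bases for a in policy.adaptor_sequences)


def n_fraction(read: SequencedRead) -> float:
    """Rule 2 statistic: fraction of unknown (N) bases. Errors on empty reads."""
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    return read.bases.upper().count("N") / len(read)


def low_quality_fraction(read: SequencedRead, policy: FilterPolicy) -> float:
    """Rule 3 statistic: fraction of bases at quality <= policy threshold."""
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    t = policy.low_quality_threshold
    return sum(1 for q in read.qualities if q <= t) / len(read)


def _violated_rule(read: SequencedRead, policy: FilterPolicy) -> str | None:
    """First rule (in published order) the read violates, or None if clean."""
    if has_adaptor(read, policy):
        return "adaptor"
    if n_fraction(read) > policy.max_n_fraction:
        return "n"
    if low_quality_fraction(read, policy) > policy.max_low_quality_fraction:
        return "quality"
    return None


def filter_reads(
    reads: Iterable[SequencedRead], policy: FilterPolicy
) -> tuple[list[SequencedRead], FilterStats]:
    """Apply rules 1->2->3; attribute each removal to the first violated rule.

    Output order preserves input order.
    """
    stats = FilterStats()
    clean: list[SequencedRead] = []
    for read in reads:
        stats.input_count += 1
        rule = _violated_rule(read, policy)
        if rule is None:
            clean.append(read)
            stats.retained_count += 1
        elif rule == "adaptor":
            stats.removed_by_adaptor += 1
        elif rule == "n":
            stats.removed_by_n += 1
        else:
            stats.removed_by_quality += 1
    stats.check()
    return clean, stats


# -- FASTQ I/O (Phred+33 default, Phred+64 dialect available) -----------------

_FORMATS = {33: "fastq", 64: "fastq-illumina"}


def read_fastq(path: str | Path, phred_offset: int = 33) -> list[SequencedRead]:
    fmt = _FORMATS[phred_offset]
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        out.append(
            SequencedRead(
                read_id=rec.id,
                bases=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: Sequence[SequencedRead], path: str | Path, phred_offset: int = 33) -> None:
    fmt = _FORMATS[phred_offset]
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, fmt)
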