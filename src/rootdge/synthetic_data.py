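"""Synthetic inputs with known ground truth for the whole pipeline.

The study design this emulates: six RNA-Seq libraries — primary (PR), crown
(CR) and seminal (SR) maize roots, each untreated and after 100 mM NaCl —
with roughly 10^6-10^7 uniquely gene-mapped reads each and one library per
condition (no replicates). The generators plant known signal so every
downstream stage can be tested against ground truth:

* ``gen_fastq`` — raw reads with exact planted fractions of adaptor
  contamination, high-N reads and low-quality reads, mutually exclusive per
  read so retained-count arithmetic is exact;
* ``gen_counts`` — six count libraries with planted differentially
  transcribed genes at chosen log2 fold-changes (negative binomial, Poisson
  in the zero-dispersion limit that matches the exact test's sampling
  model);
* ``gen_annotations`` — a gene-to-GO-term table with one term enriched in a
  target gene set at a chosen odds ratio;
* ``gen_qpcr_cts`` — replicate Ct tables whose delta-delta-Ct ratios encode
  chosen log2 ratios against multi-reference normalization.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rootdge.expression import CountLibrary
from rootdge.read_filter import SequencedRead

__all__ = [
    "DEFAULT_LIBRARY_IDS",
    "FastqSimSpec",
    "CountSimSpec",
    "PlantedDe",
    "gen_fastq",
    "gen_counts",
    "gen_annotations",
    "gen_qpcr_cts",
    "gene_id",
]

#: the six libraries of the emulated study, as (root x condition) labels
DEFAULT_LIBRARY_IDS = ("PR", "PR-salt", "CR", "CR-salt", "SR", "SR-salt")

#: widely used sequencing-adaptor prefix; any nucleotide string works
DEFAULT_ADAPTOR = "AGATCGGAAGAGC"

CLEAN, ADAPTOR, HIGH_N, LOW_QUALITY = "clean", "adaptor", "high_n", "low_quality"


def gene_id(i: int) -> str:
    return f"gene{i:05d}"


# ---------------------------------------------------------------------------
# FASTQ with planted contamination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FastqSimSpec:
    """Planted-contamination FASTQ simulation.

    The three defect classes are disjoint: a read carries at most one planted
    defect, and exactly round(n_reads * fraction) reads per class.
    """

    n_reads: int
    read_length: int = 49
    adaptor_fraction: float = 0.0
    high_n_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    adaptor_sequence: str = DEFAULT_ADAPTOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        for f in (self.adaptor_fraction, self.high_n_fraction, self.low_quality_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("planted fractions must lie in [0, 1]")
        total = self.adaptor_fraction + self.high_n_fraction + self.low_quality_fraction
        if total > 1.0:
            raise ValueError(
                f"planted fractions sum to {total:.3f} > 1; defect classes are disjoint"
            )
        if self.adaptor_fraction > 0 and len(self.adaptor_sequence) > self.read_length:
            raise ValueError("adaptor longer than the read")


_GOOD_Q = (30, 41)  # quality range of bases outside planted low-quality stretches
_BAD_Q = (0, 6)  # quality range of planted low-quality bases (Phred <= 5)


def _random_bases(rng: np.random.Generator, length: int, forbid: str) -> str:
    """ACGT string not containing ``forbid`` as a substring."""
    alphabet = np.array(list("ACGT"))
    while True:
        s = "".join(rng.choice(alphabet, size=length))
        if not forbid or forbid not in s:
            return s


def gen_fastq(spec: FastqSimSpec) -> tuple[list[SequencedRead], list[str]]:
    """Generate reads and their ground-truth class labels, in shuffled order.

    Exactly round(n_reads * fraction) reads per defect class: ``adaptor``
    reads contain the adaptor verbatim, ``high_n`` reads have an N fraction
    strictly above 10 %, ``low_quality`` reads have strictly more than half
    of their bases at Phred <= 5; ``clean`` reads violate no rule.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reads
    L = spec.read_length
    n_adapt = round(n * spec.adaptor_fraction)
    n_highn = round(n * spec.high_n_fraction)
    n_lowq = round(n * spec.low_quality_fraction)
    if n_adapt + n_highn + n_lowq > n:
        raise ValueError("rounded planted class sizes exceed n_reads")
    labels = (
        [ADAPTOR] * n_adapt
        + [HIGH_N] * n_highn
        + [LOW_QUALITY] * n_lowq
        + [CLEAN] * (n - n_adapt - n_highn - n_lowq)
    )
    labels = [labels[i] for i in rng.permutation(n)]

    adaptor = spec.adaptor_sequence
    n_planted_n = int(np.floor(0.10 * L)) + 1  # strictly > 10 % of L
    n_planted_lq = int(np.floor(0.50 * L)) + 1  # strictly > 50 % of L
    if n_planted_n > L and n_highn > 0:
        raise ValueError("read too short to plant an N fraction above 10 %")

    reads: list[SequencedRead] = []
    for i, label in enumerate(labels):
        quals = rng.integers(*_GOOD_Q, size=L)
        if label == ADAPTOR:
            bases = list(_random_bases(rng, L, adaptor))
            start = int(rng.integers(0, L - len(adaptor) + 1))
            bases[start : start + len(adaptor)] = list(adaptor)
            bases = "".join(bases)
        elif label == HIGH_N:
            seq = list(_random_bases(rng, L, adaptor))
            pos = rng.choice(L, size=n_planted_n, replace=False)
            for p in pos:
                seq[p] = "N"
            bases = "".join(seq)
        elif label == LOW_QUALITY:
            bases = _random_bases(rng, L, adaptor)
            pos = rng.choice(L, size=n_planted_lq, replace=False)
            quals[pos] = rng.integers(*_BAD_Q, size=n_planted_lq)
        else:
            bases = _random_bases(rng, L, adaptor)
        reads.append(
            SequencedRead(read_id=f"read{i:06d}", bases=bases, qualities=tuple(int(q) for q in quals))
        )
    return reads, labels


# ---------------------------------------------------------------------------
# Count libraries with planted differential transcription
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedDe:
    """One planted differentially transcribed gene in one root's comparison."""

    gene_index: int
    root: str  # e.g. "PR": affects the "PR-salt" library relative to "PR"
    log2fc: float


@dataclass(frozen=True)
class CountSimSpec:
    """Six-library count simulation with planted fold-changes.

    Non-planted genes draw a per-gene baseline mean (lognormal around
    ``baseline_mean``) shared by all libraries; planted genes sit exactly at
    ``baseline_mean`` in the control and at baseline * 2^log2fc in the salt
    library of their root. ``dispersion`` is the negative-binomial
    overdispersion alpha (variance = mu + alpha mu^2); 0 gives Poisson
    sampling, the model of the downstream exact test.
    """

    n_genes: int = 5000
    library_ids: tuple[str, ...] = DEFAULT_LIBRARY_IDS
    baseline_mean: float = 400.0
    dispersion: float = 0.0
    planted_de: tuple[PlantedDe, ...] = ()
    gene_length_range: tuple[int, int] = (200, 5000)
    mean_log_sd: float = 1.0
    depth_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.gene_length_range[0] < 1 or self.gene_length_range[1] < self.gene_length_range[0]:
            raise ValueError("gene_length_range must be [lo, hi] with lo >= 1")
        planted_genes = {p.gene_index for p in self.planted_de}
        if len(planted_genes) > self.n_genes:
            raise ValueError("more planted DE genes than genes")
        roots = self.roots()
        for p in self.planted_de:
            if not np.isfinite(p.log2fc):
                raise ValueError("planted log2 fold-changes must be finite")
            if not 0 <= p.gene_index < self.n_genes:
                raise ValueError(f"planted gene index {p.gene_index} out of range")
            if p.root not in roots:
                raise ValueError(f"planted root {p.root!r} has no control/salt library pair")
        if self.depth_factors is not None and len(self.depth_factors) != len(self.library_ids):
            raise ValueError("need one depth factor per library")

    def roots(self) -> tuple[str, ...]:
        """Root labels with both a control and a salt library."""
        ids = set(self.library_ids)
        return tuple(r for r in self.library_ids if "-salt" not in r and f"{r}-salt" in ids)


def gen_counts(spec: CountSimSpec) -> tuple[list[CountLibrary], pd.DataFrame]:
    """Generate the six count libraries plus the planted-DE truth table.

    Returns ``(libraries, truth)`` where truth has columns gene_id, root,
    log2fc (one row per planted gene x comparison).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    lengths = rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=n)
    ids = pd.Index([gene_id(i) for i in range(n)], name="gene_id")

    # per-gene baseline means; planted genes pinned at baseline_mean so their
    # planted effect size is exact
    sd = spec.mean_log_sd
    mu = spec.baseline_mean * np.exp(rng.normal(0.0, sd, size=n) - sd * sd / 2.0)
    planted_idx = {p.gene_index for p in spec.planted_de}
    for i in planted_idx:
        mu[i] = spec.baseline_mean

    depth = (
        np.ones(len(spec.library_ids))
        if spec.depth_factors is None
        else np.asarray(spec.depth_factors, dtype=float)
    )
    fold = {lib: np.ones(n) for lib in spec.library_ids}
    for p in spec.planted_de:
        fold[f"{p.root}-salt"][p.gene_index] *= 2.0**p.log2fc

    libraries = []
    lengths_s = pd.Series(lengths, index=ids, name="length_bp")
    for lib, d in zip(spec.library_ids, depth):
        lam = mu * fold[lib] * d
        if spec.dispersion == 0.0:
            counts = rng.poisson(lam)
        else:
            r = 1.0 / spec.dispersion
            counts = rng.negative_binomial(r, r / (r + lam))
        libraries.append(
            CountLibrary(
                library_id=lib,
                counts=pd.Series(counts.astype(np.int64), index=ids, name=lib),
                gene_lengths=lengths_s,
            )
        )
    truth = pd.DataFrame(
        [
            {"gene_id": gene_id(p.gene_index), "root": p.root, "log2fc": p.log2fc}
            for p in spec.planted_de
        ],
        columns=["gene_id", "root", "log2fc"],
    )
    return libraries, truth


# ---------------------------------------------------------------------------
# GO annotations with one planted enriched term
# ---------------------------------------------------------------------------


def gen_annotations(
    gene_ids: Sequence[str],
    n_terms: int,
    planted_term: str,
    target_gene_set: Iterable[str],
    odds_ratio: float = 10.0,
    baseline_prob: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-to-term table with ``planted_term`` enriched in the target set.

    Every term annotates each gene independently with probability
    ``baseline_prob``; for the planted term, target-set genes are annotated
    at ``odds_ratio`` times the baseline odds. Returns a two-column
    DataFrame (gene_id, term_id).
    """
    target = set(target_gene_set)
    if not target:
        raise ValueError("target gene set is empty")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    stray = target - set(gene_ids)
    if stray:
        raise ValueError(f"target genes not in gene list: {sorted(stray)[:5]}")
    rng = np.random.default_rng(seed)
    p0 = baseline_prob
    odds1 = odds_ratio * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    rows: list[tuple[str, str]] = []
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    if n_terms > 0:
        terms[0] = planted_term
    for term in terms:
        for g in gene_ids:
            p = p1 if (term == planted_term and g in target) else p0
            if rng.random() < p:
                rows.append((g, term))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------------------
# qPCR Ct tables encoding chosen log2 ratios
# ---------------------------------------------------------------------------

DEFAULT_REFERENCE_GENES = ("Zm18SrRNA", "ZmActin", "ZmUBQ")


def gen_qpcr_cts(
    log2_ratios: Mapping[str, float],
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    base_target_ct: float = 26.0,
    base_reference_ct: float = 18.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy Ct table whose delta-delta-Ct ratios encode ``log2_ratios``.

    One target row block per gene and condition ("control"/"treated") with
    replicate Ct values, plus reference-gene rows per condition. The treated
    target Ct is shifted by -log2_ratio cycles so that 2^(-ddCt) equals
    2^log2_ratio up to replicate noise (``noise_sd`` cycles).

    Columns: gene_id, sample, replicate, ct, is_reference.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(gene: str, sample: str, center: float, is_ref: bool) -> None:
        for rep in range(1, n_replicates + 1):
            ct = center + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "gene_id": gene,
                    "sample": sample,
                    "replicate": rep,
                    "ct": round(float(ct), 3),
                    "is_reference": int(is_ref),
                }
            )

    for ref in reference_genes:
        for sample in ("control", "treated"):
            emit(ref, sample, base_reference_ct, True)
    for gene, lfc in log2_ratios.items():
        emit(gene, "control", base_target_ct, False)
        emit(gene, "treated", base_target_ct - lfc, False)
    return pd.DataFrame(rows)
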