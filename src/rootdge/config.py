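"""Structured pipeline configuration (YAML, per-stage sections).

All randomness flows from the single top-level ``seed``; stage generators
derive fixed offsets from it, so a config fully determines every output.
Validation happens up front: an out-of-range threshold is rejected before
any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from rootdge.dge_test import CallingThresholds
from rootdge.read_filter import FilterPolicy

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class FastqSection:
    n_reads: int = 10_000
    read_length: int = 49
    adaptor_fraction: float = 0.05
    high_n_fraction: float = 0.03
    low_quality_fraction: float = 0.07
    adaptor_sequence: str = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class CountsSection:
    n_genes: int = 5000
    baseline_mean: float = 400.0
    dispersion: float = 0.0
    n_planted_per_root: int = 30
    planted_log2fc: float = 3.0
    planted_down_fraction: float = 0.5


@dataclass(frozen=True)
class AnnotationSection:
    n_terms: int = 50
    planted_term: str = "GO:0006950"  # response to stress
    odds_ratio: float = 10.0
    baseline_prob: float = 0.05


@dataclass(frozen=True)
class ClusterSection:
    policy: str = "complete-rows"

    def __post_init__(self) -> None:
        if self.policy not in ("complete-rows", "pairwise"):
            raise ValueError(f"unknown clustering policy {self.policy!r}")


@dataclass(frozen=True)
class EnrichSection:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("enrichment alpha must be in (0, 1]")


@dataclass(frozen=True)
class QpcrSection:
    n_genes: int = 16
    discordant_fraction: float = 0.3
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValueError("discordant_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DgeSection:
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    fdr_method: str = "bh"

    def thresholds(self) -> CallingThresholds:
        return CallingThresholds(fdr_max=self.fdr_max, min_abs_log2=self.min_abs_log2)

    def __post_init__(self) -> None:
        self.thresholds()  # range checks
        if self.fdr_method.lower() not in ("bh", "by"):
            raise ValueError(f"unknown FDR method {self.fdr_method!r}")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    fastq: FastqSection = field(default_factory=FastqSection)
    counts: CountsSection = field(default_factory=CountsSection)
    annotations: AnnotationSection = field(default_factory=AnnotationSection)
    filter: FilterPolicy = field(default_factory=FilterPolicy)
    dge: DgeSection = field(default_factory=DgeSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    enrich: EnrichSection = field(default_factory=EnrichSection)
    qpcr: QpcrSection = field(default_factory=QpcrSection)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "fastq": FastqSection,
    "counts": CountsSection,
    "annotations": AnnotationSection,
    "filter": FilterPolicy,
    "dge": DgeSection,
    "cluster": ClusterSection,
    "enrich": EnrichSection,
    "qpcr": QpcrSection,
}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides win over file values."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    kwargs: dict = {}
    for key, value in raw.items():
        cls = _SECTIONS.get(key)
        if cls is not None and isinstance(value, dict):
            if key == "filter" and "adaptor_sequences" in value:
                value = {**value, "adaptor_sequences": tuple(value["adaptor_sequences"])}
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
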