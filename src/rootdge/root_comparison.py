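"""Cross-root aggregation of DTG calls.

Combines the three per-root salt-vs-control call tables (primary, crown and
seminal roots) into the summary the study reports: per-root up/down tallies,
the union of salinity-regulated genes, root-specific sets (genes called in
exactly one root), and the per-root down-regulated fraction. "Regulated"
means called up or down; undetected and not-significant genes are excluded
from the set logic. A gene called up in one root and down in another counts
once in the union and is not root-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from rootdge.dge_test import DOWN, UP
from rootdge.expression import round_half_up

__all__ = ["RootComparisonSummary", "summarize", "down_fraction", "write_summary"]


@dataclass(frozen=True)
class RootComparisonSummary:
    """Tallies across the three root types."""

    up_count: dict[str, int]
    down_count: dict[str, int]
    total_count: dict[str, int]
    specific_count: dict[str, int]
    specific_gene_ids: dict[str, frozenset[str]]
    union_count: int
    union_gene_ids: frozenset[str]
    down_fraction: dict[str, float]  # percent, one decimal


def down_fraction(up_count: int, down_count: int) -> float:
    """Percentage of DTGs that are down-regulated, one decimal half-up."""
    total = up_count + down_count
    if total <= 0:
        raise ValueError("no regulated genes: up + down must be > 0")
    return round_half_up(100.0 * down_count / total, 1)


def _called_sets(calls: pd.DataFrame) -> tuple[set[str], set[str]]:
    if calls["gene_id"].duplicated().any():
        dup = calls.loc[calls["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id within a comparison: {dup!r}")
    up = set(calls.loc[calls["call"] == UP, "gene_id"])
    down = set(calls.loc[calls["call"] == DOWN, "gene_id"])
    return up, down


def summarize(calls_by_root: Mapping[str, pd.DataFrame]) -> RootComparisonSummary:
    """Aggregate per-root call tables (as produced by ``run_comparison``).

    ``calls_by_root`` maps a root label (e.g. PR/CR/SR) to its comparison
    table; tables need columns ``gene_id`` and ``call``.
    """
    regulated: dict[str, set[str]] = {}
    up_count: dict[str, int] = {}
    down_count: dict[str, int] = {}
    total_count: dict[str, int] = {}
    fractions: dict[str, float] = {}
    for root, calls in calls_by_root.items():
        up, down = _called_sets(calls)
        regulated[root] = up | down
        up_count[root] = len(up)
        down_count[root] = len(down)
        total_count[root] = len(up) + len(down)
        if total_count[root] > 0:
            fractions[root] = down_fraction(len(up), len(down))

    union: set[str] = set().union(*regulated.values()) if regulated else set()
    specific_ids = {
        root: frozenset(
            genes.difference(*(regulated[r] for r in regulated if r != root))
            if len(regulated) > 1
            else genes
        )
        for root, genes in regulated.items()
    }
    return RootComparisonSummary(
        up_count=up_count,
        down_count=down_count,
        total_count=total_count,
        specific_count={r: len(s) for r, s in specific_ids.items()},
        specific_gene_ids=specific_ids,
        union_count=len(union),
        union_gene_ids=frozenset(union),
        down_fraction=fractions,
    )


def write_summary(summary: RootComparisonSummary, path: str | Path) -> None:
    rows = []
    for root in summary.total_count:
        rows.append(
            {
                "root": root,
                "up": summary.up_count[root],
                "down": summary.down_count[root],
                "total": summary.total_count[root],
                "specific": summary.specific_count[root],
                "down_pct": summary.down_fraction.get(root, float("nan")),
            }
        )
    df = pd.DataFrame(rows)
    df["union_total"] = summary.union_count
    df.to_csv(path, sep="\t", index=False)
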