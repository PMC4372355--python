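"""Exact between-library differential-transcription test and DTG calling.

With one sequencing library per condition, the evidence that a gene is
differentially transcribed rests on its clean-tag counts x (control) and y
(treatment) and the library totals N1, N2. Under the null of equal relative
abundance, the probability of observing y treatment tags given x control
tags is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1),

the classical exact test for digital gene-expression (tag-count) data. A
two-sided p-value doubles the smaller cumulative tail around the observed y
(capped at 1). Genes are called differentially transcribed when the
FDR-adjusted q-value is <= 0.001 and |log2(treatment/control)| >= 1, with
the ratio computed from RPKM; a gene with zero expression in either library
is flagged ``undetected`` and excluded from ratio-based calling.

The point mass is evaluated in log-gamma space. For whole-table work a
vectorised tail path uses the algebraic identity of p(y|x) with the negative
binomial pmf NB(x + 1, N1/(N1+N2)), whose cumulative tail is a regularized
incomplete beta function; tests pin the two routes together and against
brute-force summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc, betaincc, gammaln
from statsmodels.stats.multitest import multipletests

from rootdge.expression import CountLibrary, rpkm

__all__ = [
    "DgeRecord",
    "CallingThresholds",
    "ac_probability",
    "ac_pvalue",
    "ac_pvalue_vec",
    "fdr_adjust",
    "call_dtg",
    "run_comparison",
    "comparison_records",
    "write_comparison",
    "UP",
    "DOWN",
    "NOT_SIGNIFICANT",
    "UNDETECTED",
]

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"
UNDETECTED = "undetected"


@dataclass(frozen=True)
class CallingThresholds:
    """DTG calling thresholds; both boundaries are inclusive."""

    fdr_max: float = 0.001
    min_abs_log2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_max <= 1.0:
            raise ValueError("fdr_max must be in (0, 1]")
        if self.min_abs_log2 < 0:
            raise ValueError("min_abs_log2 must be >= 0")


@dataclass(frozen=True)
class DgeRecord:
    """One gene in one treatment-vs-control comparison."""

    gene_id: str
    x: int
    y: int
    N1: int
    N2: int
    rpkm_control: float
    rpkm_treatment: float
    log2_ratio: float  # NaN when undetected
    p_value: float
    q_value: float
    call: str


def _check_counts(x: int, y: int, N1: int, N2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("tag counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")


def ac_probability(x: int, y: int, N1: int, N2: int) -> float:
    """Point mass p(y|x) for tag counts between libraries of totals N1, N2."""
    _check_counts(x, y, N1, N2)
    log_r = np.log(N2) - np.log(N1)
    lo, hi = sorted((x, y))  # symmetric combination: exact x<->y symmetry at N1=N2
    log_p = (
        y * log_r
        + gammaln(x + y + 1)
        - (gammaln(lo + 1) + gammaln(hi + 1))
        - (x + y + 1) * np.log1p(np.exp(log_r))
    )
    return float(np.exp(log_p))


def _lower_tail(x: int, y: int, N1: int, N2: int) -> float:
    """Sum_{k=0..y} p(k|x) by the stable multiplicative recurrence."""
    r = N2 / N1
    # p(0|x) = (1+r)^-(x+1); then p(k+1|x) = p(k|x) * r/(1+r) * (x+k+1)/(k+1)
    log_t = -(x + 1) * np.log1p(r)
    total = float(np.exp(log_t))
    log_step = np.log(r) - np.log1p(r)
    for k in range(y):
        log_t += log_step + np.log(x + k + 1) - np.log(k + 1)
        total += float(np.exp(log_t))
    return min(total, 1.0)


def _upper_tail_direct(x: int, y: int, N1: int, N2: int) -> float:
    """Sum_{k>=y} p(k|x), truncated once the geometric tail is negligible."""
    r = N2 / N1
    log_t = (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )
    log_step = np.log(r) - np.log1p(r)
    total = t = float(np.exp(log_t))
    k = y
    while t > total * 1e-17 or k <= x + y + 2:
        log_t += log_step + np.log(x + k + 1) - np.log(k + 1)
        t = float(np.exp(log_t))
        total += t
        k += 1
        if k > y + 100_000:
            break
    return min(total, 1.0)


def ac_pvalue(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided p: doubled smaller cumulative tail around y, capped at 1.

    The upper tail is evaluated as 1 minus the lower tail below y; when that
    subtraction is ill-conditioned (tail below ~1e-6) it is refined by direct
    summation from y upward, truncated once terms are negligible.
    """
    _check_counts(x, y, N1, N2)
    lower = _lower_tail(x, y, N1, N2)
    upper = 1.0 if y == 0 else 1.0 - _lower_tail(x, y - 1, N1, N2)
    if upper < 1e-6:
        upper = _upper_tail_direct(x, y, N1, N2)
    p = min(1.0, 2.0 * min(lower, max(upper, 0.0)))
    return 1.0 if p >= 1.0 - 1e-12 else p


def ac_pvalue_vec(
    x: np.ndarray, y: np.ndarray, N1: int, N2: int
) -> np.ndarray:
    """Vectorised two-sided p over count arrays.

    Uses the negative-binomial identity: the lower tail of p(.|x) at y is the
    regularized incomplete beta I_{N1/(N1+N2)}(x+1, y+1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("tag counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    p1 = N1 / (N1 + N2)
    lower = betainc(x + 1.0, y + 1.0, p1)
    upper = np.where(y > 0, betaincc(x + 1.0, np.maximum(y, 1.0), p1), 1.0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(p >= 1.0 - 1e-12, 1.0, p)


def fdr_adjust(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR step-up adjustment, input order preserved.

    method: "bh" (Benjamini-Hochberg, default) or "by" (Benjamini-Yekutieli).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    return multipletests(p, method=key)[1]


def call_dtg(record: DgeRecord, thresholds: CallingThresholds = CallingThresholds()) -> str:
    """Classify one gene: up/down at q <= fdr_max and |log2| >= min_abs_log2."""
    if record.call == UNDETECTED or np.isnan(record.log2_ratio):
        return UNDETECTED
    if record.q_value <= thresholds.fdr_max:
        if record.log2_ratio >= thresholds.min_abs_log2:
            return UP
        if record.log2_ratio <= -thresholds.min_abs_log2:
            return DOWN
    return NOT_SIGNIFICANT


def run_comparison(
    control: CountLibrary,
    treatment: CountLibrary,
    thresholds: CallingThresholds = CallingThresholds(),
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-gene exact test of one treatment-vs-control library pair.

    Tests every gene observed in at least one library (raw clean-tag counts);
    q-values are adjusted over all tested genes of this comparison. The log2
    ratio is computed from RPKM so library size and gene length cancel
    consistently; genes unobserved in either library are ``undetected``.

    Returns a DataFrame with columns gene_id, x, y, N1, N2, rpkm_control,
    rpkm_treatment, log2_ratio, p_value, q_value, call.
    """
    if not control.gene_ids.equals(treatment.gene_ids):
        raise ValueError("control and treatment libraries must share one gene list")
    x = control.counts.to_numpy(dtype=np.int64)
    y = treatment.counts.to_numpy(dtype=np.int64)
    L = control.gene_lengths.to_numpy(dtype=float)
    N1 = control.total_unique
    N2 = treatment.total_unique

    rpkm_c = 1e6 * x / (N1 * L / 1e3)
    rpkm_t = 1e6 * y / (N2 * L / 1e3)
    detected = (x > 0) & (y > 0)
    log2_ratio = np.full(x.shape, np.nan)
    log2_ratio[detected] = np.log2(rpkm_t[detected] / rpkm_c[detected])

    tested = (x + y) > 0
    p = np.full(x.shape, np.nan)
    q = np.full(x.shape, np.nan)
    p[tested] = ac_pvalue_vec(x[tested], y[tested], N1, N2)
    if tested.any():
        q[tested] = fdr_adjust(p[tested], method=fdr_method)

    df = pd.DataFrame(
        {
            "gene_id": control.gene_ids,
            "x": x,
            "y": y,
            "N1": N1,
            "N2": N2,
            "rpkm_control": rpkm_c,
            "rpkm_treatment": rpkm_t,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "q_value": q,
        }
    ).reset_index(drop=True)

    call = np.where(
        ~detected,
        UNDETECTED,
        np.where(
            (df["q_value"] <= thresholds.fdr_max) & (df["log2_ratio"] >= thresholds.min_abs_log2),
            UP,
            np.where(
                (df["q_value"] <= thresholds.fdr_max)
                & (df["log2_ratio"] <= -thresholds.min_abs_log2),
                DOWN,
                NOT_SIGNIFICANT,
            ),
        ),
    )
    df["call"] = call
    return df


def comparison_records(df: pd.DataFrame) -> list[DgeRecord]:
    """View a comparison table as typed per-gene records."""
    return [
        DgeRecord(
            gene_id=row.gene_id,
            x=int(row.x),
            y=int(row.y),
            N1=int(row.N1),
            N2=int(row.N2),
            rpkm_control=row.rpkm_control,
            rpkm_treatment=row.rpkm_treatment,
            log2_ratio=row.log2_ratio,
            p_value=row.p_value,
            q_value=row.q_value,
            call=row.call,
        )
        for row in df.itertuples(index=False)
    ]


def write_comparison(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
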