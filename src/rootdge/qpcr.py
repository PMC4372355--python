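"""Delta-delta-Ct relative quantification and RNA-Seq concordance.

Relative transcript abundance from qPCR cycle-threshold (Ct) values with
multi-reference normalization: per condition, the reference Cts (the study
uses Zm18S rRNA, ZmActin and ZmUBQ) are combined by arithmetic mean per
replicate and subtracted from the mean target Ct,

    dCt   = mean(target Ct) - mean(reference Ct),
    ddCt  = dCt_treated - dCt_control,
    ratio = 2^(-ddCt),

assuming the classical amplification efficiency of 2. Concordance scores a
gene/comparison pair as agreeing when the sign of the log2 qPCR ratio
matches the RNA-Seq call direction (up <-> positive, down <-> negative); a
ratio of exactly 1 agrees with no directional call.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rootdge.dge_test import DOWN, UP

__all__ = ["delta_delta_ct", "concordance", "ratios_from_table"]


def _mean_reference_ct(refs: Sequence[Sequence[float]]) -> float:
    """Combine reference genes: arithmetic mean of per-replicate mean Cts."""
    if len(refs) == 0 or any(len(r) == 0 for r in refs):
        raise ValueError("missing reference measurements")
    per_gene = [float(np.mean(np.asarray(r, dtype=float))) for r in refs]
    return float(np.mean(per_gene))


def delta_delta_ct(
    target_treated: Sequence[float],
    refs_treated: Sequence[Sequence[float]],
    target_control: Sequence[float],
    refs_control: Sequence[Sequence[float]],
) -> float:
    """Relative abundance 2^(-ddCt) of the treated vs control condition.

    ``refs_*`` hold one replicate-Ct sequence per reference gene.
    """
    if len(target_treated) == 0 or len(target_control) == 0:
        raise ValueError("missing target measurements")
    d_treated = float(np.mean(np.asarray(target_treated, dtype=float))) - _mean_reference_ct(
        refs_treated
    )
    d_control = float(np.mean(np.asarray(target_control, dtype=float))) - _mean_reference_ct(
        refs_control
    )
    ddct = d_treated - d_control
    return float(2.0 ** (-ddct))


def ratios_from_table(
    table: pd.DataFrame,
    control_sample: str = "control",
    treated_sample: str = "treated",
) -> dict[str, float]:
    """Per-target delta-delta-Ct ratios from a tidy Ct table.

    Expects columns gene_id, sample, replicate, ct, is_reference. Reference
    rows (is_reference truthy) are shared by all targets of a sample.
    """
    required = {"gene_id", "sample", "replicate", "ct", "is_reference"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")

    def ref_cts(sample: str) -> list[list[float]]:
        block = table[(table["sample"] == sample) & (table["is_reference"].astype(bool))]
        if block.empty:
            raise ValueError(f"no reference measurements for sample {sample!r}")
        return [grp["ct"].tolist() for _, grp in block.groupby("gene_id")]

    refs_c, refs_t = ref_cts(control_sample), ref_cts(treated_sample)
    targets = table[~table["is_reference"].astype(bool)]
    ratios: dict[str, float] = {}
    for gene, grp in targets.groupby("gene_id"):
        ct_c = grp.loc[grp["sample"] == control_sample, "ct"].tolist()
        ct_t = grp.loc[grp["sample"] == treated_sample, "ct"].tolist()
        ratios[str(gene)] = delta_delta_ct(ct_t, refs_t, ct_c, refs_c)
    return ratios


def concordance(
    qpcr_ratios: Mapping[str, float], rnaseq_calls: Mapping[str, str]
) -> float:
    """Fraction of shared gene/comparison keys whose directions agree.

    A qPCR ratio > 1 agrees with an ``up`` call, < 1 with ``down``; a ratio
    of exactly 1 counts as non-agreeing with any directional call.
    """
    shared = sorted(set(qpcr_ratios) & set(rnaseq_calls))
    if not shared:
        raise ValueError("no shared gene/comparison keys")
    agree = 0
    for key in shared:
        ratio = qpcr_ratios[key]
        if ratio <= 0:
            raise ValueError(f"qPCR ratio for {key!r} must be positive")
        call = rnaseq_calls[key]
        sign = np.sign(np.log2(ratio))
        if (call == UP and sign > 0) or (call == DOWN and sign < 0):
            agree += 1
    return agree / len(shared)
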