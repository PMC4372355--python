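"""End-to-end pipeline: simulate -> filter -> quantify -> dge -> compare ->
cluster -> enrich -> qpcr.

Each stage writes its outputs under the configured directory and passes them
to the next stage; a manifest records every output file's SHA-256 and the
parameters used, so a rerun with the same config is byte-reproducible and
auditable. Stages log their headline numbers at the boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from rootdge import clustering, dge_test, enrichment, qpcr, root_comparison, synthetic_data
from rootdge.config import PipelineConfig
from rootdge.expression import rpkm_matrix, write_count_table
from rootdge.read_filter import FilterPolicy, filter_reads, write_fastq
from rootdge.synthetic_data import CountSimSpec, FastqSimSpec, PlantedDe

__all__ = ["run_pipeline", "planted_de_from_config"]

log = logging.getLogger("rootdge.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def planted_de_from_config(cfg: PipelineConfig) -> tuple[PlantedDe, ...]:
    """Deterministic planted-DE layout: per root, n genes at +/- the
    configured |log2FC|, gene indices disjoint across roots."""
    planted = []
    k = cfg.counts.n_planted_per_root
    n_down = round(k * cfg.counts.planted_down_fraction)
    i = 0
    for root in ("PR", "CR", "SR"):
        for j in range(k):
            sign = -1.0 if j < n_down else 1.0
            planted.append(PlantedDe(gene_index=i, root=root, log2fc=sign * cfg.counts.planted_log2fc))
            i += 1
    return tuple(planted)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    def record(stage: str, files: dict[str, Path], **params) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
        }
        log.info("stage %s done: %s", stage, {k: str(p) for k, p in files.items()})

    try:
        # -- simulate -------------------------------------------------------
        fq_spec = FastqSimSpec(seed=cfg.seed + 1, **asdict(cfg.fastq))
        reads, labels = synthetic_data.gen_fastq(fq_spec)
        fastq_path = out / "raw_reads.fastq"
        write_fastq(reads, fastq_path)
        labels_path = out / "read_truth.tsv"
        pd.DataFrame({"read_id": [r.read_id for r in reads], "label": labels}).to_csv(
            labels_path, sep="\t", index=False
        )

        planted = planted_de_from_config(cfg)
        count_spec = CountSimSpec(
            n_genes=cfg.counts.n_genes,
            baseline_mean=cfg.counts.baseline_mean,
            dispersion=cfg.counts.dispersion,
            planted_de=planted,
            seed=cfg.seed + 2,
        )
        libraries, truth = synthetic_data.gen_counts(count_spec)
        counts_path = out / "counts.tsv"
        write_count_table(libraries, counts_path)
        truth_path = out / "planted_de.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)

        gene_ids = list(libraries[0].gene_ids)
        # the planted term is enriched among the planted DTGs — the set the
        # enrichment stage will actually test downstream
        target = sorted(truth["gene_id"].unique())
        ann = synthetic_data.gen_annotations(
            gene_ids,
            n_terms=cfg.annotations.n_terms,
            planted_term=cfg.annotations.planted_term,
            target_gene_set=target,
            odds_ratio=cfg.annotations.odds_ratio,
            baseline_prob=cfg.annotations.baseline_prob,
            seed=cfg.seed + 3,
        )
        ann_path = out / "annotations.tsv"
        ann.to_csv(ann_path, sep="\t", index=False)
        record(
            "simulate",
            {
                "fastq": fastq_path,
                "read_truth": labels_path,
                "counts": counts_path,
                "planted_de": truth_path,
                "annotations": ann_path,
            },
            seed=cfg.seed,
            n_reads=fq_spec.n_reads,
            n_genes=count_spec.n_genes,
        )

        # -- filter ---------------------------------------------------------
        policy = cfg.filter
        if not policy.adaptor_sequences:
            policy = FilterPolicy(
                adaptor_sequences=(cfg.fastq.adaptor_sequence,),
                max_n_fraction=policy.max_n_fraction,
                low_quality_threshold=policy.low_quality_threshold,
                max_low_quality_fraction=policy.max_low_quality_fraction,
            )
        clean, stats = filter_reads(reads, policy)
        clean_path = out / "clean_reads.fastq"
        write_fastq(clean, clean_path)
        stats_path = out / "filter_stats.tsv"
        pd.DataFrame([vars(stats)]).to_csv(stats_path, sep="\t", index=False)
        record(
            "filter",
            {"clean_fastq": clean_path, "stats": stats_path},
            retained=stats.retained_count,
            removed=stats.removed_total,
        )

        # -- quantify -------------------------------------------------------
        rpkms, not_expressed = rpkm_matrix(libraries)
        rpkm_path = out / "rpkm.tsv"
        rpkms.to_csv(rpkm_path, sep="\t")
        record("quantify", {"rpkm": rpkm_path}, libraries=len(libraries))

        # -- dge ------------------------------------------------------------
        libs = {lib.library_id: lib for lib in libraries}
        thresholds = cfg.dge.thresholds()
        calls_by_root: dict[str, pd.DataFrame] = {}
        dge_files: dict[str, Path] = {}
        for root in ("PR", "CR", "SR"):
            comp = dge_test.run_comparison(
                libs[root], libs[f"{root}-salt"], thresholds, fdr_method=cfg.dge.fdr_method
            )
            calls_by_root[root] = comp
            p = out / f"dge_{root}.tsv"
            dge_test.write_comparison(comp, p)
            dge_files[root] = p
        record(
            "dge",
            dge_files,
            fdr_max=thresholds.fdr_max,
            min_abs_log2=thresholds.min_abs_log2,
            calls={r: int((c["call"].isin(["up", "down"])).sum()) for r, c in calls_by_root.items()},
        )

        # -- compare --------------------------------------------------------
        summary = root_comparison.summarize(calls_by_root)
        summary_path = out / "root_summary.tsv"
        root_comparison.write_summary(summary, summary_path)
        specific_files = {}
        for root, genes in summary.specific_gene_ids.items():
            p = out / f"specific_{root}.txt"
            p.write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))
            specific_files[f"specific_{root}"] = p
        record(
            "compare",
            {"summary": summary_path, **specific_files},
            union=summary.union_count,
        )

        # -- cluster --------------------------------------------------------
        regulated = sorted(summary.union_gene_ids)
        profile_cols = {}
        for root, comp in calls_by_root.items():
            s = comp.set_index("gene_id")["log2_ratio"]
            profile_cols[root] = s.reindex(regulated)
        profiles = clustering.ProfileMatrix(values=pd.DataFrame(profile_cols))
        cluster_files: dict[str, Path] = {}
        if len(regulated) >= 2:
            dendro, ordered, gray = clustering.cluster_profiles(profiles, policy=cfg.cluster.policy)
            merges_path = out / "cluster_merges.tsv"
            clustering.write_dendrogram(dendro, merges_path)
            ordered_path = out / "cluster_profiles.tsv"
            ordered.to_csv(ordered_path, sep="\t")
            cluster_files = {"merges": merges_path, "ordered_profiles": ordered_path}
            record("cluster", cluster_files, n_profiles=len(regulated), policy=cfg.cluster.policy)
        else:
            record("cluster", {}, n_profiles=len(regulated), skipped="fewer than 2 regulated genes")

        # -- enrich ---------------------------------------------------------
        annotated = set(ann["gene_id"]) & set(gene_ids)
        dtgs = set(regulated) & annotated
        records = enrichment.enrich(dtgs, annotated, ann, alpha=cfg.enrich.alpha)
        enr_path = out / "enrichment.tsv"
        pd.DataFrame([vars(r) for r in records]).to_csv(enr_path, sep="\t", index=False)
        record(
            "enrich",
            {"enrichment": enr_path},
            n_terms_tested=len(records),
            n_significant=sum(r.significant for r in records),
        )

        # -- qpcr -----------------------------------------------------------
        pr = calls_by_root["PR"]
        called = pr[pr["call"].isin(["up", "down"])].set_index("gene_id")
        chosen = list(called.index[: cfg.qpcr.n_genes])
        rng = np.random.default_rng(cfg.seed + 4)
        n_flip = round(len(chosen) * cfg.qpcr.discordant_fraction)
        flipped = set(rng.choice(chosen, size=n_flip, replace=False)) if chosen else set()
        true_lfc = {
            g: (-called.loc[g, "log2_ratio"] if g in flipped else called.loc[g, "log2_ratio"])
            for g in chosen
        }
        ct_table = synthetic_data.gen_qpcr_cts(
            true_lfc, noise_sd=cfg.qpcr.noise_sd, seed=cfg.seed + 5
        )
        ct_path = out / "qpcr_cts.tsv"
        ct_table.to_csv(ct_path, sep="\t", index=False)
        report: dict = {"n_genes": len(chosen)}
        if chosen:
            ratios = qpcr.ratios_from_table(ct_table)
            calls = {g: str(called.loc[g, "call"]) for g in chosen}
            report["concordance"] = qpcr.concordance(ratios, calls)
        report_path = out / "qpcr_concordance.json"
        report_path.write_text(json.dumps(report, indent=2) + "\n")
        record("qpcr", {"cts": ct_path, "report": report_path}, **report)
    except Exception as exc:  # annotate which stage died, keep the traceback
        done = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {done}; partial outputs in {out}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
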