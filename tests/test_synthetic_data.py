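"""Generator contracts: planted ground truth, determinism, input validation."""

import io

import numpy as np
import pandas as pd
import pytest

from rootdge.read_filter import write_fastq
from rootdge.synthetic_data import (
    CountSimSpec,
    FastqSimSpec,
    PlantedDe,
    gen_annotations,
    gen_counts,
    gen_fastq,
    gen_qpcr_cts,
    gene_id,
)


class TestGenFastq:
    def test_planted_classes_exact_and_disjoint(self):
        spec = FastqSimSpec(
            n_reads=1000,
            adaptor_fraction=0.05,
            high_n_fraction=0.03,
            low_quality_fraction=0.07,
            seed=1,
        )
        reads, labels = gen_fastq(spec)
        counts = pd.Series(labels).value_counts()
        assert counts["adaptor"] == 50 and counts["high_n"] == 30
        assert counts["low_quality"] == 70 and counts["clean"] == 850
        # re-check every read against the three rules it was planted for
        for read, label in zip(reads, labels):
            has_ad = spec.adaptor_sequence in read.bases
            nf = read.bases.count("N") / len(read)
            lqf = sum(q <= 5 for q in read.qualities) / len(read)
            expected = {
                "adaptor": (True, False, False),
                "high_n": (False, True, False),
                "low_quality": (False, False, True),
                "clean": (False, False, False),
            }[label]
            assert (has_ad, nf > 0.10, lqf > 0.50) == expected

    def test_all_fractions_zero_all_clean(self):
        reads, labels = gen_fastq(FastqSimSpec(n_reads=200, seed=2))
        assert set(labels) == {"clean"}

    def test_byte_identical_for_same_seed(self):
        spec = FastqSimSpec(n_reads=100, adaptor_fraction=0.1, seed=9)

        def dump():
            buf = io.StringIO()
            reads, _ = gen_fastq(spec)
            import tempfile, pathlib

            with tempfile.TemporaryDirectory() as d:
                p = pathlib.Path(d) / "x.fastq"
                write_fastq(reads, p)
                return p.read_bytes()

        assert dump() == dump()

    def test_overlapping_fractions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            FastqSimSpec(n_reads=10, adaptor_fraction=0.6, high_n_fraction=0.5)


class TestGenCounts:
    def test_planted_ratio_near_eight(self):
        spec = CountSimSpec(
            n_genes=50,
            baseline_mean=1000.0,
            planted_de=(PlantedDe(0, "PR", 3.0),),
            seed=4,
        )
        libs, truth = gen_counts(spec)
        by_id = {l.library_id: l for l in libs}
        g = gene_id(0)
        ratio = by_id["PR-salt"].counts[g] / by_id["PR"].counts[g]
        assert ratio == pytest.approx(8.0, rel=0.10)
        assert truth.iloc[0].tolist() == [g, "PR", 3.0]

    def test_null_log_ratios_centred_at_zero(self):
        libs, truth = gen_counts(CountSimSpec(n_genes=2000, baseline_mean=300.0, seed=5))
        assert truth.empty
        by_id = {l.library_id: l for l in libs}
        x = by_id["CR"].counts.to_numpy()
        y = by_id["CR-salt"].counts.to_numpy()
        keep = (x > 0) & (y > 0)
        mean_lr = np.log2(y[keep] / x[keep]).mean()
        assert abs(mean_lr) < 0.02

    def test_totals_equal_sum_of_counts(self, six_libraries):
        for lib in six_libraries[0]:
            assert lib.total_unique == lib.counts.sum()

    def test_seeds_change_counts_and_same_seed_reproduces(self):
        spec = dict(n_genes=100, baseline_mean=100.0)
        a, _ = gen_counts(CountSimSpec(seed=1, **spec))
        b, _ = gen_counts(CountSimSpec(seed=2, **spec))
        c, _ = gen_counts(CountSimSpec(seed=1, **spec))
        assert not a[0].counts.equals(b[0].counts)
        assert a[0].counts.equals(c[0].counts)

    def test_negative_binomial_is_overdispersed(self):
        pois, _ = gen_counts(CountSimSpec(n_genes=3000, baseline_mean=200.0, mean_log_sd=0.0, seed=6))
        nb, _ = gen_counts(
            CountSimSpec(n_genes=3000, baseline_mean=200.0, mean_log_sd=0.0, dispersion=0.3, seed=6)
        )
        assert nb[0].counts.var() > 3 * pois[0].counts.var()

    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            CountSimSpec(n_genes=2, planted_de=(PlantedDe(5, "PR", 1.0),))
        with pytest.raises(ValueError):
            CountSimSpec(planted_de=(PlantedDe(0, "XX", 1.0),))
        with pytest.raises(ValueError):
            CountSimSpec(planted_de=(PlantedDe(0, "PR", float("inf")),))


class TestGenAnnotations:
    def test_planted_term_best_in_majority_of_seeds(self):
        from rootdge.enrichment import enrich

        genes = [gene_id(i) for i in range(1000)]
        target = set(genes[:50])
        wins = 0
        for seed in range(20):
            ann = gen_annotations(genes, n_terms=30, planted_term="GO:TEST",
                                  target_gene_set=target, odds_ratio=10.0, seed=seed)
            records = enrich(target, set(genes), ann)
            if records and records[0].term_id == "GO:TEST":
                wins += 1
        assert wins >= 15

    def test_null_odds_ratio_gives_uniformish_p(self):
        from rootdge.enrichment import enrich

        genes = [gene_id(i) for i in range(400)]
        target = set(genes[:40])
        raw_ps = []
        for seed in range(30):
            ann = gen_annotations(genes, n_terms=1, planted_term="GO:NULL",
                                  target_gene_set=target, odds_ratio=1.0, seed=seed)
            recs = enrich(target, set(genes), ann)
            if recs:
                raw_ps.append(recs[0].raw_p)
        assert 0.2 < np.mean(raw_ps) < 0.8

    def test_zero_terms_and_empty_target(self):
        genes = [gene_id(i) for i in range(10)]
        assert gen_annotations(genes, 0, "GO:X", {genes[0]}, seed=0).empty
        with pytest.raises(ValueError, match="empty"):
            gen_annotations(genes, 5, "GO:X", set(), seed=0)


class TestGenQpcr:
    def test_encoded_ratio_recovered(self):
        from rootdge.qpcr import ratios_from_table

        table = gen_qpcr_cts({"gA": 2.0, "gB": -1.0}, noise_sd=0.0, seed=0)
        ratios = ratios_from_table(table)
        assert ratios["gA"] == pytest.approx(4.0, rel=1e-6)
        assert ratios["gB"] == pytest.approx(0.5, rel=1e-6)
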