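"""Exact DGE test: point mass, tails, FDR adjustment, and DTG calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import nbinom

from rootdge.dge_test import (
    DOWN,
    NOT_SIGNIFICANT,
    UNDETECTED,
    UP,
    CallingThresholds,
    DgeRecord,
    ac_probability,
    ac_pvalue,
    ac_pvalue_vec,
    call_dtg,
    comparison_records,
    fdr_adjust,
    run_comparison,
)
from rootdge.synthetic_data import CountSimSpec, PlantedDe, gen_counts
from tests.conftest import make_library


def exact_mass(x: int, y: int, N1: int, N2: int) -> Fraction:
    """The point mass in exact rational arithmetic (independent oracle)."""
    r = Fraction(N2, N1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


class TestPointMass:
    @pytest.mark.parametrize(
        "x,y,expected", [(0, 0, 0.5), (1, 1, 0.25), (2, 0, 0.125)]
    )
    def test_hand_examples_equal_totals(self, x, y, expected):
        assert ac_probability(x, y, 10**6, 10**6) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_rational_arithmetic(self):
        for N1, N2 in [(100, 100), (1000, 3000), (987654, 123456)]:
            for x in range(0, 31, 3):
                for y in range(0, 31, 3):
                    exact = float(exact_mass(x, y, N1, N2))
                    assert ac_probability(x, y, N1, N2) == pytest.approx(exact, rel=1e-10)

    def test_symmetry_when_totals_equal(self):
        for x in range(0, 40, 7):
            for y in range(0, 40, 7):
                assert ac_probability(x, y, 500, 500) == pytest.approx(
                    ac_probability(y, x, 500, 500), rel=1e-12
                )

    def test_normalization_partial_sums(self):
        for N1, N2 in [(10**6, 10**6), (2 * 10**6, 5 * 10**5)]:
            for x in (0, 5, 50):
                partial = np.cumsum([ac_probability(x, y, N1, N2) for y in range(4000)])
                assert (partial <= 1 + 1e-9).all()
                assert partial[-1] == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 0, 10, 10)

    def test_is_negative_binomial_mass(self):
        # p(.|x) is NB(x+1, N1/(N1+N2)) in y — pin the identity with scipy
        for x, y, N1, N2 in [(3, 7, 1000, 2500), (0, 0, 10, 90), (20, 4, 777, 333)]:
            assert ac_probability(x, y, N1, N2) == pytest.approx(
                nbinom.pmf(y, x + 1, N1 / (N1 + N2)), rel=1e-12
            )


class TestPvalue:
    def test_mode_gives_one(self):
        assert ac_pvalue(17, 17, 10**6, 10**6) == 1.0

    def test_extreme_tail(self):
        assert ac_pvalue(50, 0, 10**6, 10**6) < 1e-9
        assert ac_pvalue(50, 0, 10**6, 10**6) == pytest.approx(2 * 0.5**51, rel=1e-9)

    def test_brute_force_summation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            x, y = (int(v) for v in rng.integers(0, 80, 2))
            N1, N2 = (int(v) for v in rng.integers(10**4, 10**6, 2))
            lower = sum(ac_probability(x, k, N1, N2) for k in range(y + 1))
            upper = sum(ac_probability(x, k, N1, N2) for k in range(y, x + y + 1000))
            expected = min(1.0, 2.0 * min(lower, upper))
            assert ac_pvalue(x, y, N1, N2) == pytest.approx(expected, abs=1e-10)

    def test_vectorised_path_matches_scalar(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 500, 100)
        y = rng.integers(0, 500, 100)
        N1, N2 = 1_234_567, 2_345_678
        vec = ac_pvalue_vec(x, y, N1, N2)
        for xi, yi, pi in zip(x, y, vec):
            assert ac_pvalue(int(xi), int(yi), N1, N2) == pytest.approx(pi, rel=1e-9, abs=1e-300)


class TestFdr:
    def test_bh_hand_worked_example(self):
        q = fdr_adjust([0.001, 0.01, 0.02, 0.03])
        assert q == pytest.approx([0.004, 0.02, 0.02667, 0.03], abs=5e-6)

    def test_constant_and_single(self):
        assert fdr_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])
        assert fdr_adjust([0.123]) == pytest.approx([0.123])

    def test_by_is_more_conservative(self):
        p = [0.001, 0.01, 0.02, 0.03]
        assert (fdr_adjust(p, "by") >= fdr_adjust(p, "bh")).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([0.5], method="bonf")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_monotone_in_sorted_p(self, ps):
        q = fdr_adjust(sorted(ps))
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= np.sort(ps) - 1e-12).all()


class TestCalling:
    def rec(self, q, lr, call=NOT_SIGNIFICANT):
        return DgeRecord("g", 1, 1, 10, 10, 1.0, 1.0, lr, 0.5 * q, q, call)

    def test_boundaries_inclusive(self):
        t = CallingThresholds()
        assert call_dtg(self.rec(0.0005, 1.0), t) == UP
        assert call_dtg(self.rec(0.001, -2.0), t) == DOWN
        assert call_dtg(self.rec(0.01, 3.0), t) == NOT_SIGNIFICANT
        assert call_dtg(self.rec(0.0005, 0.99), t) == NOT_SIGNIFICANT

    def test_undetected_passes_through(self):
        r = DgeRecord("g", 0, 5, 10, 10, 0.0, 1.0, float("nan"), 0.01, 0.02, UNDETECTED)
        assert call_dtg(r) == UNDETECTED

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CallingThresholds(fdr_max=0.0)


class TestRunComparison:
    def test_identical_libraries_zero_calls(self):
        lib = make_library("c", [100, 200, 0, 5], [500, 1000, 800, 300])
        lib2 = make_library("t", [100, 200, 0, 5], [500, 1000, 800, 300])
        df = run_comparison(lib, lib2)
        assert set(df["call"]) <= {NOT_SIGNIFICANT, UNDETECTED}
        assert (df.loc[df["x"] == df["y"], "p_value"].dropna() == 1.0).all()

    def test_undetected_semantics_and_log_ratio_from_rpkm(self):
        c = make_library("c", [0, 10, 8], [1000, 1000, 500])
        t = make_library("t", [5, 0, 16], [1000, 1000, 500])
        df = run_comparison(c, t)
        assert df["call"].tolist()[:2] == [UNDETECTED, UNDETECTED]
        # RPKM ratio equals count ratio rescaled by library totals
        expected = np.log2((16 / t.total_unique) / (8 / c.total_unique))
        assert df["log2_ratio"].iloc[2] == pytest.approx(expected)

    def test_planted_gene_called_with_direction(self):
        spec = CountSimSpec(
            n_genes=500,
            baseline_mean=1000.0,
            planted_de=(PlantedDe(0, "PR", 3.0), PlantedDe(1, "PR", -3.0)),
            seed=21,
        )
        libs, _ = gen_counts(spec)
        by_id = {l.library_id: l for l in libs}
        df = run_comparison(by_id["PR"], by_id["PR-salt"]).set_index("gene_id")
        assert df.loc["gene00000", "call"] == UP
        assert df.loc["gene00001", "call"] == DOWN

    def test_gene_list_mismatch_rejected(self):
        a = make_library("a", [1], [100], gene_ids=["g1"])
        b = make_library("b", [1], [100], gene_ids=["g2"])
        with pytest.raises(ValueError):
            run_comparison(a, b)

    def test_records_view_roundtrips(self):
        c = make_library("c", [3, 9], [100, 200])
        t = make_library("t", [9, 3], [100, 200])
        df = run_comparison(c, t)
        recs = comparison_records(df)
        assert [r.gene_id for r in recs] == df["gene_id"].tolist()
        assert all(r.N1 == c.total_unique and r.N2 == t.total_unique for r in recs)
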