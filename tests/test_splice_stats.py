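"""Splicing efficiency, CMH test, q values, RPKM, diagnostic counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lariatscan.aligner import ClassificationResult, LariatHit
from lariatscan.annotation_io import Intron
from lariatscan.junction_db import JunctionRecord
from lariatscan.splice_stats import (
    cmh_test,
    count_diagnostic_reads,
    differential_splicing,
    qvalues,
    rpkm,
    splicing_efficiency,
)


def cmh_oracle(tables):
    """Direct evaluation of the CMH formula, written independently:
    sum_k (a_k - E_k) squared over sum_k Var_k, 1 df."""
    delta = 0.0
    variance = 0.0
    for (a, b), (c, d) in tables:
        n = a + b + c + d
        if n <= 1 or (a + b) * (c + d) * (a + c) * (b + d) == 0:
            continue
        delta += a - (a + b) * (a + c) / n
        variance += (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    return delta**2 / variance


class TestSplicingEfficiency:
    @pytest.mark.parametrize(
        "jr,ei,expected", [(0, 7, 0.0), (5, 0, 1.0), (30, 10, 0.75)]
    )
    def test_proportion(self, jr, ei, expected):
        assert splicing_efficiency(jr, ei) == pytest.approx(expected)

    def test_both_zero_is_nan(self):
        assert np.isnan(splicing_efficiency(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            splicing_efficiency(-1, 5)

    def test_ratio_flag(self):
        assert splicing_efficiency(30, 10, ratio=True) == pytest.approx(3.0)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_bounded_and_complementary(self, jr, ei):
        se = splicing_efficiency(jr, ei)
        if jr + ei == 0:
            assert np.isnan(se)
        else:
            assert 0.0 <= se <= 1.0
            assert se + splicing_efficiency(ei, jr) == pytest.approx(1.0)


class TestCMH:
    TABLE = [[[10, 20], [15, 5]]]

    def test_single_stratum_matches_hand_formula(self):
        stat, p = cmh_test(self.TABLE)
        assert stat == pytest.approx(cmh_oracle(self.TABLE))
        # Hand computation: E = 30*25/50 = 15, Var = 30*20*25*25/(2500*49).
        assert stat == pytest.approx((10 - 15) ** 2 / (30 * 20 * 25 * 25 / (2500 * 49)))
        assert 0 < p < 0.01

    def test_two_identical_strata_doubles_statistic(self):
        single, _ = cmh_test(self.TABLE)
        double, _ = cmh_test(self.TABLE * 2)
        assert double == pytest.approx(2 * single)

    def test_identical_columns_zero_statistic(self):
        stat, p = cmh_test([[[12, 12], [30, 30]]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_stratum_order_invariance(self):
        strata = [[[10, 20], [15, 5]], [[3, 9], [8, 2]], [[7, 7], [1, 12]]]
        stat_fwd, _ = cmh_test(strata)
        stat_rev, _ = cmh_test(strata[::-1])
        assert stat_fwd == pytest.approx(stat_rev)

    def test_zero_stratum_contributes_nothing(self):
        stat, _ = cmh_test(self.TABLE)
        stat_padded, _ = cmh_test(self.TABLE + [[[0, 0], [0, 0]]])
        assert stat_padded == pytest.approx(stat)

    def test_all_zero_returns_nan(self):
        stat, p = cmh_test([[[0, 0], [0, 0]]])
        assert np.isnan(stat) and np.isnan(p)

    def test_matches_statsmodels(self):
        # Independent cross-check against the reference implementation.
        from statsmodels.stats.contingency_tables import StratifiedTable

        strata = [[[10, 20], [15, 5]], [[3, 9], [8, 2]]]
        arr = np.array(strata, dtype=float)
        sm_tables = [arr[k] for k in range(arr.shape[0])]
        result = StratifiedTable(sm_tables).test_null_odds(correction=False)
        stat, p = cmh_test(strata)
        assert stat == pytest.approx(result.statistic)
        assert p == pytest.approx(result.pvalue)

    def test_continuity_correction_flag(self):
        stat_plain, _ = cmh_test(self.TABLE)
        stat_corr, _ = cmh_test(self.TABLE, continuity_correction=True)
        assert stat_corr < stat_plain


class TestQvalues:
    def test_all_ones_stay_one(self):
        assert np.allclose(qvalues(np.ones(20)), 1.0)

    def test_bh_hand_example(self):
        q = qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        assert np.allclose(q, 0.04)

    @pytest.mark.parametrize("method", ["bh", "storey_lambda_grid"])
    def test_monotone_in_p_rank_and_bounded(self, method):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 1, 150), rng.uniform(0, 1e-3, 20)])
        q = qvalues(p, method=method)
        assert (q <= 1.0 + 1e-12).all() and (q >= 0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_no_less_conservative_than_bh_scaled(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 200)
        q_storey = qvalues(p, method="storey_lambda_grid")
        q_bh = qvalues(p, method="bh")
        assert (q_storey <= q_bh + 1e-9).all()  # pi0 <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestRpkm:
    def test_worked_example(self):
        assert rpkm(100, 1e7, 1000) == pytest.approx(10 + 1e-5)

    def test_zero_reads_gives_eps(self):
        assert rpkm(0, 1e7, 1000) == pytest.approx(1e-5)

    def test_linear_in_reads(self):
        assert rpkm(200, 1e7, 1000) - 1e-5 == pytest.approx(
            2 * (rpkm(100, 1e7, 1000) - 1e-5)
        )

    @pytest.mark.parametrize("total,length", [(0, 100), (100, 0)])
    def test_degenerate_denominators_rejected(self, total, length):
        with pytest.raises(ValueError):
            rpkm(10, total, length)


class TestCountDiagnosticReads:
    """Constructed single-transcript fixture with known read placements."""

    GENOME = {"chr1": "A" * 200}

    def setup_objects(self):
        intron = Intron("tx1.i1", "tx1", 1, "chr1", (51, 100), "+", "G" * 50)
        junction = JunctionRecord("tx1.j1-2", "tx1", 1, 2, "X" * 86, 43, "adjacent")
        return intron, junction

    def genome_hit(self, read_id, start0, length=20, orientation="sense"):
        return LariatHit(read_id, "chr1", start0, orientation, (), length)

    def result(self, genome_hits=(), junction_hits=()):
        return ClassificationResult(
            assignments={},
            ambiguous=set(),
            genome_hits={h.read_id: h for h in genome_hits},
            junction_hits={h.read_id: h for h in junction_hits},
            lariat_hits={},
            counts={},
        )

    def test_exonic_read_counts_to_neither(self):
        intron, junction = self.setup_objects()
        res = self.result(genome_hits=[self.genome_hit("r1", 10)])
        counts = count_diagnostic_reads(res, [junction], [intron], min_overlap=6)
        assert counts.loc["tx1.i1", "JR"] == 0 and counts.loc["tx1.i1", "EI"] == 0

    def test_upstream_boundary_read_counts_ei(self):
        # Exon/intron boundary after genomic base 50; read covering
        # 41..60 straddles it 10/10.
        intron, junction = self.setup_objects()
        res = self.result(genome_hits=[self.genome_hit("r1", 40)])
        counts = count_diagnostic_reads(res, [junction], [intron], min_overlap=6)
        assert counts.loc["tx1.i1", "EI"] == 1

    def test_downstream_boundary_not_counted(self):
        # Intron/downstream-exon boundary after base 100: upstream 5' exon
        # only, so this read counts to neither.
        intron, junction = self.setup_objects()
        res = self.result(genome_hits=[self.genome_hit("r1", 90)])
        counts = count_diagnostic_reads(res, [junction], [intron], min_overlap=6)
        assert counts.loc["tx1.i1", "EI"] == 0

    def test_insufficient_overlap_not_counted(self):
        intron, junction = self.setup_objects()
        res = self.result(genome_hits=[self.genome_hit("r1", 46)])  # 5/15 split
        counts = count_diagnostic_reads(res, [junction], [intron], min_overlap=6)
        assert counts.loc["tx1.i1", "EI"] == 0

    def test_antisense_placement_ignored_when_stranded(self):
        intron, junction = self.setup_objects()
        res = self.result(
            genome_hits=[self.genome_hit("r1", 40, orientation="antisense")]
        )
        counts = count_diagnostic_reads(res, [junction], [intron], min_overlap=6)
        assert counts.loc["tx1.i1", "EI"] == 0

    def test_junction_read_counts_jr(self):
        intron, junction = self.setup_objects()
        jr_hit = LariatHit("r1", "tx1.j1-2", 23, "sense", (), 40)  # 20/20 overlap
        res = self.result(junction_hits=[jr_hit])
        counts = count_diagnostic_reads(res, [junction], [intron], min_overlap=6)
        assert counts.loc["tx1.i1", "JR"] == 1


class TestDifferentialSplicing:
    def test_affected_introns_enriched_among_significant(self):
        from lariatscan.simulate import simulate_splice_counts

        counts, affected = simulate_splice_counts(
            n_introns=300, n_affected=30, n_replicates=2, mean_depth=60, seed=3
        )
        table = differential_splicing(counts, ["A1", "A2"], ["B1", "B2"])
        significant = set(table.index[table["q_value"] < 0.05])
        affected = set(affected)
        # Power check: most affected introns are recovered, and they are
        # strongly enriched among the significant calls.
        recall = len(significant & affected) / len(affected)
        assert recall >= 0.7
        background_rate = len(significant - affected) / (300 - len(affected))
        assert recall > 5 * max(background_rate, 1 / 270)

    def test_se_columns_match_direct_computation(self):
        counts = {
            "A1": pd.DataFrame({"JR": [30, 0], "EI": [10, 0]}, index=["i1", "i2"]),
            "B1": pd.DataFrame({"JR": [5, 8], "EI": [15, 0]}, index=["i1", "i2"]),
        }
        table = differential_splicing(counts, ["A1"], ["B1"])
        assert table.loc["i1", "SE_A1"] == pytest.approx(0.75)
        assert np.isnan(table.loc["i2", "SE_A1"])
        assert table.loc["i2", "SE_B1"] == pytest.approx(1.0)
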