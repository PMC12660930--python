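"""QC filters: thresholds, boundary semantics, doublet and conversion recovery."""

import numpy as np
import pandas as pd
import pytest

from snmctkit.nucleus_qc import (NucleusQCRecord, QCThresholds, basic_qc,
                                 censor_coverage_doublets,
                                 conversion_qc, coverage_doublet_stats,
                                 organelle_filter, run_qc, records_to_frame)
from conftest import meth_table

SIZES = {"chr1": 100_000}


def _counts(total, genes):
    """A count column with `total` reads spread over `genes` genes."""
    per = total // genes
    vals = [per] * genes
    vals[0] += total - per * genes
    return pd.Series(vals, index=[f"g{i}" for i in range(genes)])


class TestBasicQC:
    def test_rna_read_threshold_is_at_least_1000(self):
        rec = basic_qc(meth_table([]), _counts(999, 500), SIZES)
        assert "fail_rna" in rec.flags
        rec = basic_qc(meth_table([("chr1", i * 1000, "+", "CG", 0, 1)
                                   for i in range(20)]),
                       _counts(1000, 500), SIZES)
        assert "fail_rna" not in rec.flags

    def test_gene_threshold_is_at_least_200(self):
        rec = basic_qc(meth_table([]), _counts(5000, 199), SIZES)
        assert "fail_rna" in rec.flags

    def test_wgbs_bin_fraction_boundary_inclusive(self):
        # 100 one-kb bins; reads in exactly 10 distinct bins -> 0.10 passes
        table = meth_table([("chr1", b * 1000 + 5, "+", "CG", 0, 1)
                            for b in range(10)])
        rec = basic_qc(table, _counts(5000, 500), SIZES)
        assert rec.wgbs_bin_fraction == pytest.approx(0.10)
        assert "fail_wgbs" not in rec.flags
        table9 = meth_table([("chr1", b * 1000 + 5, "+", "CG", 0, 1)
                             for b in range(9)])
        assert "fail_wgbs" in basic_qc(table9, _counts(5000, 500), SIZES).flags

    def test_last_partial_bin_counts(self):
        sizes = {"chr1": 1500}  # bins [0,1000) and [1000,1500)
        table = meth_table([("chr1", 1400, "+", "CG", 0, 1)])
        rec = basic_qc(table, _counts(5000, 500), sizes)
        assert rec.wgbs_bin_fraction == pytest.approx(0.5)

    def test_empty_count_column_fails_rna_not_raises(self):
        rec = basic_qc(meth_table([]), pd.Series(dtype=np.int64), SIZES)
        assert "fail_rna" in rec.flags


class TestOrganelleFilter:
    @pytest.mark.parametrize("org,total,flagged", [
        (11, 100, True),   # 0.11 > 0.10 strict
        (10, 100, False),  # exactly 0.10 passes
        (0, 100, False),
    ])
    def test_strict_boundary(self, org, total, flagged):
        col = pd.Series({"org1": org, "g1": total - org})
        frac, flag = organelle_filter(col, {"org1"})
        assert frac == pytest.approx(org / total)
        assert flag is flagged

    def test_zero_reads_not_flagged(self):
        frac, flag = organelle_filter(pd.Series({"org1": 0, "g1": 0}), {"org1"})
        assert (frac, flag) == (0.0, False)


class TestCoverageDoubletStats:
    def test_haploid_nucleus(self):
        t = meth_table([("chr1", p, "+", "CG", 0, 1) for p in (1, 5, 9)])
        assert coverage_doublet_stats(t) == (3, 0, 0.0)

    def test_hand_counted_mixture(self):
        t = meth_table([("chr1", 1, "+", "CG", 0, 1), ("chr1", 2, "+", "CG", 0, 2),
                        ("chr1", 3, "+", "CG", 0, 3), ("chr1", 4, "+", "CG", 0, 1)])
        assert coverage_doublet_stats(t) == (2, 2, 0.5)

    def test_union_of_half_coverage_nuclei_gives_one_third(self):
        """Two nuclei covering 50% of 1000 sites independently: the union's
        multi fraction has expectation 0.25/0.75."""
        rng = np.random.default_rng(42)
        a = rng.random(1000) < 0.5
        b = rng.random(1000) < 0.5
        cov = a.astype(int) + b.astype(int)
        rows = [("chr1", i, "+", "CG", 0, c) for i, c in enumerate(cov) if c]
        _, _, mf = coverage_doublet_stats(meth_table(rows))
        assert mf == pytest.approx(1 / 3, abs=0.05)

    def test_union_dominates_singletons(self, tiny_result):
        truth = tiny_result.truth.nuclei.set_index("nucleus_id")
        singles = [coverage_doublet_stats(tiny_result.meth[n])[2]
                   for n in truth.index[~truth["is_doublet"]]]
        doublets = [coverage_doublet_stats(tiny_result.meth[n])[2]
                    for n in truth.index[truth["is_doublet"]]]
        assert min(doublets) > max(singles)


def _records(fracs, totals):
    recs = []
    for i, (f, tot) in enumerate(zip(fracs, totals)):
        nm = int(round(f * tot))
        recs.append(NucleusQCRecord(f"n{i:03d}", n_cov1=tot - nm, n_covmulti=nm,
                                    multi_fraction=f))
    return recs


class TestCensorCoverageDoublets:
    def test_all_zero_flags_nothing(self):
        recs = _records([0.0] * 50, [1000] * 50)
        assert censor_coverage_doublets(recs) == set()

    def test_planted_outliers_at_equal_coverage_exactly_flagged(self):
        rng = np.random.default_rng(0)
        fracs = list(rng.uniform(0.0005, 0.0015, size=100)) + [0.3] * 5
        recs = _records(fracs, [1000] * 105)
        flagged = censor_coverage_doublets(recs)
        assert flagged == {f"n{i:03d}" for i in range(100, 105)}

    def test_flagging_invariant_under_input_order(self):
        rng = np.random.default_rng(1)
        fracs = list(rng.uniform(0, 0.002, size=80)) + [0.25] * 4
        totals = list(rng.integers(500, 5000, size=84))
        recs = _records(fracs, totals)
        ref = censor_coverage_doublets(recs)
        perm = [recs[i] for i in rng.permutation(len(recs))]
        for r in perm:
            r.flags.discard("doublet_coverage")
        assert censor_coverage_doublets(perm) == ref

    def test_small_cohort_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 20"):
            assert censor_coverage_doublets(_records([0.5] * 5, [100] * 5)) == set()


class TestConversionQC:
    def test_perfect_conversion(self):
        t = meth_table([("ChrC", i, "+", "CG", 0, 1) for i in range(500)])
        frac, est, flag = conversion_qc(t)
        assert (frac, est, flag) == (0.0, 1.0, False)

    def test_five_percent_failure_flagged(self):
        rows = [("ChrC", i, "+", "CG", int(i < 25), 1) for i in range(500)]
        frac, est, flag = conversion_qc(meth_table(rows))
        assert frac == pytest.approx(0.05)
        assert flag

    def test_insufficient_coverage_withholds_flag(self):
        rows = [("ChrC", i, "+", "CG", 1, 1) for i in range(50)]
        with pytest.warns(UserWarning, match="coverage"):
            frac, _, flag = conversion_qc(meth_table(rows))
        assert frac == 1.0 and not flag

    def test_binomial_estimate_accuracy_at_2000x(self):
        """conversion 0.99 at 2000 chloroplast calls: estimate within
        +-0.005 (about 2.2 binomial SE)."""
        rng = np.random.default_rng(1234)
        mc = rng.random(2000) < 0.01
        rows = [("ChrC", i, "+", "CG", int(m), 1) for i, m in enumerate(mc)]
        _, est, _ = conversion_qc(meth_table(rows))
        assert est == pytest.approx(0.99, abs=0.005)


class TestRunQC:
    def test_planted_failures_recovered_by_category(self, qc_stress_result):
        res = qc_stress_result
        recs = run_qc(res.meth, res.counts, res.chrom_sizes)
        df = records_to_frame(recs)
        truth = res.truth.nuclei.set_index("nucleus_id")
        expect = {"low_rna": "fail_rna", "few_genes": "fail_rna",
                  "low_wgbs": "fail_wgbs", "high_organelle": "fail_organelle",
                  "conversion": "fail_conversion"}
        for cat, flag in expect.items():
            planted = truth.index[truth["planted"] == cat]
            assert df.loc[planted, flag].all(), f"{cat} not fully recovered"
        # large-separation planted failures produce no false positives among
        # clean singletons
        clean = truth.index[truth["planted"] == "ok"]
        for flag in ("fail_wgbs", "fail_organelle", "fail_conversion"):
            assert not df.loc[clean, flag].any(), flag
        doublets = truth.index[truth["planted"] == "doublet"]
        assert df.loc[doublets, "doublet_coverage"].all()
        assert not df.loc[clean, "doublet_coverage"].any()

    def test_passed_iff_no_flags(self, qc_stress_result):
        recs = run_qc(qc_stress_result.meth, qc_stress_result.counts,
                      qc_stress_result.chrom_sizes)
        for r in recs:
            assert r.passed == (not r.flags)
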