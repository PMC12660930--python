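"""Region means, pooling conservation, profiles, densities, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from snmctkit.io_formats import MethCallTable, RegionSet, combine_meth_tables
from snmctkit.methylome_stats import (cohens_d, effect_grid, mc_density_bins,
                                      pool_cluster, pooled_fraction,
                                      profile_matrix, region_mean_per_nucleus,
                                      region_means_table,
                                      smooth_chromosome_profile, star_category,
                                      tss_window_regions)
from conftest import meth_table


def _regions(intervals, name="r", strand=None):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["id"] = [f"{name}{i}" for i in range(len(df))]
    if strand is not None:
        df["strand"] = strand
    return RegionSet(name, df)


class TestRegionMean:
    REG = _regions([("chr1", 0, 1000)])

    def test_weighted_mean_formula(self):
        t = meth_table([("chr1", 10, "+", "CG", 2, 4),
                        ("chr1", 20, "+", "CG", 1, 1)])
        assert region_mean_per_nucleus(t, self.REG, "CG") == pytest.approx(0.6)

    def test_no_covered_site_is_missing(self):
        t = meth_table([("chr1", 5000, "+", "CG", 1, 1)])
        assert np.isnan(region_mean_per_nucleus(t, self.REG, "CG"))

    def test_fully_methylated(self):
        t = meth_table([("chr1", i * 10, "+", "CG", 1, 1) for i in range(5)])
        assert region_mean_per_nucleus(t, self.REG, "CG") == 1.0

    def test_min_cov_filters_sites(self):
        t = meth_table([("chr1", 10, "+", "CG", 2, 4),
                        ("chr1", 20, "+", "CG", 1, 1)])
        assert region_mean_per_nucleus(t, self.REG, "CG", min_cov=2) \
            == pytest.approx(0.5)

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            region_mean_per_nucleus(meth_table([]), self.REG, "CpG")


class TestPooling:
    def test_sitewise_addition(self):
        t1 = meth_table([("chr1", 10, "+", "CG", 1, 1)], "n1")
        t2 = meth_table([("chr1", 10, "+", "CG", 0, 1)], "n2")
        tracks = pool_cluster({"n1": t1, "n2": t2}, {"n1": "A", "n2": "A"})
        row = tracks[("A", "all")].iloc[0]
        assert (row["mc"], row["cov"]) == (1, 2)

    def test_pooled_fraction_is_coverage_weighted_mean(self, tiny_result):
        labels = {n: "all" for n in tiny_result.meth}
        track = pool_cluster(tiny_result.meth, labels)[("all", "all")]
        pooled = pooled_fraction(track, context="CG")
        num = den = 0.0
        for t in tiny_result.meth.values():
            sub = t.df[t.df["context"] == "CG"]
            num += sub["mc"].sum()
            den += sub["cov"].sum()
        assert pooled == pytest.approx(num / den, abs=1e-15)

    def test_removing_a_nucleus_changes_only_its_sites(self):
        t1 = meth_table([("chr1", 10, "+", "CG", 1, 1)], "n1")
        t2 = meth_table([("chr1", 99, "+", "CG", 1, 1)], "n2")
        full = pool_cluster({"n1": t1, "n2": t2}, {"n1": "A", "n2": "A"})[("A", "all")]
        reduced = pool_cluster({"n1": t1, "n2": t2}, {"n1": "A", "n2": "A"},
                               include=["n1"])[("A", "all")]
        kept = full[full["pos"] == 10].reset_index(drop=True)
        pd.testing.assert_frame_equal(kept, reduced)

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            pool_cluster({}, {})


class TestTssWindows:
    SIZES = {"chr1": 10_000}

    def test_plus_strand_window(self):
        tss = _regions([("chr1", 1000, 1001)], strand="+")
        win = tss_window_regions(tss, self.SIZES, flank=400)
        assert (win.df.iloc[0]["start"], win.df.iloc[0]["end"]) == (600, 1400)

    def test_clipped_at_chromosome_start(self):
        tss = _regions([("chr1", 100, 101)], strand="+")
        win = tss_window_regions(tss, {"chr1": 1000}, flank=400)
        assert (win.df.iloc[0]["start"], win.df.iloc[0]["end"]) == (0, 500)

    def test_minus_strand_anchor_is_end_minus_one(self):
        tss = _regions([("chr1", 1000, 2000)], strand="-")
        win = tss_window_regions(tss, self.SIZES, flank=100)
        assert (win.df.iloc[0]["start"], win.df.iloc[0]["end"]) == (1899, 2099)

    def test_zero_flank_is_an_error(self):
        tss = _regions([("chr1", 1000, 1001)], strand="+")
        with pytest.raises(ValueError):
            tss_window_regions(tss, self.SIZES, flank=0)


def _uniform_track(positions, frac, chrom="chr1", context="CG"):
    rows = [(chrom, p, "+", context, int(frac * 2), 2) for p in positions]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "mc", "cov"])


class TestProfiles:
    def test_uniform_methylation_gives_flat_profile(self):
        track = _uniform_track(range(0, 4000, 10), 0.5)
        regions = _regions([("chr1", 1000, 2000), ("chr1", 2500, 3500)],
                           strand="+")
        prof = profile_matrix(track, regions, mode="reference_point",
                              flank=500, n_bins=10)
        np.testing.assert_allclose(prof["methylation"], 0.5)

    def test_strand_flip_oracle_on_step_pattern(self):
        # 0% upstream, 100% inside the region body, on both strands
        rows = []
        for p in range(0, 3000, 10):
            inside = 1000 <= p < 2000
            rows.append(("chr1", p, "+", "CG", int(inside), 1))
        track = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                            "context", "mc", "cov"])
        plus = profile_matrix(track, _regions([("chr1", 1000, 2000)], strand="+"),
                              mode="scale_regions", n_bins=10)
        minus = profile_matrix(track, _regions([("chr1", 1000, 2000)], strand="-"),
                               mode="scale_regions", n_bins=10)
        np.testing.assert_allclose(plus["methylation"], minus["methylation"])
        np.testing.assert_allclose(plus["methylation"], 1.0)

    def test_profile_of_pool_is_coverage_weighted_mean(self, tiny_result):
        regions = tiny_result.regions["cg_hypo_dmr"]
        labels = {n: "all" for n in tiny_result.meth}
        track = pool_cluster(tiny_result.meth, labels)[("all", "all")]
        pooled = profile_matrix(track, regions, mode="scale_regions",
                                n_bins=5, context="CG")
        mc = np.zeros(5)
        cov = np.zeros(5)
        for t in tiny_result.meth.values():
            p = profile_matrix(t.df, regions, mode="scale_regions", n_bins=5,
                               context="CG")
            w = p["coverage"].to_numpy()
            v = np.nan_to_num(p["methylation"].to_numpy())
            mc += v * w
            cov += w
        np.testing.assert_allclose(
            pooled["methylation"].to_numpy(),
            np.where(cov > 0, mc / np.where(cov > 0, cov, 1), np.nan))

    def test_record_order_invariance(self):
        track = _uniform_track(range(0, 2000, 7), 0.5)
        regions = _regions([("chr1", 200, 1200)], strand="+")
        a = profile_matrix(track, regions, mode="scale_regions", n_bins=8)
        b = profile_matrix(track.sample(frac=1.0, random_state=0), regions,
                           mode="scale_regions", n_bins=8)
        pd.testing.assert_frame_equal(a, b)


class TestDensity:
    def test_summed_percent_definition(self):
        rows = [("chr1", 10, "+", "CG", 5, 10),   # 50%
                ("chr1", 20, "+", "CG", 10, 10),  # 100%
                ("chr1", 30, "+", "CG", 0, 10)]   # 0%
        track = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                            "context", "mc", "cov"])
        out = mc_density_bins(track, bin_size=400)
        assert out.loc[0, "CG"] == pytest.approx(150.0)

    def test_min_cov_five_applies(self):
        rows = [("chr1", 10, "+", "CG", 1, 1)]  # below the 5-read rule
        track = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                            "context", "mc", "cov"])
        out = mc_density_bins(track, bin_size=400, chrom_sizes={"chr1": 400})
        assert out.loc[0, "CG"] == 0.0

    def test_empty_bins_zero_when_grid_given(self):
        track = _uniform_track([10], 1.0)
        track["cov"] = 10
        track["mc"] = 10
        out = mc_density_bins(track, bin_size=400, chrom_sizes={"chr1": 1200})
        assert len(out) == 3
        assert out.loc[1, "CG"] == 0.0

    def test_peak_centered_window_arithmetic(self):
        rows = [("chr1", 995, "+", "CG", 10, 10), ("chr1", 1194, "+", "CG", 10, 10),
                ("chr1", 1195, "+", "CG", 10, 10), ("chr1", 794, "+", "CG", 10, 10),
                ("chr1", 795, "+", "CG", 10, 10)]
        track = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                            "context", "mc", "cov"])
        centers = _regions([("chr1", 900, 1090)])  # midpoint 995
        out = mc_density_bins(track, bin_size=400, mode="peak_centered",
                              centers=centers)
        # window [795, 1195): includes 795, 995, 1194; excludes 794, 1195
        assert out.loc[0, "window_start"] == 795
        assert out.loc[0, "CG"] == pytest.approx(300.0)

    def test_smoothed_chromosome_profile_runs(self, tiny_result):
        labels = {n: "all" for n in tiny_result.meth}
        track = pool_cluster(tiny_result.meth, labels)[("all", "all")]
        prof = smooth_chromosome_profile(track, "Chr1", "CG", 120_000)
        assert prof["methylation"].notna().any()


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        assert cohens_d([0, 1], [2, 3]) == pytest.approx(-2 / np.sqrt(0.5))

    def test_scale_invariance(self):
        a, b = [0.1, 0.4, 0.2], [0.5, 0.6, 0.7]
        assert cohens_d(a, b) == pytest.approx(
            cohens_d([10 * x for x in a], [10 * x for x in b]))

    def test_zero_spread_sentinels(self):
        assert cohens_d([1, 1], [1, 1]) == 0.0
        assert cohens_d([2, 2], [1, 1]) == np.inf
        assert cohens_d([0, 0], [1, 1]) == -np.inf

    def test_nan_dropped(self):
        assert cohens_d([0, 1, np.nan], [2, 3]) == pytest.approx(-2 / np.sqrt(0.5))

    @pytest.mark.parametrize("d,star", [
        (0.0, "n.e."), (0.19, "n.e."), (0.2, "*"), (-0.49, "*"), (0.5, "**"),
        (0.6, "**"), (-0.9, "***"), (-1.0, "***"), (1.49, "***"),
        (1.5, "****"), (np.inf, "****"),
    ])
    def test_star_boundaries(self, d, star):
        assert star_category(d) == star


class TestEffectGrid:
    def _means(self, rng):
        rows = []
        for i in range(40):
            geno = "WT" if i < 20 else "mut"
            shift = 0.0 if geno == "WT" else -0.3
            rows.append((f"n{i}", "rs", "CG", 0.8 + shift + rng.normal(0, 0.05), 30))
        return pd.DataFrame(rows, columns=["nucleus_id", "region_set",
                                           "context", "mean_methylation",
                                           "n_sites"])

    def test_pair_order_negates_d_keeps_p(self):
        rng = np.random.default_rng(0)
        means = self._means(rng)
        labels = {f"n{i}": "C1" for i in range(40)}
        genos = {f"n{i}": ("WT" if i < 20 else "mut") for i in range(40)}
        g1 = effect_grid(means, labels, genos, [("WT", "mut")])
        g2 = effect_grid(means, labels, genos, [("mut", "WT")])
        assert g1.iloc[0]["cohens_d"] == pytest.approx(-g2.iloc[0]["cohens_d"])
        assert g1.iloc[0]["t_pvalue"] == pytest.approx(g2.iloc[0]["t_pvalue"])

    def test_permuted_genotypes_give_null_effects(self):
        rng = np.random.default_rng(3)
        means = self._means(rng)
        labels = {f"n{i}": "C1" for i in range(40)}
        ds = []
        genos_base = ["WT"] * 20 + ["mut"] * 20
        for _ in range(30):
            perm = rng.permutation(genos_base)
            genos = {f"n{i}": perm[i] for i in range(40)}
            ds.append(effect_grid(means, labels, genos, [("WT", "mut")])
                      .iloc[0]["cohens_d"])
        assert abs(np.median(ds)) < 0.15

    def test_insufficient_group_marked(self):
        means = pd.DataFrame({
            "nucleus_id": ["n1", "n2", "n3"], "region_set": "rs",
            "context": "CG", "mean_methylation": [0.5, 0.6, 0.7], "n_sites": 5})
        labels = {"n1": "C", "n2": "C", "n3": "C"}
        genos = {"n1": "WT", "n2": "WT", "n3": "mut"}
        g = effect_grid(means, labels, genos, [("WT", "mut")])
        assert g.iloc[0]["star"] == "insufficient"

    def test_region_means_table_matches_single_region_op(self, tiny_result):
        rs = tiny_result.regions["cg_hypo_dmr"]
        table = region_means_table(tiny_result.meth, {"cg_hypo_dmr": rs},
                                   contexts=("CG",)).set_index("nucleus_id")
        for nid in list(tiny_result.meth)[:5]:
            expect = region_mean_per_nucleus(tiny_result.meth[nid], rs, "CG")
            got = table.loc[nid, "mean_methylation"]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect)
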