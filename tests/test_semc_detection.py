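import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import semseason as ss
from semseason.io_formats import GenomeAnnotation
from semseason.semc_detection import (correlation_distance, gtest_statistic,
                                      pairwise_min_fisher, sidak_adjust)
from helpers import fisher_two_sided_exact

C40_20 = 137846528820  # C(40, 20)


class TestFisherExact:
    def test_identical_proportions(self):
        assert ss.fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_fully_separated_table(self):
        assert ss.fisher_exact_2x2([[10, 0], [0, 10]]) == \
            pytest.approx(2 / 184756, rel=1e-9)

    def test_degenerate_margins(self):
        assert ss.fisher_exact_2x2([[0, 0], [3, 7]]) == 1.0
        assert ss.fisher_exact_2x2([[0, 5], [0, 9]]) == 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ss.fisher_exact_2x2([[1, -1], [2, 3]])

    def test_against_scipy_random_tables(self):
        rng = np.random.default_rng(1)
        tabs = rng.integers(0, 40, size=(300, 4))
        mine = ss.semc_detection.fisher_exact_many(*tabs.T)
        ref = np.array([scipy.stats.fisher_exact(t.reshape(2, 2)).pvalue
                        for t in tabs])
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15))
    def test_against_exact_enumeration(self, a, b, c, d):
        assert ss.fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_two_sided_exact(a, b, c, d), abs=1e-12)


class TestSiteStatistic:
    def test_constant_counts_give_p_one(self):
        p, n = ss.site_statistic(np.array([[10, 10]] * 8))
        assert p == 1.0 and n == 28

    def test_one_extreme_date(self):
        # 7 dates fully unmethylated at depth 20, one fully methylated:
        # the best pair is [[0,20],[20,0]], two-sided p = 2 / C(40,20)
        counts = np.array([[0, 20]] * 7 + [[20, 0]])
        p, n = ss.site_statistic(counts)
        assert p == pytest.approx(2 / C40_20, rel=1e-9)
        assert n == 28

    def test_coverage_filter_skips_pairs(self):
        counts = np.array([[2, 1]] + [[10, 10]] * 7)  # first date total 3
        p, n = ss.site_statistic(counts, min_cov=5)
        assert n == 21  # the 7 pairs involving the shallow date are skipped
        assert p == 1.0

    def test_no_testable_pair_is_excluded_not_p_one(self):
        counts = np.array([[1, 1]] * 8)
        p, n = ss.site_statistic(counts, min_cov=5)
        assert np.isnan(p) and n == 0

    def test_t2_reduces_to_single_fisher(self):
        counts = np.array([[3, 17], [12, 8]])
        p, n = ss.site_statistic(counts)
        assert n == 1
        assert p == pytest.approx(ss.fisher_exact_2x2(counts), rel=1e-12)


class TestStoreyQvalues:
    def test_all_ones(self):
        q, pi0 = ss.storey_qvalues(np.ones(200))
        assert pi0 == 1.0
        assert (q == 1.0).all()

    def test_single_small_p(self):
        # with fewer than 50 values pi0 is held at 1, so q = p for m = 1
        q, pi0 = ss.storey_qvalues([0.01])
        assert pi0 == 1.0 and q[0] == pytest.approx(0.01)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(0)
        q, pi0 = ss.storey_qvalues(rng.uniform(size=20_000))
        assert pi0 > 0.9
        assert (q > 0.5).mean() > 0.9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.storey_qvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=200))
    def test_monotone_in_p(self, ps):
        q, _ = ss.storey_qvalues(np.array(ps))
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_sidak_adjustment_edges(self):
        p = np.array([0.0, 1.0, 0.01])
        k = np.array([28, 28, 1])
        adj = sidak_adjust(p, k)
        assert adj[0] == 0.0 and adj[1] == 1.0
        assert adj[2] == pytest.approx(0.01)


class TestClassifyPeak:
    def test_unique_maximum(self):
        ratios = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.65]
        peak, month, tie = ss.classify_peak(ratios, list(ss.STUDY_DATES))
        assert peak == "2015-07-28" and month == "Jul" and not tie

    def test_tie_goes_to_earliest_and_is_flagged(self):
        ratios = [0.1, 0.1, 0.9, 0.1, 0.1, 0.1, 0.9, 0.1]
        peak, _, tie = ss.classify_peak(ratios, list(ss.STUDY_DATES))
        assert peak == "2015-02-09" and tie

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            ss.classify_peak([np.nan] * 8, list(ss.STUDY_DATES))


def _annotation_with_overlap():
    genes = pd.DataFrame([("gA", "chr_test", 0, 100, "+")],
                         columns=["gene_id", "seq_id", "start", "end",
                                  "strand"])
    exons = pd.DataFrame([("gA", "chr_test", 0, 40)],
                         columns=["gene_id", "seq_id", "start", "end"])
    reps = pd.DataFrame(columns=["repeat_id", "seq_id", "start", "end",
                                 "family", "strand"])
    return GenomeAnnotation({"chr_test": 100_000}, genes, exons, reps)


class TestDetectSemcs:
    def _series(self, seed=0, n=400):
        series, truth = ss.simulate_series(n_sites=n, semc_fraction=0.05,
                                           amplitude=0.5, coverage_mean=30.0,
                                           seed=seed)
        return series, truth

    def test_planted_strong_site_is_called(self, series_factory):
        meth = np.full((300, 8), 9)
        total = np.full((300, 8), 18)
        meth[0] = [0, 0, 0, 18, 18, 0, 0, 0]  # one extreme seasonal site
        series = series_factory(meth, total)
        calls = ss.detect_semcs(series, None)
        strong = calls[calls["pos"] == 0].iloc[0]
        assert bool(strong["is_semc"])
        assert strong["p_min"] < 1e-6

    def test_input_order_invariance(self):
        series, _ = self._series()
        perm = np.random.default_rng(5).permutation(series.n_sites)
        shuffled = series.subset(perm)
        a = ss.detect_semcs(series, None)
        b = ss.detect_semcs(shuffled, None)
        pd.testing.assert_frame_equal(a, b)

    def test_location_precedence_exon_over_intron(self):
        sites = pd.DataFrame({"seq_id": "chr_test", "pos": [10, 50, 500],
                              "strand": "+", "context": "CG"})
        series = ss.MethylomeSeries(sites, np.full((3, 8), 5),
                                    np.full((3, 8), 10),
                                    list(ss.STUDY_DATES))
        calls = ss.detect_semcs(series, _annotation_with_overlap())
        by_pos = calls.set_index("pos")["location"]
        assert by_pos[10] == "exon"    # inside exon [0, 40) of gene [0, 100)
        assert by_pos[50] == "intron"  # in the gene but outside its exon
        assert by_pos[500] == "intergenic"

    def test_semc_requires_both_thresholds(self):
        series, _ = self._series(seed=3, n=1000)
        calls = ss.detect_semcs(series, None, sidak=True)
        called = calls[calls["is_semc"]]
        assert (called["p_stat"] < 0.001).all()
        assert (called["q"] < 0.2).all()

    def test_gtest_mode_flags_strong_sites(self, series_factory):
        meth = np.full((100, 8), 9)
        total = np.full((100, 8), 18)
        meth[0] = [0, 0, 0, 18, 18, 0, 0, 0]
        series = series_factory(meth, total)
        calls = ss.detect_semcs(series, None, method="gtest")
        assert bool(calls[calls["pos"] == 0].iloc[0]["is_semc"])
        p0 = gtest_statistic(series.meth, series.total)[0][0]
        assert p0 < 1e-10


class TestClusterSemcs:
    def _calls(self, rows):
        rows = np.asarray(rows, dtype=float)
        df = pd.DataFrame({
            "seq_id": "chr_test", "pos": np.arange(len(rows)) * 10,
            "strand": "+",
        })
        for t, d in enumerate(ss.STUDY_DATES):
            df[f"ratio_{d}"] = rows[:, t]
        return df

    def test_identical_rows_merge_first_at_distance_zero(self):
        base = np.linspace(0.1, 0.9, 8)
        calls = self._calls([base, base, 1.0 - base])
        _, newick, Z = ss.cluster_semcs(calls, list(ss.STUDY_DATES))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_row_merges_last_at_distance_two(self):
        base = np.linspace(0.1, 0.9, 8)
        calls = self._calls([base, base, 1.0 - base])
        _, _, Z = ss.cluster_semcs(calls, list(ss.STUDY_DATES))
        assert Z[-1, 2] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_row_at_distance_one(self):
        rows = np.vstack([np.linspace(0, 1, 8), np.full(8, 0.5)])
        d = correlation_distance(rows)
        assert d[0] == 1.0

    def test_newick_has_all_leaves(self):
        import dendropy

        rng = np.random.default_rng(2)
        calls = self._calls(rng.uniform(size=(6, 8)))
        _, newick, _ = ss.cluster_semcs(calls, list(ss.STUDY_DATES))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == 6

    def test_fewer_than_two_calls_rejected(self):
        calls = self._calls([np.linspace(0, 1, 8)])
        with pytest.raises(ValueError, match="at least 2"):
            ss.cluster_semcs(calls, list(ss.STUDY_DATES))


class TestLocationBreakdown:
    def _calls(self, locations, context="CHH"):
        return pd.DataFrame({"context": context, "location": locations})

    def test_all_intergenic(self):
        props = ss.location_breakdown(self._calls(["intergenic"] * 4))
        row = props.iloc[0]
        assert row["intergenic"] == 1.0 and row["exon"] == 0.0

    def test_half_exon_half_intron(self):
        props = ss.location_breakdown(
            self._calls(["exon", "exon", "intron", "intron"]))
        row = props.iloc[0]
        assert row["exon"] == 0.5 and row["intron"] == 0.5 \
            and row["intergenic"] == 0.0

    def test_proportions_sum_to_one_per_context(self, small_sim):
        calls = ss.detect_semcs(
            small_sim["series"].for_sequences(
                [small_sim["cfg"].spike_in_name], invert=True),
            small_sim["annotation"])
        semcs = calls[calls["is_semc"]]
        props = ss.location_breakdown(semcs)
        sums = props[["exon", "intron", "intergenic"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_planted_intergenic_repeat_semcs_located_intergenic(
            self, small_sim):
        import dataclasses

        cfg = dataclasses.replace(
            small_sim["cfg"], semc_fraction=1.0, semc_contexts=("CHH",),
            semc_placement="repeat_intergenic", semc_amplitude=0.5,
            coverage_mean=30.0)
        reports, truth = ss.simulate_methylome(cfg, small_sim["genome"],
                                               small_sim["annotation"])
        series = ss.truth_series(truth, reports).for_sequences(
            [cfg.spike_in_name], invert=True)
        calls = ss.detect_semcs(series, small_sim["annotation"])
        chh = calls[(calls["context"] == "CHH") & calls["is_semc"]]
        props = ss.location_breakdown(chh).set_index("context")
        assert props.loc["CHH", "intergenic"] > 0.95
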