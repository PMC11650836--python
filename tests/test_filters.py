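"""filter_engine: presets, custom filters, runs, BH correction, bin z-test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

import exoncnv as x
from conftest import make_bin, make_ref_stats, random_annotated_fixture
from oracles import bh_stepup_oracle, normal_sf_oracle, runs_oracle


class TestAnnotate:
    def test_frequencies_copied_from_reference(self):
        ref = x.ExonReference([make_ref_stats(gene="G", exon_index=1, hom_del_freq=0.2)])
        recs = [x.CnrRecord("chr1", 100, 150, "G_1", 200.0, 0.0, 1.0)]
        (b,) = x.annotate_frequencies(recs, ref)
        assert b.hom_del_freq == pytest.approx(0.2)
        assert b.exon_index == 1 and b.gene == "G"

    def test_unknown_exon_retained_with_missing_frequencies(self):
        ref = x.ExonReference([make_ref_stats(gene="OTHER")])
        recs = [x.CnrRecord("chr1", 100, 150, "G_1", 200.0, 0.0, 1.0)]
        (b,) = x.annotate_frequencies(recs, ref)
        assert b.het_del_freq is None and b.hom_del_freq is None and b.dup_freq is None

    @pytest.mark.parametrize("log2,expected", [(-0.7, True), (-0.6, False), (-0.65, False)])
    def test_grid_highlight_threshold(self, log2, expected):
        recs = [x.CnrRecord("chr1", 100, 150, "G_1", 200.0, log2, 1.0)]
        (b,) = x.annotate_frequencies(recs)
        assert b.highlight is expected

    def test_row_order_preserved(self):
        recs = [x.CnrRecord("chr1", s, s + 50, "G_1", 10, 0.0, 1.0) for s in (900, 100, 500)]
        bins = x.annotate_frequencies(recs)
        assert [b.start for b in bins] == [900, 100, 500]
        assert [b.exon_index for b in bins] == [3, 1, 2]


class TestCustomFilters:
    def bins(self):
        return [
            make_bin(gene="A", start=100, end=200, depth=10.0, log2=-0.5, exon_index=1,
                     hom_del_freq=0.2, het_del_freq=0.0, dup_freq=0.0),
            make_bin(gene="B", start=5000, end=5100, depth=25.0, log2=0.7, exon_index=1,
                     hom_del_freq=0.0, het_del_freq=0.0, dup_freq=0.0),
            make_bin(gene="C", start=9000, end=9100, depth=40.0, log2=0.0, exon_index=1),
        ]

    def test_min_depth(self):
        out = x.apply_custom_filters(self.bins(), x.FilterConfig(min_depth=20))
        assert [b.gene for b in out] == ["B", "C"]

    def test_all_unset_is_identity(self):
        bins = self.bins()
        assert x.apply_custom_filters(bins, x.FilterConfig()) == bins

    def test_max_inhouse_freq_missing_passes(self):
        out = x.apply_custom_filters(self.bins(), x.FilterConfig(max_inhouse_freq=0.05))
        assert [b.gene for b in out] == ["B", "C"]

    def test_region_overlap_half_open(self):
        cfg = x.FilterConfig(region="chr1:5001-5050")
        out = x.apply_custom_filters(self.bins(), cfg)
        assert [b.gene for b in out] == ["B"]
        # interval beyond every bin
        assert x.apply_custom_filters(self.bins(), x.FilterConfig(region="chr1:20000-30000")) == []

    def test_gene_membership_case_insensitive(self):
        out = x.apply_custom_filters(self.bins(), x.FilterConfig(genes={"a", "C"}))
        assert [b.gene for b in out] == ["A", "C"]

    def test_copy_number_and_abs_log2(self):
        out = x.apply_custom_filters(self.bins(), x.FilterConfig(copy_numbers={3}))
        assert [b.gene for b in out] == ["B"]
        out = x.apply_custom_filters(self.bins(), x.FilterConfig(min_abs_log2=0.4))
        assert [b.gene for b in out] == ["A", "B"]

    def test_malformed_region_is_config_error(self):
        with pytest.raises(x.ConfigError):
            x.apply_custom_filters(self.bins(), x.FilterConfig(region="chr1:9-1"))

    def test_conjunction_is_order_independent(self):
        rng = np.random.default_rng(5)
        bins = random_annotated_fixture(rng, n_genes=3)
        single = {
            "depth": x.FilterConfig(min_depth=50),
            "log2": x.FilterConfig(min_abs_log2=0.3),
            "gene": x.FilterConfig(genes={"G0", "G2"}),
        }
        combined = x.FilterConfig(min_depth=50, min_abs_log2=0.3, genes={"G0", "G2"})
        expected = {id(b) for b in x.apply_custom_filters(bins, combined)}
        for order in itertools.permutations(single.values()):
            out = bins
            for cfg in order:
                out = x.apply_custom_filters(out, cfg)
            assert {id(b) for b in out} == expected


class TestConsecutiveRuns:
    def gene_bins(self, quals, gene="G"):
        """Bins with exon i deleted when quals[i-1] is truthy."""
        return [
            make_bin(gene=gene, start=1000 * i, end=1000 * i + 100, exon_index=i,
                     log2=-1.0 if q else 0.0)
            for i, q in enumerate(quals, start=1)
        ]

    def test_single_run_spanning_three_exons(self):
        bins = self.gene_bins([0, 0, 1, 1, 1, 0])
        runs = x.find_consecutive_runs(bins, "deletion", min_run=2)
        assert len(runs) == 1
        assert (runs[0].exon_from, runs[0].exon_to, runs[0].length) == (3, 5, 3)

    def test_gap_breaks_run(self):
        bins = self.gene_bins([0, 0, 1, 0, 1])
        assert x.find_consecutive_runs(bins, "deletion", min_run=2) == []

    def test_min_run_one_equals_plain_filter(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            bins = random_annotated_fixture(rng)
            runs = x.find_consecutive_runs(bins, "deletion", min_run=1)
            th = x.Thresholds()
            flat = sorted(id(b) for r in runs for b in r.bins)
            plain = sorted(id(b) for b in bins if b.log2 < th.het_del_log2)
            assert flat == plain

    def test_runs_never_span_genes(self):
        bins = self.gene_bins([1, 1], gene="A") + self.gene_bins([1, 1], gene="B")
        runs = x.find_consecutive_runs(bins, "deletion", min_run=2)
        assert sorted(r.gene for r in runs) == ["A", "B"]

    @pytest.mark.parametrize("min_run", [1, 2, 3, 4])
    def test_matches_exhaustive_window_enumeration(self, min_run):
        rng = np.random.default_rng(23)
        th = x.Thresholds()
        for direction, pred in (
            ("deletion", lambda b: b.log2 < th.het_del_log2),
            ("amplification", lambda b: b.log2 > th.dup_log2),
        ):
            for _ in range(25):
                bins = random_annotated_fixture(rng, n_genes=1, max_exons=12)
                assert len(bins) <= 50
                got = x.find_consecutive_runs(bins, direction, min_run=min_run)
                expected = runs_oracle(bins, pred, min_run)
                assert [[b.exon_index for b in r.bins] for r in got] == [
                    [b.exon_index for b in w] for w in expected
                ]

    def test_invalid_min_run(self):
        with pytest.raises(x.ConfigError):
            x.find_consecutive_runs([], "deletion", min_run=0)


class TestBhAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([], []),
    ])
    def test_worked_examples(self, pvals, expected):
        assert x.bh_adjust(pvals) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            x.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            x.bh_adjust([-0.1])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50))
    def test_properties_vs_oracle_and_statsmodels(self, pvals):
        adjusted = x.bh_adjust(pvals)
        assert adjusted == pytest.approx(bh_stepup_oracle(pvals), abs=1e-12)
        sm = multipletests(pvals, method="fdr_bh")[1]
        assert adjusted == pytest.approx(list(sm), abs=1e-12)
        assert all(a >= p - 1e-15 for a, p in zip(adjusted, pvals))

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = x.bh_adjust(pvals)
        permuted = x.bh_adjust([pvals[i] for i in perm])
        assert permuted == pytest.approx([base[i] for i in perm], abs=1e-12)


class TestRecomputeBintest:
    def reference(self, sd=0.25):
        return x.ExonReference([make_ref_stats(gene="G", exon_index=1, mean_log2=0.0, sd_log2=sd)])

    def test_bin_at_reference_mean_has_p_one(self):
        res = x.recompute_bintest([make_bin(gene="G", log2=0.0)], self.reference())
        assert res.tested[0].p_value == pytest.approx(1.0)
        assert res.significant == []

    def test_z_minus_four_two_sided_p(self):
        res = x.recompute_bintest([make_bin(gene="G", log2=-1.0)], self.reference(sd=0.25))
        expected = 2.0 * normal_sf_oracle(4.0)
        assert res.tested[0].p_value == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(6.33e-5, rel=1e-2)

    def test_all_at_mean_nothing_significant(self):
        bins = [make_bin(gene="G", start=100 * i, end=100 * i + 50, log2=0.0) for i in range(5)]
        res = x.recompute_bintest(bins, self.reference(), alpha=0.999)
        assert res.significant == []

    def test_unresolvable_bins_skipped_and_counted(self):
        bins = [make_bin(gene="G", log2=0.0), make_bin(gene="UNKNOWN", log2=0.0, start=5000, end=5100)]
        res = x.recompute_bintest(bins, self.reference())
        assert res.n_skipped == 1 and len(res.tested) == 1

    def test_empty_testable_set_is_content_error(self):
        with pytest.raises(x.ContentError):
            x.recompute_bintest([make_bin(gene="UNKNOWN")], self.reference())


class TestPresets:
    def setup_bins(self):
        cnr = [
            make_bin(gene="UBR4", start=100, end=200, exon_index=1, log2=0.0),
            make_bin(gene="UBR4", start=300, end=400, exon_index=2, log2=-1.5),
            make_bin(gene="FNTA", start=900, end=1000, exon_index=1, log2=0.6),
        ]
        bintest = [
            make_bin(gene="UBR4", start=300, end=400, exon_index=2, log2=-1.5, p_value=0.001),
            make_bin(gene="FNTA", start=900, end=1000, exon_index=1, log2=0.6, p_value=0.01),
        ]
        return cnr, bintest

    def test_total_is_identity(self):
        cnr, bintest = self.setup_bins()
        assert x.apply_preset(cnr, bintest, x.FilterConfig(preset="total")) == cnr

    def test_bintest_is_identity_on_bintest_input(self):
        cnr, bintest = self.setup_bins()
        assert x.apply_preset(cnr, bintest, x.FilterConfig(preset="bintest")) == bintest

    def test_homozygous_deletion_selects_single_bin(self):
        cnr, bintest = self.setup_bins()
        out = x.apply_preset(cnr, bintest, x.FilterConfig(preset="homozygous_deletion"))
        assert [(b.gene, b.exon_index) for b in out] == [("UBR4", 2)]

    def test_bintest_candidate_restricts_to_panel(self):
        cnr, bintest = self.setup_bins()
        panel = x.PanelGeneList("p", frozenset({"UBR4"}))
        out = x.apply_preset(cnr, bintest, x.FilterConfig(preset="bintest_candidate"), panel)
        assert {b.gene for b in out} == {"UBR4"}

    def test_candidate_preset_without_panel_is_config_error(self):
        cnr, bintest = self.setup_bins()
        with pytest.raises(x.ConfigError):
            x.apply_preset(cnr, bintest, x.FilterConfig(preset="total_candidate"))

    def test_consecutive_preset_returns_runs(self):
        bins = [make_bin(gene="G", start=1000 * i, end=1000 * i + 100, exon_index=i, log2=-1.0)
                for i in (1, 2, 3)]
        out = x.apply_preset(bins, None, x.FilterConfig(preset="consecutive_del", consecutive_cutoff=2))
        assert len(out) == 1 and out[0].length == 3

    def test_custom_filters_applied_after_preset(self):
        cnr, bintest = self.setup_bins()
        out = x.apply_preset(cnr, bintest, x.FilterConfig(preset="total", min_abs_log2=0.5))
        assert [(b.gene) for b in out] == ["UBR4", "FNTA"]

    def test_every_preset_output_is_subset_of_input(self):
        cnr, bintest = self.setup_bins()
        panel = x.PanelGeneList("p", frozenset({"UBR4", "FNTA"}))
        for preset in x.Preset:
            out = x.apply_preset(cnr, bintest, x.FilterConfig(preset=preset), panel)
            pool = {id(b) for b in cnr} | {id(b) for b in bintest}
            for item in out:
                bins = item.bins if isinstance(item, x.Run) else [item]
                assert all(id(b) in pool for b in bins)
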