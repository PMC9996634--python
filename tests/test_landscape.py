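"""Peak landscape operations: caller, reproducibility, bivalency,
feature annotation precedence, G-test, gene states.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from markscape import landscape as ls
from markscape.formats_io import (
    FEATURE_CLASSES,
    GeneModel,
    GenomeModel,
    make_peakset,
    make_tags,
)


def uniform_tags(rng, n, chrom_len, chrom="chr1"):
    pos = rng.integers(0, chrom_len - 60, size=n)
    return make_tags([(chrom, int(p), int(p) + 50, "+") for p in pos])


class TestStandinCaller:
    GENOME = GenomeModel(chroms={"chr1": 100_000})

    def test_enriched_window_called_against_sparse_background(self):
        rng = np.random.default_rng(0)
        control = uniform_tags(rng, 100, 100_000)  # 1 tag / kb
        background = uniform_tags(rng, 100, 100_000)
        spike = make_tags(
            [("chr1", int(p), int(p) + 50, "+")
             for p in rng.integers(50_000, 50_150, size=50)]
        )
        treatment = make_tags(
            list(background.df.itertuples(index=False))
            + list(spike.df.itertuples(index=False))
        )
        # Poisson oracle: 50 tags in a 200-bp window vs lambda = 0.2
        assert stats.poisson.sf(49, 0.2) < 1e-5
        peaks = ls.standin_call_peaks(treatment, control, self.GENOME, "narrow")
        hit = peaks.df[(peaks.df["start"] < 50_200) & (peaks.df["end"] > 50_000)]
        assert len(hit) == 1

    def test_null_input_produces_almost_no_peaks(self):
        rng = np.random.default_rng(1)
        treatment = uniform_tags(rng, 5000, 100_000)
        control = uniform_tags(rng, 5000, 100_000)
        peaks = ls.standin_call_peaks(treatment, control, self.GENOME, "narrow")
        assert len(peaks) <= 2

    def test_empty_tags_give_empty_peakset(self):
        assert len(ls.standin_call_peaks(make_tags([]), None, self.GENOME, "narrow")) == 0

    def test_narrow_peaks_carry_summits_at_maximum(self):
        rng = np.random.default_rng(2)
        spike = make_tags(
            [("chr1", int(p), int(p) + 50, "+")
             for p in rng.normal(50_000, 40, size=300).astype(int)]
        )
        peaks = ls.standin_call_peaks(spike, None, self.GENOME, "narrow")
        assert len(peaks) >= 1
        row = peaks.df.iloc[0]
        summit_pos = row["start"] + row["summit"]
        assert abs(summit_pos - 50_025) < 100

    def test_fixture_truth_recovery(self, sim, analysis):
        """Reproducible called peaks recover the planted intervals."""
        from intervaltree import IntervalTree

        for mark in ("H3K4me3", "H3K27me3"):
            called = analysis["reproducible"][mark]
            truth = sim.truth_peaks[mark]
            trees = {}
            for row in truth.df.itertuples(index=False):
                trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
            matched = 0
            hit = set()
            for row in called.df.itertuples(index=False):
                ov = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
                if ov:
                    matched += 1
                for iv in ov:
                    hit.add((row.chrom, iv.begin, iv.end))
            precision = matched / len(called)
            recall = len(hit) / len(truth)
            assert precision >= 0.9, f"{mark} precision {precision:.3f}"
            assert recall >= 0.9, f"{mark} recall {recall:.3f}"


class TestReproduciblePeaks:
    def test_identical_sets_are_returned_unchanged(self):
        ps = make_peakset([("chr1", 0, 300, 5.0), ("chr1", 1000, 1400, 7.0)])
        out = ls.reproducible_peaks(ps, ps)
        assert out.df[["chrom", "start", "end", "score"]].equals(
            ps.df[["chrom", "start", "end", "score"]]
        )

    def test_disjoint_sets_give_empty_output(self):
        a = make_peakset([("chr1", 0, 300, 5.0)])
        b = make_peakset([("chr1", 1000, 1400, 7.0)])
        assert len(ls.reproducible_peaks(a, b)) == 0

    def test_overlapping_peaks_union_with_min_score(self):
        a = make_peakset([("chr1", 0, 300, 5.0)])
        b = make_peakset([("chr1", 200, 500, 7.0)])
        out = ls.reproducible_peaks(a, b)
        assert list(out.df[["start", "end", "score"]].iloc[0]) == [0, 500, 5.0]

    def test_min_overlap_respected(self):
        a = make_peakset([("chr1", 0, 300, 5.0)])
        b = make_peakset([("chr1", 250, 500, 7.0)])
        assert len(ls.reproducible_peaks(a, b, min_overlap=100)) == 0
        assert len(ls.reproducible_peaks(a, b, min_overlap=50)) == 1


class TestDetectBivalent:
    @pytest.mark.parametrize(
        "k27_start, expected", [(100, 1), (101, 0), (99, 1)]
    )
    def test_hundred_bp_boundary(self, k27_start, expected):
        k4 = make_peakset([("chr1", 0, 200, 5.0)], mark="H3K4me3")
        k27 = make_peakset([("chr1", k27_start, 300, 3.0)], mark="H3K27me3", shape="broad")
        domains = ls.detect_bivalent(k4, k27, min_overlap=100)
        assert len(domains) == expected
        if expected:
            assert list(domains.df[["start", "end"]].iloc[0]) == [k27_start, 200]

    def test_symmetric_in_argument_order(self):
        a = make_peakset([("chr1", 0, 500, 5.0), ("chr1", 900, 1600, 2.0)])
        b = make_peakset([("chr1", 300, 1000, 3.0)], shape="broad")
        ab = ls.detect_bivalent(a, b)
        ba = ls.detect_bivalent(b, a)
        assert ab.df[["chrom", "start", "end"]].equals(ba.df[["chrom", "start", "end"]])

    def test_domain_is_the_intersection(self):
        k4 = make_peakset([("chr1", 0, 200, 5.0)])
        k27 = make_peakset([("chr1", 100, 300, 3.0)], shape="broad")
        domains = ls.detect_bivalent(k4, k27)
        assert list(domains.df[["start", "end"]].iloc[0]) == [100, 200]


class TestAnnotatePeaks:
    def test_point_upstream_of_tss_is_promoter(self, toy_genome):
        peaks = make_peakset([("chrA", 1400, 1600, 1.0, 100)])  # point 1500, TSS 2000
        ann = ls.annotate_peaks(peaks, toy_genome)
        assert ann.loc[0, "feature"] == "promoter"
        assert ann.loc[0, "nearest_gene"] == "gx"
        assert ann.loc[0, "tss_distance"] == -500

    def test_promoter_precedence_over_exon(self):
        # the point is inside geneA's exon but within 1 kb of geneB's TSS
        genome = GenomeModel(
            chroms={"chr1": 10_000},
            genes=[
                GeneModel(id="a", chrom="chr1", strand="+", start=1000, end=3000),
                GeneModel(id="b", chrom="chr1", strand="+", start=3500, end=5000),
            ],
        )
        peaks = make_peakset([("chr1", 2700, 2900, 1.0, 100)])  # point 2800
        ann = ls.annotate_peaks(peaks, genome)
        assert ann.loc[0, "feature"] == "promoter"

    def test_point_shortly_past_gene_end_is_downstream(self, toy_genome):
        # gx ends at 3000; 3150 is beyond the promoter window of nothing else
        peaks = make_peakset([("chrA", 3100, 3200, 1.0, 50)])
        ann = ls.annotate_peaks(peaks, toy_genome, promoter=100)
        assert ann.loc[0, "feature"] == "downstream"

    def test_far_point_is_intergenic(self, toy_genome):
        peaks = make_peakset([("chrB", 100, 200, 1.0, 50)])
        ann = ls.annotate_peaks(peaks, toy_genome)
        assert ann.loc[0, "feature"] == "intergenic"

    def test_minus_strand_distance_sign(self, toy_genome):
        # gy TSS at 7199 (minus strand); genomic 7400 is upstream in gene orientation
        peaks = make_peakset([("chrA", 7350, 7450, 1.0, 50)])
        ann = ls.annotate_peaks(peaks, toy_genome)
        assert ann.loc[0, "nearest_gene"] == "gy"
        assert ann.loc[0, "tss_distance"] == -201

    def test_every_point_gets_exactly_one_class(self, small_sim):
        rng = np.random.default_rng(3)
        genome = small_sim.genome
        records = []
        for chrom, length in genome.chroms.items():
            for pos in rng.integers(0, length - 1, size=200):
                records.append((chrom, int(pos), int(pos) + 1, 0.0, 0))
        ann = ls.annotate_peaks(make_peakset(records), genome)
        assert len(ann) == len(records)
        assert ann["feature"].isin(FEATURE_CLASSES).all()


class TestGTest:
    def test_observed_equal_expected_gives_zero(self):
        res = ls.gtest_features({"a": 30, "b": 70}, {"a": 0.3, "b": 0.7})
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_class_example_against_direct_evaluation(self):
        obs, props = [10, 90], [0.05, 0.95]
        total = sum(obs)
        oracle = 2 * math.fsum(
            o * math.log(o / (total * p)) for o, p in zip(obs, props) if o
        )
        res = ls.gtest_features({"x": 10, "y": 90}, {"x": 0.05, "y": 0.95})
        assert res.g == pytest.approx(oracle, rel=1e-12)
        assert res.g == pytest.approx(4.1308, abs=5e-4)
        assert res.df == 1

    def test_doubling_counts_doubles_g(self):
        res1 = ls.gtest_features({"a": 10, "b": 40}, {"a": 0.5, "b": 0.5})
        res2 = ls.gtest_features({"a": 20, "b": 80}, {"a": 0.5, "b": 0.5})
        assert res2.g == pytest.approx(2 * res1.g, rel=1e-12)

    def test_zero_expected_with_nonzero_observed_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            ls.gtest_features({"a": 10, "b": 1}, {"a": 1.0, "b": 0.0})

    @settings(derandomize=True, max_examples=200)
    @given(
        obs=st.lists(st.integers(0, 1000), min_size=2, max_size=6),
        scale=st.integers(2, 20),
    )
    def test_scaling_counts_scales_g_linearly(self, obs, scale):
        if sum(obs) == 0:
            return
        labels = [f"c{i}" for i in range(len(obs))]
        props = {c: 1 / len(obs) for c in labels}
        g1 = ls.gtest_features(dict(zip(labels, obs)), props).g
        g2 = ls.gtest_features(dict(zip(labels, [scale * o for o in obs])), props).g
        assert g2 == pytest.approx(scale * g1, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        k4_start=st.integers(0, 5000),
        k4_len=st.integers(1, 3000),
        k27_start=st.integers(0, 5000),
        k27_len=st.integers(1, 3000),
        min_overlap=st.integers(1, 500),
    )
    def test_bivalent_symmetry_and_overlap_bound(
        self, k4_start, k4_len, k27_start, k27_len, min_overlap
    ):
        a = make_peakset([("chr1", k4_start, k4_start + k4_len, 1.0)])
        b = make_peakset(
            [("chr1", k27_start, k27_start + k27_len, 2.0)], shape="broad"
        )
        ab = ls.detect_bivalent(a, b, min_overlap=min_overlap)
        ba = ls.detect_bivalent(b, a, min_overlap=min_overlap)
        assert ab.df[["start", "end"]].equals(ba.df[["start", "end"]])
        true_overlap = min(k4_start + k4_len, k27_start + k27_len) - max(
            k4_start, k27_start
        )
        assert len(ab) == (1 if true_overlap >= min_overlap else 0)

    def test_independence_matches_scipy_oracle(self):
        table = np.array([[15, 5], [400, 580]])
        ours = ls.gtest_independence(table)
        g_ref, p_ref, df_ref, _ = stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        assert ours.g == pytest.approx(g_ref, rel=1e-12)
        assert ours.p == pytest.approx(p_ref, rel=1e-9)
        assert ours.df == df_ref


class TestAssignGeneStates:
    def _genome(self):
        return GenomeModel(
            chroms={"chr1": 30_000},
            genes=[
                GeneModel(id="active", chrom="chr1", strand="+", start=2000, end=5000),
                GeneModel(id="poised", chrom="chr1", strand="+", start=12_000, end=15_000),
                GeneModel(id="body", chrom="chr1", strand="+", start=22_000, end=28_000),
            ],
        )

    def test_states_follow_peak_configuration(self):
        genome = self._genome()
        k4 = make_peakset(
            [("chr1", 1500, 2500, 5.0), ("chr1", 11_500, 12_500, 5.0)], mark="H3K4me3"
        )
        k27 = make_peakset(
            [("chr1", 11_800, 13_000, 3.0), ("chr1", 24_000, 26_000, 3.0)],
            mark="H3K27me3", shape="broad",
        )
        biv = ls.detect_bivalent(k4, k27)
        states = ls.assign_gene_states(k4, k27, biv, genome)
        assert states.loc["active", "state"] == ls.GeneState.H3K4ME3_ONLY_TSS.value
        assert states.loc["poised", "state"] == ls.GeneState.BIVALENT_TSS.value
        assert states.loc["body", "state"] == ls.GeneState.H3K27ME3_GENE_BODY.value

    def test_k27_at_tss_without_k4(self):
        genome = self._genome()
        k4 = make_peakset([], mark="H3K4me3")
        k27 = make_peakset([("chr1", 1500, 2500, 3.0)], mark="H3K27me3", shape="broad")
        states = ls.assign_gene_states(k4, k27, make_peakset([]), genome)
        assert states.loc["active", "state"] == ls.GeneState.H3K27ME3_ONLY_TSS.value

    def test_no_peaks_means_unmarked(self):
        genome = self._genome()
        empty = make_peakset([])
        states = ls.assign_gene_states(empty, empty, empty, genome)
        assert (states["state"] == ls.GeneState.UNMARKED.value).all()

    def test_fixture_state_recovery(self, sim, analysis):
        states = analysis["states"]
        agreement = (states["state"] == sim.truth["state"]).mean()
        assert agreement >= 0.9
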