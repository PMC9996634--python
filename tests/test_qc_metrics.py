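"""ENCODE QC panel: hand-counted ratios, cross-correlation geometry,
FRiP partition property, gate boundary semantics.
"""

import math

import numpy as np
import pytest

from markscape import qc_metrics as qc
from markscape.formats_io import GenomeModel, make_peakset, make_tags


def tags_at(positions, strand="+", length=50, chrom="chr1"):
    return make_tags(
        [(chrom, p, p + length, strand) if strand == "+" else (chrom, p - length + 1, p + 1, strand)
         for p in positions]
    )


class TestLibraryComplexity:
    def test_all_distinct(self):
        nrf, pbc1, pbc2 = qc.library_complexity(tags_at(range(0, 1000, 100)))
        assert (nrf, pbc1, pbc2) == (1.0, 1.0, math.inf)

    def test_four_at_one_position_one_at_another(self):
        # 5 tags, 2 distinct positions, one singleton, no doubleton
        nrf, pbc1, pbc2 = qc.library_complexity(tags_at([100] * 4 + [500]))
        assert nrf == pytest.approx(2 / 5)
        assert pbc1 == pytest.approx(1 / 2)
        assert pbc2 == math.inf

    def test_singleton_and_doubleton(self):
        nrf, pbc1, pbc2 = qc.library_complexity(tags_at([100, 500, 500]))
        assert nrf == pytest.approx(2 / 3)
        assert pbc1 == pytest.approx(1 / 2)
        assert pbc2 == pytest.approx(1.0)

    def test_same_position_opposite_strands_distinct(self):
        plus = tags_at([100], "+")
        minus = tags_at([100], "-")
        both = make_tags(
            list(plus.df.itertuples(index=False)) + list(minus.df.itertuples(index=False))
        )
        nrf, _, _ = qc.library_complexity(both)
        assert nrf == 1.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            qc.library_complexity(make_tags([]))

    def test_nrf_monotone_under_subsampling(self, small_sim):
        tags = small_sim.tags[("H3K4me3", 1)]
        rng = np.random.default_rng(0)
        full = tags.df
        prev_distinct = None
        for n in (len(full), len(full) // 2, len(full) // 4):
            sub = type(tags)(full.iloc[rng.choice(len(full), size=n, replace=False)])
            key = sub.df.assign(pos=sub.five_prime())[["chrom", "pos", "strand"]]
            distinct = len(key.value_counts())
            if prev_distinct is not None:
                assert distinct <= prev_distinct
            prev_distinct = distinct


class TestCrossCorrelation:
    def _paired(self, rng, n=4000, frag=200, chrom_len=1_000_000):
        starts = rng.integers(1000, chrom_len - 1000, size=n)
        plus = [("chr1", int(s), int(s) + 50, "+") for s in starts]
        minus = [("chr1", int(s) + frag - 50, int(s) + frag, "-") for s in starts]
        return make_tags(plus + minus)

    def test_recovers_constructed_fragment_length(self):
        tags = self._paired(np.random.default_rng(1))
        _, frag_len, nsc, rsc = qc.cross_correlation(tags, range(0, 400, 10))
        assert abs(frag_len - 200) <= 10
        assert nsc > 1.05 and rsc > 0.8

    def test_uniform_tags_show_no_clustering(self):
        # without fragment clustering the whole curve stays at the noise
        # level and no shift stands out
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 1_000_000, size=40_000)
        strand = rng.random(40_000) < 0.5
        tags = make_tags(
            [("chr1", int(p), int(p) + 50, "+" if s else "-") for p, s in zip(pos, strand)]
        )
        curve, _, _, _ = qc.cross_correlation(tags)
        assert curve["cc"].abs().max() < 0.02

    def test_single_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            qc.cross_correlation(tags_at(range(0, 5000, 50)))

    def test_invariant_to_relabeling_and_translation(self):
        rng = np.random.default_rng(3)
        tags = self._paired(rng, n=2000)
        curve1, fl1, _, _ = qc.cross_correlation(tags, range(0, 300, 10))
        moved = tags.df.copy()
        moved["chrom"] = "chrOther"
        moved["start"] += 7000
        moved["end"] += 7000
        curve2, fl2, _, _ = qc.cross_correlation(type(tags)(moved), range(0, 300, 10))
        assert fl1 == fl2
        np.testing.assert_allclose(curve1["cc"], curve2["cc"], rtol=1e-2, atol=1e-3)


class TestFrip:
    def test_all_midpoints_inside(self):
        tags = tags_at([100, 150, 200])
        peaks = make_peakset([("chr1", 0, 1000, 5.0)])
        assert qc.frip(tags, peaks) == 1.0

    def test_no_overlap(self):
        tags = tags_at([100])
        peaks = make_peakset([("chr1", 5000, 6000, 5.0)])
        assert qc.frip(tags, peaks) == 0.0

    def test_hand_counted_fraction(self):
        # midpoints p+25 = 25, 125, ..., 1125: exactly 3 of 12 lie in [0, 300)
        tags = tags_at(range(0, 1200, 100))
        peaks = make_peakset([("chr1", 0, 300, 5.0)])
        assert qc.frip(tags, peaks) == pytest.approx(3 / 12)

    def test_empty_peaks_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert qc.frip(tags_at([100]), make_peakset([])) == 0.0
        assert any("empty peak set" in r.message for r in caplog.records)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(4)
        tags = tags_at(rng.integers(0, 9_900, size=500))
        peaks = make_peakset([("chr1", 0, 3000, 1.0), ("chr1", 5000, 7000, 1.0)])
        complement = make_peakset(
            [("chr1", 3000, 5000, 1.0), ("chr1", 7000, 10_000, 1.0)]
        )
        assert qc.frip(tags, peaks) + qc.frip(tags, complement) == pytest.approx(1.0)


class TestReplicateCorrelation:
    GENOME = GenomeModel(chroms={"chr1": 100_000})

    def test_identical_collections_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        tags = tags_at(rng.integers(0, 99_000, size=2000))
        pcc, scc = qc.replicate_correlation(tags, tags, self.GENOME)
        assert pcc == pytest.approx(1.0)
        assert scc == pytest.approx(1.0)

    def test_shuffled_bins_decorrelate(self):
        rng = np.random.default_rng(6)
        a = tags_at(rng.integers(0, 50_000, size=3000))
        b = tags_at(rng.integers(50_000, 99_000, size=3000))
        pcc, _ = qc.replicate_correlation(a, b, self.GENOME)
        assert pcc < 1.0

    def test_zero_variance_flagged_nan(self, caplog):
        a = tags_at([100])
        with caplog.at_level("WARNING"):
            pcc, scc = qc.replicate_correlation(a, a, self.GENOME, bin=200_000)
        assert math.isnan(pcc) and math.isnan(scc)

    def test_replicates_of_same_truth_correlate(self, small_sim):
        pcc, _ = qc.replicate_correlation(
            small_sim.tags[("H3K4me3", 1)],
            small_sim.tags[("H3K4me3", 2)],
            small_sim.genome,
        )
        assert pcc > 0.8


class TestQcGate:
    def test_nrf_below_threshold_fails(self):
        report = qc.QcReport(nrf=0.79)
        assert qc.qc_gate(report)["nrf"] is False

    def test_boundary_semantics_at_least_vs_higher_than(self):
        report = qc.QcReport(nrf=0.8, pbc1=0.5, pbc2=1.0, nsc=1.05, rsc=0.8, frip=0.01)
        flags = qc.qc_gate(report)
        assert flags["nrf"] is True  # "at least"
        assert flags["frip"] is True  # "at least"
        assert flags["pbc1"] is False  # "higher than"
        assert flags["pbc2"] is False
        assert flags["nsc"] is False
        assert flags["rsc"] is False

    def test_strong_frip_passes(self):
        assert qc.qc_gate(qc.QcReport(frip=0.611))["frip"] is True

    def test_infinite_pbc2_passes(self):
        assert qc.qc_gate(qc.QcReport(pbc2=math.inf))["pbc2"] is True

    def test_threshold_override(self):
        assert qc.qc_gate(qc.QcReport(nrf=0.7), {"nrf": 0.6})["nrf"] is True
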