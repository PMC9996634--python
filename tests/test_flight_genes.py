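"""Candidate-list enrichment, direction concordance, motif input prep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markscape import flight_genes as fg
from markscape.formats_io import GeneModel, GenomeModel, make_peakset
from markscape.landscape import GeneState


def _states(n_marked, n_unmarked):
    rows = []
    for i in range(n_marked + n_unmarked):
        marked = i < n_marked
        rows.append(
            {
                "gene": f"g{i}",
                "state": GeneState.H3K4ME3_ONLY_TSS.value if marked else GeneState.UNMARKED.value,
                "k4_tss": marked,
                "k27_tss": False,
                "bivalent_tss": False,
                "k27_body": False,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _genome(n):
    genes = [
        GeneModel(id=f"g{i}", chrom="chr1", strand="+", start=1000 * i + 10, end=1000 * i + 900)
        for i in range(n)
    ]
    return GenomeModel(chroms={"chr1": 1000 * n + 1000}, genes=genes)


class TestCategoryEnrichment:
    def test_marked_only_list_is_positively_enriched(self):
        states = _states(50, 50)
        lst = fg.CandidateGeneList("test", tuple(f"g{i}" for i in range(10)))
        overlap, res, direction = fg.category_enrichment(states, lst, _genome(100))
        assert overlap == 10
        assert res.g > 0
        assert direction > 0

    def test_list_matching_genome_proportion_gives_zero_g(self):
        states = _states(50, 50)
        # 5 marked + 5 unmarked = exactly the genome-wide 50% marked rate
        lst = fg.CandidateGeneList(
            "balanced", tuple(f"g{i}" for i in list(range(5)) + list(range(50, 55)))
        )
        _, res, direction = fg.category_enrichment(states, lst, _genome(100))
        assert res.g == pytest.approx(0.0, abs=1e-9)
        assert direction == pytest.approx(0.0)

    def test_contingency_table_matches_scipy_oracle(self):
        # 1000 genes: list of 20 (15 marked), rest 980 (400 marked)
        states = _states(415, 585)
        in_list = [f"g{i}" for i in range(15)] + [f"g{i}" for i in range(415, 420)]
        lst = fg.CandidateGeneList("wing", tuple(in_list))
        _, res, _ = fg.category_enrichment(states, lst, _genome(1000))
        table = np.array([[15, 5], [400, 580]])
        g_ref, p_ref, df_ref, _ = stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        assert res.g == pytest.approx(g_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_row_swap_leaves_g_unchanged(self):
        from markscape.landscape import gtest_independence

        table = np.array([[15, 5], [400, 580]])
        assert gtest_independence(table).g == pytest.approx(
            gtest_independence(table[::-1]).g, rel=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fg.category_enrichment(_states(5, 5), fg.CandidateGeneList("x", ()), _genome(10))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fg.CandidateGeneList("x", ("g1", "g1"))

    def test_unresolvable_ids_warned_and_ignored(self, caplog):
        states = _states(5, 5)
        lst = fg.CandidateGeneList("x", ("g0", "nope1", "nope2"))
        with caplog.at_level("WARNING"):
            overlap, _, _ = fg.category_enrichment(states, lst, _genome(10))
        assert overlap == 1
        assert any("unresolvable" in r.message for r in caplog.records)


class TestDirectionConcordance:
    def test_all_k4_members_up_gives_one(self):
        states = _states(10, 10)
        up = fg.CandidateGeneList("up", tuple(f"g{i}" for i in range(5)))
        down = fg.CandidateGeneList("down", tuple(f"g{i}" for i in range(10, 15)))
        k4_up, _ = fg.direction_concordance(states, up, down)
        assert k4_up == 1.0

    def test_empty_intersection_gives_zero(self):
        states = _states(0, 10)  # nothing marked
        up = fg.CandidateGeneList("up", ("g0",))
        down = fg.CandidateGeneList("down", ("g1",))
        assert fg.direction_concordance(states, up, down) == (0.0, 0.0)

    def test_overlapping_lists_rejected(self):
        states = _states(2, 2)
        shared = fg.CandidateGeneList("up", ("g0",))
        with pytest.raises(ValueError, match="disjoint"):
            fg.direction_concordance(states, shared, fg.CandidateGeneList("down", ("g0",)))

    def test_fixture_concordance_recovered(self, sim, analysis):
        k4_up, k27_down = fg.direction_concordance(
            analysis["states"], sim.lists["up"], sim.lists["down"]
        )
        assert k4_up == pytest.approx(sim.config.concordance, abs=0.05)
        assert k27_down == pytest.approx(sim.config.concordance, abs=0.05)


class TestMotifInput:
    def _sequences(self, genome):
        rng = np.random.default_rng(0)
        return {
            c: "".join(rng.choice(list("ACGT"), size=length))
            for c, length in genome.chroms.items()
        }

    def test_records_have_twice_flank_length(self):
        genome = _genome(10)
        peaks = make_peakset(
            [("chr1", 500 + 1000 * i, 700 + 1000 * i, float(i), 100) for i in range(5)]
        )
        records = fg.motif_input(peaks, self._sequences(genome), genome, top_n=3, flank=50)
        assert len(records) == 3
        assert all(len(seq) == 100 for _, seq in records)

    def test_clipped_window_flagged(self):
        genome = _genome(3)
        peaks = make_peakset([("chr1", 0, 60, 5.0, 10)])  # summit at 10
        records = fg.motif_input(peaks, self._sequences(genome), genome, top_n=5, flank=50)
        header, seq = records[0]
        assert "clipped" in header
        assert len(seq) == 60

    def test_fewer_than_top_n_warns_and_emits_all(self, caplog):
        genome = _genome(5)
        peaks = make_peakset([("chr1", 500, 700, 5.0, 100)])
        with caplog.at_level("WARNING"):
            records = fg.motif_input(peaks, self._sequences(genome), genome, top_n=500)
        assert len(records) == 1
        assert any("qualifying peaks" in r.message for r in caplog.records)

    def test_score_ties_broken_deterministically(self):
        genome = _genome(10)
        rows = [("chr1", 500 + 1000 * i, 700 + 1000 * i, 5.0, 100) for i in range(6)]
        seqs = self._sequences(genome)
        a = fg.motif_input(make_peakset(rows), seqs, genome, top_n=4)
        b = fg.motif_input(make_peakset(list(reversed(rows))), seqs, genome, top_n=4)
        assert [h for h, _ in a] == [h for h, _ in b]

    def test_tss_distal_peaks_excluded(self):
        genome = _genome(3)
        # a peak 2 kb beyond every TSS window
        peaks = make_peakset([("chr1", 3800, 3900, 9.0, 50)])
        genome2 = GenomeModel(
            chroms={"chr1": 10_000},
            genes=[GeneModel(id="g0", chrom="chr1", strand="+", start=100, end=900)],
        )
        records = fg.motif_input(peaks, self._sequences(genome2), genome2, top_n=5)
        assert records == []
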