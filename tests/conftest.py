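"""Shared fixtures: a seed-1 synthetic study and its full analysis,
plus a small handcrafted genome for unit tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

from markscape import expression_link, landscape, signal, synthetic_data, tss_clusters
from markscape.formats_io import GeneModel, GenomeModel, TagCollection


def small_sim_config(seed: int = 1, **overrides) -> synthetic_data.SimConfig:
    """A down-scaled study for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=300_000,
        n_genes=60,
        depth_per_mark=20_000,
        n_intergenic_domains=6,
        candidate_list_size=25,
    )
    defaults.update(overrides)
    return synthetic_data.SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim() -> synthetic_data.SimResult:
    """The default-size seed-1 study (500 genes, 100k tags per library)."""
    return synthetic_data.simulate(synthetic_data.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim() -> synthetic_data.SimResult:
    return synthetic_data.simulate(small_sim_config())


@pytest.fixture(scope="session")
def analysis(sim):
    """The full downstream analysis of the seed-1 study, run once."""
    genome = sim.genome
    tracks = {
        mark: signal.coverage(sim.tags[(mark, 1)], genome)
        for mark in ("H3K4me3", "H3K27me3")
    }
    matrices = {
        mark: signal.tss_matrix(tracks[mark], genome, mark=mark)
        for mark in ("H3K4me3", "H3K27me3")
    }
    raw = tss_clusters.kmeans_cluster(
        matrices["H3K4me3"], matrices["H3K27me3"], genome.size, k=10, seed=1
    )
    assignment = tss_clusters.categorize(raw)
    control = TagCollection(
        pd.concat(
            [sim.tags[("input", 1)].df, sim.tags[("input", 2)].df],
            ignore_index=True,
        )
    )
    called = {
        (mark, rep): landscape.standin_call_peaks(
            sim.tags[(mark, rep)], control, genome, shape=shape, mark=mark
        )
        for mark, shape in (("H3K4me3", "narrow"), ("H3K27me3", "broad"))
        for rep in (1, 2)
    }
    reproducible = {
        mark: landscape.reproducible_peaks(called[(mark, 1)], called[(mark, 2)])
        for mark in ("H3K4me3", "H3K27me3")
    }
    bivalent = landscape.detect_bivalent(
        reproducible["H3K4me3"], reproducible["H3K27me3"]
    )
    states = landscape.assign_gene_states(
        reproducible["H3K4me3"], reproducible["H3K27me3"], bivalent, genome
    )
    expr = expression_link.rpkm(
        sim.counts, genome, library_size=sim.config.rna_library_size
    )
    anova = expression_link.group_anova(expr, states["state"])
    return {
        "tracks": tracks,
        "matrices": matrices,
        "raw": raw,
        "assignment": assignment,
        "called": called,
        "reproducible": reproducible,
        "bivalent": bivalent,
        "states": states,
        "expr": expr,
        "anova": anova,
    }


@pytest.fixture()
def toy_genome() -> GenomeModel:
    """Two chromosomes, three genes with exons/UTRs on both strands."""
    genes = [
        GeneModel(
            id="gx", chrom="chrA", strand="+", start=2000, end=3000,
            exons=((2000, 2300), (2500, 2700), (2800, 3000)),
            utr5=((2000, 2100),), utr3=((2900, 3000),),
        ),
        GeneModel(
            id="gy", chrom="chrA", strand="-", start=6000, end=7200,
            exons=((6000, 6400), (6800, 7200)),
            utr5=((7100, 7200),), utr3=((6000, 6100),),
        ),
        GeneModel(
            id="gz", chrom="chrB", strand="+", start=4000, end=5000,
            exons=((4000, 5000),),
        ),
    ]
    return GenomeModel(chroms={"chrA": 10_000, "chrB": 8_000}, genes=genes)
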