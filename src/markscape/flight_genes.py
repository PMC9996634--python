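"""Overlap of peak-annotated genes with curated candidate gene lists
(wing development, migratory flight), G-tests of proportion enrichment,
and preparation of summit-flank FASTA input for motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import GenomeModel, PeakSet, write_fasta
from .landscape import GeneState, GTestResult, gtest_independence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateGeneList:
    name: str
    genes: tuple[str, ...]
    source: str = "curated"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"candidate list {self.name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.genes)


def category_enrichment(
    states: pd.DataFrame,
    gene_list: CandidateGeneList,
    genome: GenomeModel,
) -> tuple[int, GTestResult, float]:
    """2x2 G-test: peak-marked vs unmarked genes, in-list vs rest of genome.

    Returns (number of marked list members, test result, direction): the
    direction is the list's marked proportion minus the genome's, so a
    positive value means enrichment of marked genes in the list.
    Unresolvable list ids are reported and ignored.
    """
    if len(gene_list) == 0:
        raise ValueError("empty candidate gene list")
    known = set(states.index)
    resolved = [g for g in gene_list.genes if g in known]
    missing = sorted(set(gene_list.genes) - known)
    if missing:
        logger.warning(
            "category_enrichment: %d unresolvable ids in %r (e.g. %s)",
            len(missing),
            gene_list.name,
            ", ".join(missing[:3]),
        )
    marked = states["state"] != GeneState.UNMARKED.value
    in_list = states.index.isin(resolved)
    table = np.array(
        [
            [int((marked & in_list).sum()), int((~marked & in_list).sum())],
            [int((marked & ~in_list).sum()), int((~marked & ~in_list).sum())],
        ]
    )
    overlap = int(table[0, 0])
    if table[0].sum() == 0:
        raise ValueError("no candidate list members resolvable against the genome")
    result = gtest_independence(table)
    p_list = table[0, 0] / table[0].sum()
    p_genome = marked.mean()
    return overlap, result, float(p_list - p_genome)


def direction_concordance(
    states: pd.DataFrame,
    up: CandidateGeneList,
    down: CandidateGeneList,
) -> tuple[float, float]:
    """Fractions of mark-bearing candidate genes on the concordant side.

    Among candidate genes (up + down) carrying H3K4me3 at the TSS, the
    fraction belonging to the upregulated list; among those carrying
    H3K27me3 (TSS or gene body), the fraction belonging to the
    downregulated list.  Lists must be disjoint.
    """
    if set(up.genes) & set(down.genes):
        raise ValueError("up and down candidate lists must be disjoint")
    members = [g for g in up.genes + down.genes if g in states.index]
    up_set = set(up.genes)
    sub = states.loc[members]
    k4 = sub[sub["k4_tss"]]
    k27 = sub[sub["k27_tss"] | sub["k27_body"]]
    frac_k4_up = (
        float(k4.index.isin(up_set).mean()) if len(k4) else 0.0
    )
    frac_k27_down = (
        float((~k27.index.isin(up_set)).mean()) if len(k27) else 0.0
    )
    return frac_k4_up, frac_k27_down


def motif_input(
    peaks: PeakSet,
    sequences,
    genome: GenomeModel,
    top_n: int = 500,
    flank: int = 50,
    tss_window: int = 1000,
    out_path=None,
) -> list[tuple[str, str]]:
    """Summit-flank sequences of the top TSS-proximal peaks, as FASTA records.

    Peaks overlapping any TSS region (TSS +/- ``tss_window``) are ranked
    by score (descending), ties broken by (chrom, start); the top
    ``top_n`` contribute the window [summit - flank, summit + flank)
    (midpoint for broad peaks).  Windows clipped at chromosome ends are
    flagged in the record header.  ``sequences`` is a mapping of
    chromosome name to sequence (e.g. a pyfaidx.Fasta).
    """
    tss_trees: dict[str, IntervalTree] = {}
    for g in genome.genes:
        tss_trees.setdefault(g.chrom, IntervalTree()).addi(
            max(g.tss - tss_window, 0), g.tss + tss_window + 1
        )
    df = peaks.df.copy()
    df["summit_pos"] = peaks.summit_positions()
    keep = [
        bool(tss_trees.get(row.chrom) and tss_trees[row.chrom].overlap(row.start, row.end))
        for row in df.itertuples(index=False)
    ]
    df = df[np.array(keep, dtype=bool)] if len(df) else df
    df = df.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    if len(df) < top_n:
        logger.warning(
            "motif_input: only %d qualifying peaks (requested %d); emitting all",
            len(df),
            top_n,
        )
    df = df.head(top_n)
    records: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        lo = row.summit_pos - flank
        hi = row.summit_pos + flank
        chrom_len = genome.chroms[row.chrom]
        clipped = lo < 0 or hi > chrom_len
        lo_c, hi_c = max(lo, 0), min(hi, chrom_len)
        seq = str(sequences[row.chrom][lo_c:hi_c])
        header = f"{row.chrom}:{lo_c}-{hi_c}"
        if clipped:
            header += " clipped"
        records.append((header, seq.upper()))
    if out_path is not None:
        write_fasta(records, out_path)
    return records
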