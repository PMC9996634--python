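"""CPM-normalized coverage tracks and strand-oriented TSS signal matrices.

Coverage counts, per fixed-width bin, the number of extended tags touching
the bin, scaled to counts per million mapped tags (CPM).  Each tag is
extended from its strand-aware 5' end to the expected fragment length
before counting, the usual single-end ChIP-seq convention.

Occupancy "density" used by the cluster categorizer is coverage rescaled
to a fixed reference sequencing rate (10 million fragments per 468 Mb of
genome, i.e. one fragment per 46.8 bp) so that the absolute band
thresholds are comparable across library depths and genome sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenomeModel, TagCollection

logger = logging.getLogger(__name__)

#: reference sequencing rate defining occupancy-density units (fragments/bp)
REFERENCE_RATE = 1e7 / 4.68e8


@dataclass
class CoverageTrack:
    """Binned genome coverage in CPM units."""

    bin: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            expected = -(-self.chrom_lengths[chrom] // self.bin)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(arr)}"
                )
            if len(arr) and arr.min() < -1e-12:
                raise ValueError(f"{chrom}: negative coverage values")

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin])


@dataclass
class TssSignalMatrix:
    """Genes x TSS-centered bins of CPM signal, oriented 5'->3' of each gene.

    Column j covers gene-relative offsets [-window + j*bin, -window + (j+1)*bin).
    ``mask`` is False where the window fell off the chromosome (those cells
    are zero-filled and must be excluded from means).
    """

    genes: list[str]
    window: int
    bin: int
    values: np.ndarray
    mask: np.ndarray
    mark: str = "other"

    def __post_init__(self) -> None:
        ncol = 2 * self.window // self.bin
        if self.values.shape != (len(self.genes), ncol):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({len(self.genes)}, {ncol})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")

    @property
    def offsets(self) -> np.ndarray:
        """Genomic-orientation-free bin start offsets, -window ... window-bin."""
        return np.arange(-self.window, self.window, self.bin)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.genes, columns=self.offsets)


def coverage(
    tags: TagCollection,
    genome: GenomeModel,
    bin: int = 10,
    extend: int = 200,
) -> CoverageTrack:
    """Extended-tag coverage in CPM per bin.

    Each tag is replaced by the interval of length ``extend`` growing from
    its 5' end in the strand direction, clipped at chromosome ends; each
    bin counts the tags whose extended interval overlaps it, scaled by
    1e6 / library_size.
    """
    if tags.library_size == 0:
        values = {
            c: np.zeros(-(-length // bin)) for c, length in genome.chroms.items()
        }
        return CoverageTrack(bin=bin, chrom_lengths=dict(genome.chroms), values=values)
    read_lengths = tags.df["end"] - tags.df["start"]
    if extend < read_lengths.max():
        logger.warning(
            "coverage: extend=%d is shorter than the longest tag (%d); proceeding",
            extend,
            int(read_lengths.max()),
        )
    scale = 1e6 / tags.library_size
    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.chroms.items():
        values[chrom] = np.zeros(-(-length // bin))
    for chrom, sub in tags.per_chrom():
        if chrom not in genome.chroms:
            raise ValueError(f"tags on unknown chromosome {chrom!r}")
        length = genome.chroms[chrom]
        plus = sub["strand"].to_numpy() == "+"
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        ext_start = np.where(plus, start, end - extend)
        ext_end = ext_start + extend
        ext_start = np.clip(ext_start, 0, length)
        ext_end = np.clip(ext_end, 0, length)
        keep = ext_end > ext_start
        first_bin = ext_start[keep] // bin
        last_bin = (ext_end[keep] - 1) // bin  # inclusive
        nbins = len(values[chrom])
        diff = np.zeros(nbins + 1)
        np.add.at(diff, first_bin, 1.0)
        np.add.at(diff, last_bin + 1, -1.0)
        values[chrom] += np.cumsum(diff[:-1])
    for chrom in values:
        values[chrom] *= scale
    return CoverageTrack(
        bin=bin,
        chrom_lengths=dict(genome.chroms),
        values=values,
        library_size=tags.library_size,
    )


def tss_matrix(
    track: CoverageTrack,
    genome: GenomeModel,
    window: int = 3000,
    mark: str = "other",
) -> TssSignalMatrix:
    """Extract TSS-centered windows of a coverage track, one row per gene.

    Rows of minus-strand genes are reversed so that all rows read 5'->3'
    in gene orientation.  Bins falling off the chromosome are zero with
    mask=False.
    """
    if window % track.bin:
        raise ValueError("track bin must divide the window")
    ncol = 2 * window // track.bin
    n = len(genome.genes)
    values = np.zeros((n, ncol))
    mask = np.zeros((n, ncol), dtype=bool)
    for i, gene in enumerate(genome.genes):
        if gene.chrom not in track.values:
            raise ValueError(f"gene {gene.id}: chromosome {gene.chrom!r} not in track")
        arr = track.values[gene.chrom]
        tss_bin = gene.tss // track.bin
        half = window // track.bin
        if gene.strand == "-":
            # shift by one bin so the TSS-containing bin lands on offset 0
            # after the row is reversed into gene orientation
            lo, hi = tss_bin - half + 1, tss_bin + half + 1
        else:
            lo, hi = tss_bin - half, tss_bin + half
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        row = np.zeros(ncol)
        rowmask = np.zeros(ncol, dtype=bool)
        row[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        rowmask[src_lo - lo : src_hi - lo] = True
        if gene.strand == "-":
            row = row[::-1]
            rowmask = rowmask[::-1]
        values[i] = row
        mask[i] = rowmask
    return TssSignalMatrix(
        genes=genome.gene_ids(),
        window=window,
        bin=track.bin,
        values=values,
        mask=mask,
        mark=mark,
    )


def density_scale(library_size: int, genome_size: int) -> float:
    """Factor converting raw per-bin tag counts to occupancy-density units."""
    if library_size <= 0 or genome_size <= 0:
        raise ValueError("library and genome size must be positive")
    return REFERENCE_RATE * genome_size / library_size


def cpm_to_density(genome_size: int) -> float:
    """Factor converting CPM values to occupancy-density units."""
    return REFERENCE_RATE * genome_size / 1e6


def write_matrix_tsv(matrix: TssSignalMatrix, path) -> None:
    """Write a TSS matrix as TSV with a header row of bin start offsets."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(str(o) for o in matrix.offsets) + "\n")
        for gene, row in zip(matrix.genes, matrix.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
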