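"""Readers and writers for the external formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals
(BED convention).  GFF3 input (1-based, closed) is converted on read and
back-converted on write.  Gene models are collapsed to one representative
transcript per gene (the longest by summed exon length), because every
downstream statistic in this package is computed at gene level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

FEATURE_CLASSES = (
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream",
    "intergenic",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A single gene with one representative transcript.

    ``start``/``end`` are 0-based half-open genomic coordinates; the TSS is
    ``start`` on the plus strand and ``end - 1`` on the minus strand.  Exon
    and UTR intervals are genomic (not transcript-oriented), sorted and
    non-overlapping.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id}: invalid interval [{self.start}, {self.end})")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.id}: exon [{s}, {e}) outside gene body")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        if not self.exons:
            return self.end - self.start
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        if len(self.exons) < 2:
            return ()
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene models; the coordinate frame for everything."""

    chroms: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if g.chrom not in self.chroms:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chrom!r}")
            if g.end > self.chroms[g.chrom]:
                raise ValueError(f"gene {g.id}: extends past end of {g.chrom}")

    @property
    def size(self) -> int:
        return sum(self.chroms.values())

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class TagCollection:
    """Aligned, deduplicatable sequence tags (fragments or reads).

    Held as a DataFrame with columns ``chrom, start, end, strand``; the
    library size for CPM/RPKM scaling is the number of tags.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "strand"]
        if list(self.df.columns[:4]) != required:
            self.df = self.df[required]
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("empty or inverted tag intervals")
        self.df = self.df.reset_index(drop=True)

    @property
    def library_size(self) -> int:
        return len(self.df)

    def five_prime(self) -> np.ndarray:
        """Strand-aware 5' end coordinate of every tag."""
        plus = self.df["strand"].to_numpy() == "+"
        return np.where(plus, self.df["start"].to_numpy(), self.df["end"].to_numpy() - 1)

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2

    def per_chrom(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom, sub in self.per_chrom():
            if chrom not in genome.chroms:
                raise ValueError(f"tags on unknown chromosome {chrom!r}")
            if int(sub["end"].max()) > genome.chroms[chrom]:
                raise ValueError(f"tags extend past end of {chrom}")


@dataclass
class PeakSet:
    """Scored peak intervals; narrow peaks may carry a summit offset.

    The summit column holds the offset from ``start`` (NaN when absent).
    Peaks are kept sorted by (chrom, start).
    """

    df: pd.DataFrame
    mark: str = "other"
    shape: str = "narrow"

    COLUMNS = ["chrom", "start", "end", "score", "summit"]

    def __post_init__(self) -> None:
        if self.shape not in ("narrow", "broad"):
            raise ValueError(f"shape must be narrow or broad, got {self.shape!r}")
        for col in self.COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"PeakSet frame missing column {col!r}")
        df = self.df[self.COLUMNS].copy()
        if len(df):
            lengths = df["end"] - df["start"]
            if (lengths <= 0).any():
                raise ValueError("peak with non-positive length")
            bad = df["summit"].notna() & (
                (df["summit"] < 0) | (df["summit"] >= lengths)
            )
            if bad.any():
                raise ValueError("summit offset outside peak interval")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def summit_positions(self) -> np.ndarray:
        """Absolute summit coordinate, falling back to the midpoint."""
        start = self.df["start"].to_numpy()
        end = self.df["end"].to_numpy()
        summit = self.df["summit"].to_numpy(dtype=float)
        mid = (start + end) // 2
        return np.where(np.isnan(summit), mid, start + summit).astype(int)

    def intervals_by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            out[chrom] = sub[["start", "end"]].to_numpy(dtype=int)
        return out


def make_peakset(
    records: Iterable[tuple],
    mark: str = "other",
    shape: str = "narrow",
) -> PeakSet:
    """Build a PeakSet from (chrom, start, end[, score[, summit]]) tuples."""
    rows = []
    for rec in records:
        chrom, start, end = rec[0], int(rec[1]), int(rec[2])
        score = float(rec[3]) if len(rec) > 3 else 0.0
        summit = rec[4] if len(rec) > 4 else None
        rows.append(
            (chrom, start, end, score, math.nan if summit is None else float(summit))
        )
    df = pd.DataFrame(rows, columns=PeakSet.COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in zip(PeakSet.COLUMNS, [str, int, int, float, float])}
    )
    return PeakSet(df, mark=mark, shape=shape)


def make_tags(records: Iterable[tuple]) -> TagCollection:
    """Build a TagCollection from (chrom, start, end[, strand]) tuples."""
    rows = [(r[0], int(r[1]), int(r[2]), r[3] if len(r) > 3 else "+") for r in records]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]) if rows else (
        pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
                      "end": pd.Series(dtype=int), "strand": pd.Series(dtype=str)})
    )
    return TagCollection(df)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_gff_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"GFF3 line {lineno}: malformed attribute {part!r}")
        key, value = part.split("=", 1)
        out[key] = value
    return out


def read_gff3(path) -> GenomeModel:
    """Read gene models from GFF3, keeping one (longest) transcript per gene.

    Chromosome lengths come from ``##sequence-region`` pragmas when present;
    otherwise each chromosome length is the maximum feature end.  Child
    features whose parent is unknown are skipped (counted in a warning).
    """
    chroms: dict[str, int] = {}
    genes: dict[str, dict] = {}  # gene id -> {line fields}
    transcripts: dict[str, dict] = {}  # mRNA id -> {gene, chrom, strand, exons, utr5, utr3}
    orphans = 0
    max_end: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chroms[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attr = cols
            start, end = int(start1) - 1, int(end1)  # to 0-based half-open
            attrs = _parse_gff_attributes(attr, lineno)
            max_end[chrom] = max(max_end.get(chrom, 0), end)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"GFF3 line {lineno}: gene without ID")
                genes[gid] = {"chrom": chrom, "strand": strand, "start": start, "end": end}
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if parent not in genes:
                    orphans += 1
                    continue
                transcripts[tid] = {
                    "gene": parent,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                }
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attrs.get("Parent")
                if parent not in transcripts:
                    orphans += 1
                    continue
                key = {"exon": "exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[
                    ftype
                ]
                transcripts[parent][key].append((start, end))

    if orphans:
        logger.warning("read_gff3: skipped %d features with unknown parents", orphans)

    # group transcripts under genes, keep the longest by summed exon length
    by_gene: dict[str, list[dict]] = {}
    for t in transcripts.values():
        by_gene.setdefault(t["gene"], []).append(t)

    models: list[GeneModel] = []
    for gid, info in genes.items():
        cands = by_gene.get(gid, [])
        if cands:
            best = max(
                cands,
                key=lambda t: sum(e - s for s, e in t["exons"])
                if t["exons"]
                else 0,
            )
            exons = tuple(sorted(best["exons"]))
            utr5 = tuple(sorted(best["utr5"]))
            utr3 = tuple(sorted(best["utr3"]))
        else:
            exons, utr5, utr3 = (), (), ()
        models.append(
            GeneModel(
                id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                exons=exons or ((info["start"], info["end"]),),
                utr5=utr5,
                utr3=utr3,
            )
        )

    for chrom, end in max_end.items():
        chroms.setdefault(chrom, end)
    models.sort(key=lambda g: (g.chrom, g.start, g.id))
    return GenomeModel(chroms=chroms, genes=models)


def write_gff3(genome: GenomeModel, path) -> None:
    """Write a GenomeModel back to GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.chroms):
            fh.write(f"##sequence-region {chrom} 1 {genome.chroms[chrom]}\n")
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\tmarkscape\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}\n"
            )
            tid = f"{g.id}.t1"
            fh.write(
                f"{g.chrom}\tmarkscape\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tmarkscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            for s, e in g.utr5:
                fh.write(
                    f"{g.chrom}\tmarkscape\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.chrom}\tmarkscape\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# tags: BED / tagAlign / BAM
# ---------------------------------------------------------------------------


def read_tags(path, dialect: str = "BED", genome: GenomeModel | None = None) -> TagCollection:
    """Read aligned tags from BED3/6, ENCODE tagAlign, or BAM.

    Strand defaults to '+' (with a warning) when the file carries none.
    When a genome is given, tags on unknown chromosomes raise an error
    listing the offending names.
    """
    dialect = dialect.upper()
    if dialect == "BAM":
        return _read_tags_bam(path, genome)
    if dialect not in ("BED", "TAGALIGN"):
        raise ValueError(f"unknown tag dialect {dialect!r}")

    rows: list[tuple[str, int, int, str]] = []
    defaulted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{dialect} line {lineno}: fewer than 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise FormatError(
                    f"{dialect} line {lineno}: empty interval [{start}, {end})"
                )
            if len(cols) >= 6:
                strand = cols[5]
                if strand not in "+-":
                    strand = "+"
                    defaulted += 1
            else:
                strand = "+"
                defaulted += 1
            rows.append((chrom, start, end, strand))
    if defaulted:
        logger.warning("read_tags: %d tags without strand, defaulted to '+'", defaulted)
    tags = make_tags(rows)
    if genome is not None:
        unknown = sorted(set(tags.df["chrom"]) - set(genome.chroms))
        if unknown:
            raise ValueError(f"tags on unknown chromosomes: {', '.join(unknown)}")
    return tags


def _read_tags_bam(path, genome: GenomeModel | None) -> TagCollection:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("BAM support requires pysam") from exc
    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:  # pragma: no cover
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            rows.append(
                (
                    read.reference_name,
                    read.reference_start,
                    read.reference_end,
                    "-" if read.is_reverse else "+",
                )
            )
    tags = make_tags(rows)
    if genome is not None:
        unknown = sorted(set(tags.df["chrom"]) - set(genome.chroms))
        if unknown:
            raise ValueError(f"tags on unknown chromosomes: {', '.join(unknown)}")
    return tags


def write_tags(tags: TagCollection, path) -> None:
    """Write tags as 6-column ENCODE tagAlign (sequence column 'N')."""
    with open(path, "w") as fh:
        for chrom, start, end, strand in tags.df.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\tN\t1000\t{strand}\n")


# ---------------------------------------------------------------------------
# peaks: narrowPeak / broadPeak
# ---------------------------------------------------------------------------


def read_peaks(path, shape: str, mark: str = "other") -> PeakSet:
    """Read ENCODE narrowPeak (10 columns) or broadPeak (9 columns).

    The peak score is taken from the signalValue column (7) as a float;
    narrowPeak summit offsets of -1 map to "no summit".
    """
    expected = {"narrow": 10, "broad": 9}.get(shape)
    if expected is None:
        raise ValueError(f"shape must be narrow or broad, got {shape!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != expected:
                raise FormatError(
                    f"{shape}Peak line {lineno}: expected {expected} columns, got {len(cols)}"
                )
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            score = float(cols[6])
            summit = None
            if shape == "narrow":
                off = int(cols[9])
                if off != -1:
                    if not 0 <= off < end - start:
                        raise FormatError(
                            f"narrowPeak line {lineno}: summit offset {off} outside peak"
                        )
                    summit = off
            records.append((chrom, start, end, score, summit))
    return make_peakset(records, mark=mark, shape=shape)


def write_peaks(peaks: PeakSet, path) -> None:
    """Write a PeakSet as narrowPeak (narrow) or broadPeak (broad)."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.df.itertuples(index=False)):
            name = f"{peaks.mark}_peak_{i + 1}"
            base = (
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t"
                f"{min(1000, int(round(row.score * 10)))}\t.\t{row.score:.5f}\t-1\t-1"
            )
            if peaks.shape == "narrow":
                summit = -1 if math.isnan(row.summit) else int(row.summit)
                fh.write(f"{base}\t{summit}\n")
            else:
                fh.write(f"{base}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(track, path) -> None:
    """Write a CoverageTrack as bedGraph, merging adjacent equal-valued bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            values = track.values[chrom]
            if len(values) == 0:
                continue
            chrom_len = track.chrom_lengths[chrom]
            run_start = 0
            run_value = values[0]
            for i in range(1, len(values) + 1):
                v = values[i] if i < len(values) else None
                if v is None or v != run_value:
                    if run_value != 0:
                        start_bp = run_start * track.bin
                        end_bp = min(i * track.bin, chrom_len)
                        fh.write(f"{chrom}\t{start_bp}\t{end_bp}\t{_fmt(run_value)}\n")
                    run_start = i
                    run_value = v


def _fmt(value: float) -> str:
    return f"{value:.6g}"


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------


def read_counts(path) -> pd.Series:
    """Read a two-column TSV (gene id, count) into a Series."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "count"])
    if df["gene"].duplicated().any():
        raise FormatError("duplicate gene ids in counts table")
    return df.set_index("gene")["count"].astype(float)


def read_gene_list(path, name: str | None = None, source: str = "file"):
    """Read a one-column TSV of gene ids into a CandidateGeneList."""
    from .flight_genes import CandidateGeneList

    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line.split("\t")[0])
    return CandidateGeneList(
        name=name or str(path), genes=tuple(dict.fromkeys(ids)), source=source
    )


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
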