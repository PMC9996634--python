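"""Peak-level landscape analysis.

Replicate reproducibility by overlap, a simple Poisson sliding-window
enrichment caller (plumbing only -- external peak calls are accepted
through formats_io), bivalent-domain detection by minimum peak overlap,
precedence-ordered peak-to-feature annotation, the G goodness-of-fit
test for feature enrichment, and per-gene modification-state assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .formats_io import (
    FEATURE_CLASSES,
    GenomeModel,
    PeakSet,
    TagCollection,
    make_peakset,
)

logger = logging.getLogger(__name__)


class GeneState(str, Enum):
    """Primary per-gene modification state, in precedence order."""

    BIVALENT_TSS = "bivalent_TSS"
    H3K4ME3_ONLY_TSS = "H3K4me3_only_TSS"
    H3K27ME3_ONLY_TSS = "H3K27me3_only_TSS"
    H3K27ME3_GENE_BODY = "H3K27me3_gene_body"
    UNMARKED = "unmarked"


STATE_ORDER = [s.value for s in GeneState]


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# stand-in enrichment caller
# ---------------------------------------------------------------------------


def standin_call_peaks(
    tags: TagCollection,
    control: TagCollection | None,
    genome: GenomeModel,
    shape: str = "narrow",
    pvalue: float = 1e-5,
    mark: str = "other",
) -> PeakSet:
    """Poisson sliding-window enrichment caller (not a MACS2 reimplementation).

    Windows of 200 bp (narrow) or 1 kb (broad), stepped by half a window,
    are tested against a local background rate: the maximum of the
    control rate in the window, in the surrounding 5 kb, and genome-wide,
    scaled to the treatment depth.  Windows with Poisson upper-tail
    p < ``pvalue`` are merged when within 100 bp (narrow) / 1 kb (broad);
    narrow peaks get a summit at the maximum-coverage 10-bp bin.
    """
    if tags.library_size == 0:
        return make_peakset([], mark=mark, shape=shape)
    window = 200 if shape == "narrow" else 1000
    merge_gap = 100 if shape == "narrow" else 1000
    step = window // 2

    use_control = control is not None and control.library_size > 0
    if use_control:
        scale = tags.library_size / control.library_size
        genome_rate = control.library_size / genome.size * scale
    else:
        genome_rate = tags.library_size / genome.size
        scale = 1.0

    records = []
    for chrom, length in genome.chroms.items():
        t_mid = _chrom_midpoints(tags, chrom)
        if len(t_mid) == 0:
            continue
        c_mid = _chrom_midpoints(control, chrom) if use_control else np.array([])
        starts = np.arange(0, max(length - window, 0) + 1, step)
        ends = starts + window
        obs = _interval_counts(t_mid, starts, ends)
        lam = np.full(len(starts), genome_rate * window)
        if use_control:
            local_w = _interval_counts(c_mid, starts, ends) * scale
            w5_starts = np.maximum(starts + window // 2 - 2500, 0)
            w5_ends = np.minimum(starts + window // 2 + 2500, length)
            local_5k = (
                _interval_counts(c_mid, w5_starts, w5_ends)
                * scale
                / np.maximum(w5_ends - w5_starts, 1)
                * window
            )
            lam = np.maximum.reduce([lam, local_w, local_5k])
        lam = np.maximum(lam, 1e-9)
        pvals = stats.poisson.sf(obs - 1, lam)
        sig = np.flatnonzero(pvals < pvalue)
        if len(sig) == 0:
            continue
        # merge significant windows within merge_gap
        groups: list[list[int]] = [[sig[0]]]
        for i in sig[1:]:
            if starts[i] - ends[groups[-1][-1]] <= merge_gap:
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            pk_start = int(starts[grp[0]])
            pk_end = int(min(ends[grp[-1]], length))
            best_p = float(pvals[grp].min())
            score = -math.log10(max(best_p, 1e-300))
            summit = None
            if shape == "narrow":
                in_peak = t_mid[(t_mid >= pk_start) & (t_mid < pk_end)]
                if len(in_peak):
                    nb = -(-(pk_end - pk_start) // 10)
                    hist = np.bincount((in_peak - pk_start) // 10, minlength=nb)
                    summit = int(hist.argmax() * 10 + 5)
                    summit = min(summit, pk_end - pk_start - 1)
            records.append((chrom, pk_start, pk_end, score, summit))
    return make_peakset(records, mark=mark, shape=shape)


def _chrom_midpoints(tags: TagCollection | None, chrom: str) -> np.ndarray:
    if tags is None:
        return np.array([], dtype=int)
    sub = tags.df[tags.df["chrom"] == chrom]
    if sub.empty:
        return np.array([], dtype=int)
    return np.sort((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)


def _interval_counts(sorted_pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_pos, ends, side="left") - np.searchsorted(
        sorted_pos, starts, side="left"
    )


# ---------------------------------------------------------------------------
# replicate reproducibility and bivalency
# ---------------------------------------------------------------------------


def reproducible_peaks(rep1: PeakSet, rep2: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Overlap-supported peaks: unions of connected overlap groups.

    Peaks from both replicates are pooled and chained into maximal
    connected groups (each member overlapping the group's span by at
    least ``min_overlap`` bp); groups containing members from both
    replicates are emitted as their union interval, scored with the
    minimum member score.
    """
    rows = []
    for rep_idx, ps in ((0, rep1), (1, rep2)):
        for row in ps.df.itertuples(index=False):
            rows.append((row.chrom, row.start, row.end, row.score, rep_idx))
    if not rows:
        return make_peakset([], mark=rep1.mark, shape=rep1.shape)
    pooled = sorted(rows)
    records = []
    group: list[tuple] = []
    span_end = -1
    for item in pooled:
        chrom, start, end = item[0], item[1], item[2]
        if group and chrom == group[0][0] and start <= span_end - min_overlap:
            group.append(item)
            span_end = max(span_end, end)
        else:
            _flush_group(group, records)
            group = [item]
            span_end = end
    _flush_group(group, records)
    return make_peakset(records, mark=rep1.mark, shape=rep1.shape)


def _flush_group(group: list[tuple], records: list[tuple]) -> None:
    if not group:
        return
    reps = {item[4] for item in group}
    if reps == {0, 1}:
        chrom = group[0][0]
        start = min(item[1] for item in group)
        end = max(item[2] for item in group)
        score = min(item[3] for item in group)
        records.append((chrom, start, end, score, None))


def detect_bivalent(
    k4: PeakSet, k27: PeakSet, min_overlap: int = 100
) -> PeakSet:
    """Bivalent domains: intersections of a K4 and a K27 peak >= min_overlap bp.

    The minimum overlap of 100 bp approximates one nucleosome.  The
    emitted domain interval is the intersection itself; the score is the
    smaller of the two parent scores.
    """
    trees: dict[str, IntervalTree] = {}
    for row in k27.df.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.score)
    records = []
    for row in k4.df.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(row.start, row.end)):
            s = max(row.start, iv.begin)
            e = min(row.end, iv.end)
            if e - s >= min_overlap:
                records.append((row.chrom, s, e, min(row.score, iv.data), None))
    return make_peakset(records, mark="bivalent", shape="broad")


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


def annotate_peaks(
    peaks: PeakSet,
    genome: GenomeModel,
    promoter: int = 1000,
    downstream: int = 300,
) -> pd.DataFrame:
    """Classify each peak's summit (or midpoint) into one genomic feature.

    Feature classes, in precedence order: promoter (TSS +/- ``promoter``),
    5' UTR, 3' UTR, exon, intron, downstream (``downstream`` bp past the
    gene end in gene orientation), intergenic.  Exactly one class per
    peak.  Also reports the nearest gene and the signed distance from its
    TSS (negative upstream in gene orientation).
    """
    trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for g in genome.genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.id, g.strand))
        _add(tree, g.tss - promoter, g.tss + promoter + 1, "promoter", g.id)
        for s, e in g.utr5:
            _add(tree, s, e, "utr5", g.id)
        for s, e in g.utr3:
            _add(tree, s, e, "utr3", g.id)
        for s, e in g.exons:
            _add(tree, s, e, "exon", g.id)
        for s, e in g.introns:
            _add(tree, s, e, "intron", g.id)
        if g.strand == "+":
            _add(tree, g.end, g.end + downstream, "downstream", g.id)
        else:
            _add(tree, g.start - downstream, g.start, "downstream", g.id)

    tss_sorted = {
        c: sorted(v) for c, v in tss_by_chrom.items()
    }
    precedence = {cls: i for i, cls in enumerate(FEATURE_CLASSES)}
    points = peaks.summit_positions()
    rows = []
    for (row, point) in zip(peaks.df.itertuples(index=False), points):
        tree = trees.get(row.chrom)
        hits = sorted(tree.at(point), key=lambda iv: precedence[iv.data[0]]) if tree else []
        cls = hits[0].data[0] if hits else "intergenic"
        gene_id, signed = _nearest_gene(tss_sorted.get(row.chrom), genome, point)
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "point": int(point),
                "feature": cls,
                "nearest_gene": gene_id,
                "tss_distance": signed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "point", "feature", "nearest_gene", "tss_distance"],
    )


def _add(tree: IntervalTree, start: int, end: int, cls: str, gene: str) -> None:
    if end > start:
        tree.addi(max(start, 0), end, (cls, gene))


def _nearest_gene(tss_list, genome: GenomeModel, point: int):
    if not tss_list:
        return None, None
    positions = [t[0] for t in tss_list]
    i = int(np.searchsorted(positions, point))
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(tss_list):
            d = abs(point - tss_list[j][0])
            if best is None or d < best[0]:
                best = (d, tss_list[j])
    _, (tss, gene_id, strand) = best
    signed = point - tss if strand == "+" else tss - point
    return gene_id, int(signed)


def feature_null_proportions(
    genome: GenomeModel, promoter: int = 1000, downstream: int = 300, step: int = 50
) -> dict[str, float]:
    """Genome-wide feature-class proportions, by point classification on a grid.

    Serves as the null distribution for the feature G-test; every ``step``-th
    base is classified with the same precedence rules as annotate_peaks.
    """
    records = []
    for chrom, length in genome.chroms.items():
        for pos in range(0, length, step):
            records.append((chrom, pos, pos + 1, 0.0, None))
    grid = make_peakset(records, shape="narrow")
    ann = annotate_peaks(grid, genome, promoter=promoter, downstream=downstream)
    counts = ann["feature"].value_counts()
    total = counts.sum()
    return {cls: float(counts.get(cls, 0)) / total for cls in FEATURE_CLASSES}


# ---------------------------------------------------------------------------
# G test
# ---------------------------------------------------------------------------


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """G = 2 * sum O_i * ln(O_i / E_i); zero observed cells contribute 0."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    nz = observed > 0
    if np.any(expected[nz] <= 0):
        raise ValueError("zero expected value with nonzero observed count")
    return float(2.0 * np.sum(observed[nz] * np.log(observed[nz] / expected[nz])))


def gtest_features(
    observed: dict[str, float] | pd.Series,
    expected_proportions: dict[str, float] | pd.Series,
    df: int | None = None,
) -> GTestResult:
    """Goodness-of-fit G-test of observed class counts against null proportions."""
    obs = pd.Series(observed, dtype=float)
    props = pd.Series(expected_proportions, dtype=float).reindex(obs.index)
    if props.isna().any():
        raise ValueError("expected proportions missing for some classes")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed total must be positive")
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("expected proportions must sum to 1")
    g = g_statistic(obs.to_numpy(), (total * props).to_numpy())
    dof = df if df is not None else len(obs) - 1
    p = float(stats.chi2.sf(g, dof))
    return GTestResult(g=g, df=dof, p=max(p, np.finfo(float).tiny))


def gtest_independence(table: np.ndarray) -> GTestResult:
    """G-test of independence on a contingency table (expected from marginals)."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("empty contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    g = g_statistic(t.ravel(), expected.ravel())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(g, dof))
    return GTestResult(g=g, df=dof, p=max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# gene states
# ---------------------------------------------------------------------------


def assign_gene_states(
    k4: PeakSet,
    k27: PeakSet,
    bivalent: PeakSet,
    genome: GenomeModel,
    promoter: int = 1000,
) -> pd.DataFrame:
    """Per-gene modification state from reproducible peak sets.

    The TSS window is TSS +/- ``promoter``.  A gene is bivalent_TSS when a
    bivalent domain overlaps the window; otherwise H3K4me3_only_TSS or
    H3K27me3_only_TSS by exclusive overlap of the single mark.  Any gene
    whose body [gene start, gene end) is overlapped by a K27 peak is
    flagged H3K27me3_gene_body.  The primary state follows the precedence
    bivalent > K4-only > K27-only > K27 gene body > unmarked.
    """
    columns = ["state", "k4_tss", "k27_tss", "bivalent_tss", "k27_body"]
    if not genome.genes:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="gene"))
    k4_t = _tree_of(k4)
    k27_t = _tree_of(k27)
    biv_t = _tree_of(bivalent)
    rows = []
    for g in genome.genes:
        lo, hi = max(g.tss - promoter, 0), g.tss + promoter
        k4_tss = _hits(k4_t, g.chrom, lo, hi)
        k27_tss = _hits(k27_t, g.chrom, lo, hi)
        biv_tss = _hits(biv_t, g.chrom, lo, hi)
        k27_body = _hits(k27_t, g.chrom, g.start, g.end)
        if biv_tss:
            state = GeneState.BIVALENT_TSS
        elif k4_tss and not k27_tss:
            state = GeneState.H3K4ME3_ONLY_TSS
        elif k27_tss and not k4_tss:
            state = GeneState.H3K27ME3_ONLY_TSS
        elif k27_body:
            state = GeneState.H3K27ME3_GENE_BODY
        else:
            state = GeneState.UNMARKED
        rows.append(
            {
                "gene": g.id,
                "state": state.value,
                "k4_tss": k4_tss,
                "k27_tss": k27_tss,
                "bivalent_tss": biv_tss,
                "k27_body": k27_body,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _tree_of(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in peaks.df.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def _hits(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))
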