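"""ENCODE-style ChIP-seq quality metrics.

Library complexity (NRF, PBC1, PBC2), strand cross-correlation with the
NSC/RSC enrichment ratios and a fragment-length estimate, fraction of
reads in peaks (FRiP), and 500-bp-bin replicate correlations.  A gate
applies the conventional thresholds (NRF >= 0.8, PBC1 > 0.5, PBC2 > 1,
NSC > 1.05, RSC > 0.8, FRiP >= 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GenomeModel, PeakSet, TagCollection

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: dict[str, float] = {
    "nrf": 0.8,  # at least
    "pbc1": 0.5,  # higher than
    "pbc2": 1.0,  # higher than
    "nsc": 1.05,  # higher than
    "rsc": 0.8,  # higher than
    "frip": 0.01,  # at least
}

# metrics whose gate is inclusive ("at least"); the rest are strict ("higher than")
_INCLUSIVE = {"nrf", "frip"}


@dataclass
class QcReport:
    """One library's QC panel.  Unset metrics are NaN and skipped by the gate."""

    nrf: float = math.nan
    pbc1: float = math.nan
    pbc2: float = math.nan
    frag_len_est: float = math.nan
    nsc: float = math.nan
    rsc: float = math.nan
    frip: float = math.nan
    pcc: float = math.nan
    scc: float = math.nan
    flags: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("nrf", "pbc1", "pbc2", "frag_len_est", "nsc", "rsc", "frip", "pcc", "scc"):
            rows.append(
                {
                    "metric": metric,
                    "value": getattr(self, metric),
                    "status": {True: "pass", False: "fail"}.get(
                        self.flags.get(metric), "."
                    ),
                }
            )
        return pd.DataFrame(rows)


def library_complexity(tags: TagCollection) -> tuple[float, float, float]:
    """NRF, PBC1, PBC2 from strand-aware 5'-end tag positions.

    Positions are keyed by (chrom, 5' end, strand).  NRF is distinct
    positions over total tags; PBC1 is one-read positions over distinct
    positions; PBC2 is one-read over two-read positions, +inf when no
    position carries exactly two reads.
    """
    if tags.library_size == 0:
        raise ValueError("library_complexity: empty tag collection")
    key = pd.DataFrame(
        {
            "chrom": tags.df["chrom"],
            "pos": tags.five_prime(),
            "strand": tags.df["strand"],
        }
    )
    counts = key.value_counts()
    distinct = len(counts)
    n1 = int((counts == 1).sum())
    n2 = int((counts == 2).sum())
    nrf = distinct / tags.library_size
    pbc1 = n1 / distinct
    if n2 == 0:
        logger.warning("library_complexity: no two-read positions; PBC2 reported as +inf")
        pbc2 = math.inf
    else:
        pbc2 = n1 / n2
    return nrf, pbc1, pbc2


def cross_correlation(
    tags: TagCollection,
    shifts: range = range(0, 510, 10),
    read_len: int = 50,
    bin: int = 10,
) -> tuple[pd.DataFrame, int, float, float]:
    """Strand cross-correlation curve with fragment length, NSC and RSC.

    For each shift k, the minus-strand 5'-end binned count vector is
    shifted back by k and correlated (Pearson) with the plus-strand
    vector, pooled over chromosomes.  The fragment-length estimate is the
    argmax shift outside an exclusion zone of one read length either side
    of the read length (which removes the "phantom" read-length peak).
    NSC = cc(frag)/min(cc); RSC = (cc(frag)-min)/(cc(read_len)-min).
    """
    strands = set(tags.df["strand"])
    if not {"+", "-"} <= strands:
        raise ValueError("cross_correlation: both strands must be represented")
    five = tags.five_prime()
    plus_vecs: list[np.ndarray] = []
    minus_vecs: list[np.ndarray] = []
    for chrom, sub in tags.per_chrom():
        idx = sub.index.to_numpy()
        pos = five[idx]
        strand = sub["strand"].to_numpy()
        top = pos.max() // bin + 1
        pv = np.bincount(pos[strand == "+"] // bin, minlength=top).astype(float)
        mv = np.bincount(pos[strand == "-"] // bin, minlength=top).astype(float)
        plus_vecs.append(pv)
        minus_vecs.append(mv)

    shift_list = sorted({(s // bin) * bin for s in shifts})
    cc_values = []
    for s in shift_list:
        sb = s // bin
        xs, ys = [], []
        for pv, mv in zip(plus_vecs, minus_vecs):
            if len(pv) <= sb + 1:
                continue
            xs.append(pv[: len(pv) - sb] if sb else pv)
            ys.append(mv[sb:])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.std() == 0 or y.std() == 0:
            cc_values.append(0.0)
        else:
            cc_values.append(float(np.corrcoef(x, y)[0, 1]))
    curve = pd.DataFrame({"shift": shift_list, "cc": cc_values})

    # exclusion zone: shifts within one read length of the read length
    excluded = (curve["shift"] - read_len).abs() < read_len
    candidates = curve[~excluded]
    if candidates.empty:
        candidates = curve
    frag_len_est = int(candidates.loc[candidates["cc"].idxmax(), "shift"])
    cc_frag = float(curve.loc[curve["shift"] == frag_len_est, "cc"].iloc[0])
    cc_min = float(curve["cc"].min())
    # cc at the shift closest to the read length
    read_row = (curve["shift"] - read_len).abs().idxmin()
    cc_read = float(curve.loc[read_row, "cc"])
    nsc = cc_frag / cc_min if cc_min > 0 else math.inf
    denom = cc_read - cc_min
    rsc = (cc_frag - cc_min) / denom if denom > 0 else math.inf
    return curve, frag_len_est, nsc, rsc


def frip(tags: TagCollection, peaks: PeakSet) -> float:
    """Fraction of tags whose midpoint falls inside any peak."""
    if tags.library_size == 0:
        raise ValueError("frip: empty tag collection")
    if len(peaks) == 0:
        logger.warning("frip: empty peak set; returning 0.0")
        return 0.0
    merged = _merged_intervals(peaks)
    inside = 0
    mids = tags.midpoints()
    for chrom, sub in tags.per_chrom():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        m = mids[sub.index.to_numpy()]
        # midpoint is inside a merged interval iff the most recent start
        # <= midpoint is paired with an end > midpoint
        j = np.searchsorted(starts, m, side="right") - 1
        ok = j >= 0
        inside += int(np.count_nonzero(ok & (m < ends[np.clip(j, 0, None)])))
    return inside / tags.library_size


def _merged_intervals(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, ivals in peaks.intervals_by_chrom().items():
        starts, ends = [], []
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    starts.append(cur_s)
                    ends.append(cur_e)
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            starts.append(cur_s)
            ends.append(cur_e)
        out[chrom] = (np.array(starts), np.array(ends))
    return out


def replicate_correlation(
    a: TagCollection,
    b: TagCollection,
    genome: GenomeModel,
    bin: int = 500,
) -> tuple[float, float]:
    """Pearson and Spearman correlation of per-bin tag counts.

    The genome is tiled with non-overlapping bins; each tag is counted in
    the bin containing its midpoint.  Raw counts are correlated (no input
    subtraction).  Zero-variance inputs yield NaN with a warning.
    """
    xs, ys = [], []
    for chrom, length in genome.chroms.items():
        nbins = -(-length // bin)
        xs.append(_bin_counts(a, chrom, bin, nbins))
        ys.append(_bin_counts(b, chrom, bin, nbins))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        logger.warning("replicate_correlation: zero-variance counts; correlation undefined")
        return math.nan, math.nan
    pcc = float(np.corrcoef(x, y)[0, 1])
    scc = float(stats.spearmanr(x, y).statistic)
    return pcc, scc


def _bin_counts(tags: TagCollection, chrom: str, bin: int, nbins: int) -> np.ndarray:
    sub = tags.df[tags.df["chrom"] == chrom]
    if sub.empty:
        return np.zeros(nbins)
    mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
    return np.bincount(np.clip(mids // bin, 0, nbins - 1), minlength=nbins).astype(float)


def qc_gate(
    report: QcReport, thresholds: dict[str, float] | None = None
) -> dict[str, bool]:
    """Pass/fail each available metric at the conventional thresholds.

    NRF and FRiP gates are inclusive ("at least"); PBC1, PBC2, NSC and RSC
    are strict ("higher than").  PBC2 of +inf passes.  The returned flags
    are also stored on the report.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    flags: dict[str, bool] = {}
    for metric, cut in th.items():
        value = getattr(report, metric, math.nan)
        if math.isnan(value):
            continue
        flags[metric] = value >= cut if metric in _INCLUSIVE else value > cut
    report.flags.update(flags)
    return flags
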