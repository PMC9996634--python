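"""K-means clustering of joint H3K4me3/H3K27me3 TSS profiles and
rule-based assignment of four promoter categories.

Categories (evaluated on each cluster's mean occupancy-density profile):

1. dual H3K4me3 peaks around the TSS -- a highly occupied apex shifted
   <200 bp downstream and a moderately occupied apex <400 bp upstream,
   with a central notch -- and very low H3K27me3;
2. one highly occupied H3K4me3 apex <200 bp upstream, very low H3K27me3;
3. low occupancy of both marks around the TSS;
4. one low-occupancy H3K4me3 apex, very low H3K27me3.

Occupancy bands (density units, see signal.density_scale): high >= 200,
moderate [20, 200), low [10, 20), very low [0, 10).  A cluster matching
no category is assigned the one with fewest rule violations (ties to the
lower category number), with a warning.  Genes inherit the category of
their cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .signal import TssSignalMatrix, cpm_to_density

logger = logging.getLogger(__name__)


@dataclass
class ClusterRules:
    """Thresholds defining the four categories; defaults as conventionally printed."""

    high: float = 200.0
    moderate: float = 20.0
    low: float = 10.0
    downstream_shift_max: int = 200
    upstream_shift_max_c1: int = 400
    upstream_shift_max_c2: int = 200
    notch_ratio: float = 0.8  # local minimum below this fraction of the smaller apex
    summary_halfwidth: int = 500  # bp window around the TSS for occupancy summaries

    def band(self, density: float) -> str:
        if density >= self.high:
            return "high"
        if density >= self.moderate:
            return "moderate"
        if density >= self.low:
            return "low"
        return "verylow"


@dataclass
class RawClusters:
    """K-means output: per-gene labels plus per-cluster mean density profiles."""

    genes: list[str]
    labels: np.ndarray
    offsets: np.ndarray  # bin-center offsets relative to the TSS (bp)
    mean_k4: dict[int, np.ndarray]  # cluster id -> mean density profile
    mean_k27: dict[int, np.ndarray]
    inertia: float = 0.0


@dataclass
class ClusterAssignment:
    genes: list[str]
    kmeans_id: np.ndarray
    category: np.ndarray  # per gene, in {1,2,3,4}
    cluster_category: dict[int, int]
    proportions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.proportions:
            n = len(self.category)
            self.proportions = {
                c: float(np.count_nonzero(self.category == c)) / n if n else 0.0
                for c in (1, 2, 3, 4)
            }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "kmeans": self.kmeans_id, "category": self.category}
        ).set_index("gene")


def kmeans_cluster(
    m4: TssSignalMatrix,
    m27: TssSignalMatrix,
    genome_size: int,
    k: int = 8,
    seed: int = 0,
) -> RawClusters:
    """Cluster genes on row-max-scaled concatenated [K4 | K27] profiles.

    Each concatenated row is linearly scaled to its own maximum (rows
    with zero maximum are left as zeros) before k-means with ``k``
    clusters, 10 restarts and a fixed seed.  Cluster mean profiles are
    computed on the unscaled matrices in occupancy-density units,
    excluding masked (off-chromosome) cells.
    """
    if m4.genes != m27.genes:
        raise ValueError("matrices must share an identical gene order")
    n = len(m4.genes)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    joint = np.hstack([m4.values, m27.values])
    rowmax = joint.max(axis=1, keepdims=True)
    scaled = np.divide(joint, rowmax, out=np.zeros_like(joint), where=rowmax > 0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(scaled)

    to_density = cpm_to_density(genome_size)
    mean_k4: dict[int, np.ndarray] = {}
    mean_k27: dict[int, np.ndarray] = {}
    for cid in range(k):
        members = labels == cid
        if not members.any():
            continue
        mean_k4[cid] = _masked_mean(m4.values[members], m4.mask[members]) * to_density
        mean_k27[cid] = _masked_mean(m27.values[members], m27.mask[members]) * to_density
    offsets = m4.offsets + m4.bin // 2
    return RawClusters(
        genes=list(m4.genes),
        labels=labels,
        offsets=offsets,
        mean_k4=mean_k4,
        mean_k27=mean_k27,
        inertia=float(km.inertia_),
    )


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    denom = np.maximum(mask.sum(axis=0), 1)
    return (values * mask).sum(axis=0) / denom


# ---------------------------------------------------------------------------
# category rules
# ---------------------------------------------------------------------------


def _smooth(profile: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(profile, kernel, mode="same")


def _apexes(profile: np.ndarray, offsets: np.ndarray, halfwidth: int):
    """Local maxima of the smoothed profile within +/- halfwidth of the TSS.

    Returns a list of (offset, height) sorted by descending height, and a
    function giving the minimum profile value between two offsets.
    """
    sm = _smooth(profile)
    sel = np.abs(offsets) <= halfwidth
    idx = np.flatnonzero(sel)
    local = sm[idx]
    pk, _ = find_peaks(local)
    if len(pk) == 0 and len(local):
        pk = np.array([int(local.argmax())])
    apexes = sorted(
        ((int(offsets[idx[i]]), float(local[i])) for i in pk),
        key=lambda t: -t[1],
    )

    def valley(o1: int, o2: int) -> float:
        lo, hi = min(o1, o2), max(o1, o2)
        between = sm[(offsets >= lo) & (offsets <= hi)]
        return float(between.min()) if len(between) else 0.0

    return apexes, valley


def _window_mean(profile: np.ndarray, offsets: np.ndarray, halfwidth: int) -> float:
    sel = np.abs(offsets) <= halfwidth
    return float(profile[sel].mean()) if sel.any() else 0.0


def _dual_peak(apexes, valley, rules: ClusterRules):
    """Find a (downstream-main, upstream-secondary) apex pair with a notch."""
    for main_off, main_h in apexes[:3]:
        if not (0 < main_off < rules.downstream_shift_max):
            continue
        for sec_off, sec_h in apexes:
            if sec_off >= 0 or abs(sec_off) >= rules.upstream_shift_max_c1:
                continue
            smaller = min(main_h, sec_h)
            if valley(sec_off, main_off) < rules.notch_ratio * smaller:
                return (main_off, main_h), (sec_off, sec_h)
    return None


def _category_violations(
    k4: np.ndarray, k27: np.ndarray, offsets: np.ndarray, rules: ClusterRules
) -> dict[int, int]:
    """Rule-violation count for each category on one mean profile pair."""
    hw = rules.summary_halfwidth
    apexes, valley = _apexes(k4, offsets, hw)
    main_off, main_h = apexes[0] if apexes else (0, 0.0)
    k4_mean = _window_mean(k4, offsets, hw)
    k27_mean = _window_mean(k27, offsets, hw)
    dual = _dual_peak(apexes, valley, rules)
    k27_verylow = k27_mean < rules.low

    v: dict[int, int] = {}
    if dual:
        (d_off, d_h), (u_off, u_h) = dual
        c1 = [
            True,  # dual structure present
            d_h >= rules.high,
            rules.moderate <= u_h < rules.high,
            k27_verylow,
        ]
    else:
        c1 = [False, main_h >= rules.high, False, k27_verylow]
    v[1] = sum(not c for c in c1)
    c2 = [
        dual is None,
        main_h >= rules.high,
        # the shift rule is only meaningful for an actual (at least low-band) peak
        main_h >= rules.low and -rules.upstream_shift_max_c2 < main_off <= 0,
        k27_verylow,
    ]
    v[2] = sum(not c for c in c2)
    c3 = [
        rules.low <= k4_mean < rules.moderate,
        rules.low <= k27_mean < rules.moderate,
    ]
    v[3] = sum(not c for c in c3)
    c4 = [
        rules.low <= main_h < rules.moderate,
        k27_verylow,
    ]
    v[4] = sum(not c for c in c4)
    return v


def categorize(
    raw: RawClusters, rules: ClusterRules | None = None
) -> ClusterAssignment:
    """Assign each k-means cluster (and hence its genes) a category 1-4.

    Each cluster's mean profile pair is scored against the category
    definitions in order 1, 2, 3, 4; the first with no violated rule
    wins.  A cluster matching none is assigned the category with the
    fewest violations (ties to the lower number) with a warning.
    """
    rules = rules or ClusterRules()
    cluster_category: dict[int, int] = {}
    for cid in sorted(raw.mean_k4):
        v = _category_violations(raw.mean_k4[cid], raw.mean_k27[cid], raw.offsets, rules)
        exact = [c for c in (1, 2, 3, 4) if v[c] == 0]
        if exact:
            cluster_category[cid] = exact[0]
        else:
            best = min((1, 2, 3, 4), key=lambda c: (v[c], c))
            logger.warning(
                "cluster %d matches no category exactly (violations %s); assigned %d",
                cid,
                v,
                best,
            )
            cluster_category[cid] = best
    category = np.array([cluster_category[c] for c in raw.labels])
    return ClusterAssignment(
        genes=raw.genes,
        kmeans_id=raw.labels.copy(),
        category=category,
        cluster_category=cluster_category,
    )


def active_poised_fraction(assign: ClusterAssignment) -> tuple[float, float]:
    """(active-or-poised, weak-or-inactive) fractions: p(C1)+p(C2) and p(C3)+p(C4)."""
    p = assign.proportions
    return p.get(1, 0.0) + p.get(2, 0.0), p.get(3, 0.0) + p.get(4, 0.0)
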