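"""Synthetic ChIP-seq study generator with known per-gene truth.

Emulates the study design this package analyzes: a small multi-chromosome
genome; genes assigned to regulatory truth states (H3K4me3-only TSS,
H3K27me3-only TSS, bivalent TSS, H3K27me3 gene body, unmarked); narrow
TSS-proximal H3K4me3 pileups with a dual-peak/central-notch shape for
active promoters; broad H3K27me3 blocks over TSSs, gene bodies and
intergenic domains; a uniform input (control) track; two replicates per
mark; PCR-duplicate injection; and an expression count table whose group
means follow the state ordering
H3K4me3-only > bivalent > unmarked > H3K27me3-gene-body > H3K27me3-only.

Signal amplitudes are specified in occupancy-density units (see
``signal.density_scale``): one density unit is the coverage produced by
the reference sequencing rate of 10 M fragments per 468 Mb.  Defaults
put active-promoter apexes in the "high" band (>= 200), the dual peak's
upstream mate in the "moderate" band, and weak-promoter signal in the
"low" band (10-20), so the cluster categorizer's printed thresholds
apply unchanged.

Each fragment is reported as a single-end read: the fragment's 5' or 3'
end is sequenced with equal probability, so plus- and minus-strand read
5' ends sit one fragment length apart and the strand cross-correlation
curve peaks at the fragment length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import formats_io
from .formats_io import GeneModel, GenomeModel, PeakSet, TagCollection, make_peakset, make_tags
from .landscape import GeneState
from .signal import density_scale

STATES = [s.value for s in GeneState]

DEFAULT_STATE_PROPORTIONS = {
    GeneState.H3K4ME3_ONLY_TSS.value: 0.30,
    GeneState.H3K27ME3_ONLY_TSS.value: 0.08,
    GeneState.BIVALENT_TSS.value: 0.06,
    GeneState.H3K27ME3_GENE_BODY.value: 0.12,
    GeneState.UNMARKED.value: 0.44,
}

DEFAULT_EXPRESSION_MEANS = {
    GeneState.H3K4ME3_ONLY_TSS.value: 6.6,
    GeneState.BIVALENT_TSS.value: 3.8,
    GeneState.UNMARKED.value: 3.3,
    GeneState.H3K27ME3_GENE_BODY.value: 2.7,
    GeneState.H3K27ME3_ONLY_TSS.value: 2.1,
}


@dataclass
class SimConfig:
    """Study-design parameters of the simulation."""

    seed: int = 1
    n_chroms: int = 3
    chrom_length: int = 1_500_000
    n_genes: int = 500
    state_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PROPORTIONS)
    )
    fragment_length: int = 200
    read_length: int = 50
    depth_per_mark: int = 100_000
    duplicate_rate: float = 0.05
    background_rate: float = 0.0074  # background fragment starts per bp
    expression_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_MEANS)
    )
    expression_sd: float = 0.8
    rna_library_size: float = 5e6

    # signal-shape knobs (densities in occupancy-density units, offsets in
    # gene orientation relative to the TSS)
    k4_high_density: float = 220.0  # active-promoter main apex
    k4_moderate_density: float = 55.0  # dual peak's upstream mate (4x smaller)
    k4_low_density: float = 14.0  # weak-promoter apex (category 4)
    k27_tss_density: float = 15.0  # repressed-promoter H3K27me3 block
    k27_body_density: float = 25.0  # gene-body H3K27me3 domains
    peak_sigma: float = 75.0  # sd of fragment centers in narrow pileups
    main_offset: int = 100  # downstream apex of the dual peak
    secondary_offset: int = -300  # upstream apex of the dual peak
    c2_offset: int = -100  # single-apex promoters
    tss_block_halfwidth: int = 500
    body_margin: int = 2000  # gene-body domains start here, clear of the TSS window
    n_intergenic_domains: int = 30
    intergenic_domain_length: int = 3000
    # candidate-list knobs
    concordance: float = 0.8
    candidate_list_size: int = 150

    def __post_init__(self) -> None:
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state_proportions sum to {total}, expected 1")
        if self.fragment_length <= self.read_length:
            raise ValueError("fragment_length must exceed read_length")

    @property
    def genome_size(self) -> int:
        return self.n_chroms * self.chrom_length


@dataclass
class SimResult:
    """Everything the simulation produced, including the truth tables."""

    config: SimConfig
    genome: GenomeModel
    tags: dict[tuple[str, int], TagCollection]  # (mark|"input", replicate) -> tags
    truth_peaks: dict[str, PeakSet]  # mark -> truth intervals
    counts: pd.Series
    truth: pd.DataFrame  # index gene; state, category, expected_log2rpkm
    lists: dict[str, "object"]  # candidate gene lists (up/down/candidates)


# ---------------------------------------------------------------------------


def _allocate_states(rng: np.random.Generator, n: int, proportions: dict[str, float]):
    """Largest-remainder allocation of states to n genes, then shuffled."""
    items = sorted(proportions.items())
    raw = {s: p * n for s, p in items}
    counts = {s: int(math.floor(v)) for s, v in raw.items()}
    short = n - sum(counts.values())
    for s, _ in sorted(raw.items(), key=lambda kv: -(kv[1] - math.floor(kv[1])))[:short]:
        counts[s] += 1
    states = [s for s, c in counts.items() for _ in range(c)]
    rng.shuffle(states)
    return states


def _build_genome(rng: np.random.Generator, cfg: SimConfig, states: list[str]):
    """Place one gene per slot; extra slots host intergenic H3K27me3 domains."""
    n_slots = cfg.n_genes + cfg.n_intergenic_domains
    genes: list[GeneModel] = []
    domain_slots: list[tuple[str, int]] = []  # (chrom, slot start)
    chroms = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    if n_slots == 0:
        return GenomeModel(chroms=chroms, genes=[]), []
    slot_len = cfg.genome_size // n_slots
    order = np.arange(n_slots)
    domain_idx = set(
        rng.choice(n_slots, size=min(cfg.n_intergenic_domains, n_slots), replace=False)
    ) if cfg.n_intergenic_domains else set()
    gi = 0
    for slot in order:
        chrom_i = int(slot * slot_len // cfg.chrom_length)
        chrom_i = min(chrom_i, cfg.n_chroms - 1)
        chrom = f"chr{chrom_i + 1}"
        slot_start = int(slot * slot_len - chrom_i * cfg.chrom_length)
        if slot in domain_idx:
            domain_slots.append((chrom, slot_start))
            continue
        if gi >= cfg.n_genes:
            continue
        state = states[gi]
        if state == GeneState.H3K27ME3_GENE_BODY.value:
            length = int(rng.integers(4500, 6500))
        else:
            length = int(rng.integers(1500, 4000))
        margin = 600
        hi = max(slot_len - length - margin, margin + 1)
        start = slot_start + int(rng.integers(margin, hi))
        start = max(0, min(start, cfg.chrom_length - length - 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        # three exons with two introns; UTRs at the transcript ends
        cuts = np.sort(rng.integers(length // 6, 5 * length // 6, size=4))
        b = [start, start + int(cuts[0]), start + int(cuts[1]),
             start + int(cuts[2]), start + int(cuts[3]), end]
        exons = ((b[0], b[1]), (b[2], b[3]), (b[4], b[5]))
        utr_len = min(100, b[1] - b[0] - 1, b[5] - b[4] - 1)
        if strand == "+":
            utr5 = ((b[0], b[0] + utr_len),)
            utr3 = ((b[5] - utr_len, b[5]),)
        else:
            utr5 = ((b[5] - utr_len, b[5]),)
            utr3 = ((b[0], b[0] + utr_len),)
        genes.append(
            GeneModel(
                id=f"g{gi + 1:04d}", chrom=chrom, strand=strand, start=start, end=end,
                exons=exons, utr5=utr5, utr3=utr3,
            )
        )
        gi += 1
    return GenomeModel(chroms=chroms, genes=genes), domain_slots


def _assign_categories(rng: np.random.Generator, states: list[str]) -> list[int]:
    """Truth promoter category consistent with each gene's state."""
    cats = []
    for s in states:
        if s == GeneState.H3K4ME3_ONLY_TSS.value:
            cats.append(1 if rng.random() < 2 / 3 else 2)
        elif s == GeneState.BIVALENT_TSS.value:
            cats.append(1)
        elif s == GeneState.H3K27ME3_ONLY_TSS.value:
            cats.append(3)  # repressed promoters: low/absent H3K4me3 with H3K27me3
        else:  # gene-body-repressed and unmarked genes: weak or silent promoters
            cats.append(4)
    return cats


@dataclass
class _Component:
    """One fragment pileup: Gaussian peak or uniform block of fragment centers."""

    chrom: str
    kind: str  # "gauss" | "block"
    a: float  # gauss: center; block: start
    b: float  # gauss: sigma; block: end
    n_expected: float


def _gauss_n(count_at_apex: float, sigma: float, frag_len: int) -> float:
    """Fragments needed for an expected apex coverage count."""
    half = frag_len / 2
    frac = norm.cdf(half / sigma) - norm.cdf(-half / sigma)
    return count_at_apex / frac


def _block_n(count: float, width: float, frag_len: int) -> float:
    return count * width / frag_len


def _gene_components(cfg: SimConfig, genome: GenomeModel, truth: pd.DataFrame,
                     domain_slots, f: float):
    """Expected-intensity components per mark (density -> counts via 1/f)."""
    k4: list[_Component] = []
    k27: list[_Component] = []
    fl = cfg.fragment_length
    sig = cfg.peak_sigma
    for g in genome.genes:
        state = truth.loc[g.id, "state"]
        cat = truth.loc[g.id, "category"]
        sgn = 1 if g.strand == "+" else -1

        def at(offset: int) -> float:
            return g.tss + sgn * offset

        if state in (GeneState.H3K4ME3_ONLY_TSS.value, GeneState.BIVALENT_TSS.value):
            if cat == 1:
                k4.append(_Component(g.chrom, "gauss", at(cfg.main_offset), sig,
                                     _gauss_n(cfg.k4_high_density / f, sig, fl)))
                k4.append(_Component(g.chrom, "gauss", at(cfg.secondary_offset), sig,
                                     _gauss_n(cfg.k4_moderate_density / f, sig, fl)))
            else:
                k4.append(_Component(g.chrom, "gauss", at(cfg.c2_offset), sig,
                                     _gauss_n(cfg.k4_high_density / f, sig, fl)))
        elif state == GeneState.UNMARKED.value:
            if cfg.k4_low_density > 0 and truth.loc[g.id, "weak_peak"]:
                k4.append(_Component(g.chrom, "gauss", at(cfg.main_offset), sig,
                                     _gauss_n(cfg.k4_low_density / f, sig, fl)))
        if state in (GeneState.H3K27ME3_ONLY_TSS.value, GeneState.BIVALENT_TSS.value):
            hw = cfg.tss_block_halfwidth
            k27.append(_Component(g.chrom, "block", g.tss - hw, g.tss + hw,
                                  _block_n(cfg.k27_tss_density / f, 2 * hw, fl)))
        if state == GeneState.H3K27ME3_GENE_BODY.value:
            lo, hi = _body_domain(g, cfg)
            k27.append(_Component(g.chrom, "block", lo, hi,
                                  _block_n(cfg.k27_body_density / f, hi - lo, fl)))
    for chrom, slot_start in domain_slots:
        lo = slot_start + 500
        hi = min(lo + cfg.intergenic_domain_length, cfg.chrom_length)
        k27.append(_Component(chrom, "block", lo, hi,
                              _block_n(cfg.k27_body_density / f, hi - lo, fl)))
    return k4, k27


def _body_domain(g: GeneModel, cfg: SimConfig) -> tuple[int, int]:
    if g.strand == "+":
        lo, hi = g.tss + cfg.body_margin, g.end
    else:
        lo, hi = g.start, g.tss - cfg.body_margin
    if hi - lo < 500:  # degenerate short gene: keep a minimal domain
        lo, hi = min(lo, hi - 500), max(hi, lo + 500)
    return int(lo), int(hi)


def _emit_tags(rng: np.random.Generator, cfg: SimConfig, genome: GenomeModel,
               components: list[_Component],
               background_rate: float | None = None) -> TagCollection:
    """Draw fragments from components + uniform background, report reads."""
    chrom_arr: list[str] = []
    centers: list[np.ndarray] = []
    for comp in components:
        n = rng.poisson(comp.n_expected)
        if n == 0:
            continue
        if comp.kind == "gauss":
            c = rng.normal(comp.a, comp.b, size=n)
        else:
            c = rng.uniform(comp.a, comp.b, size=n)
        centers.append(c)
        chrom_arr.extend([comp.chrom] * n)
    # uniform background on every chromosome
    bg = cfg.background_rate if background_rate is None else background_rate
    for chrom, length in genome.chroms.items():
        n = rng.poisson(bg * length)
        if n:
            centers.append(rng.uniform(0, length, size=n))
            chrom_arr.extend([chrom] * n)
    if not centers:
        return make_tags([])
    center = np.concatenate(centers)
    chroms = np.array(chrom_arr)
    half = cfg.fragment_length // 2
    frag_start = np.round(center).astype(int) - half
    lengths = np.array([genome.chroms[c] for c in chroms])
    frag_start = np.clip(frag_start, 0, lengths - cfg.fragment_length)
    frag_end = frag_start + cfg.fragment_length
    plus = rng.random(len(center)) < 0.5
    start = np.where(plus, frag_start, frag_end - cfg.read_length)
    end = start + cfg.read_length
    strand = np.where(plus, "+", "-")
    df = pd.DataFrame({"chrom": chroms, "start": start, "end": end, "strand": strand})
    # PCR duplicates: append copies of randomly chosen tags
    n_dup = int(round(cfg.duplicate_rate * len(df)))
    if n_dup:
        dup = df.iloc[rng.integers(0, len(df), size=n_dup)]
        df = pd.concat([df, dup], ignore_index=True)
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    return TagCollection(df.reset_index(drop=True))


def _truth_peaks(cfg: SimConfig, genome: GenomeModel, truth: pd.DataFrame,
                 domain_slots) -> dict[str, PeakSet]:
    k4_rec, k27_rec = [], []
    for g in genome.genes:
        state = truth.loc[g.id, "state"]
        cat = truth.loc[g.id, "category"]
        sgn = 1 if g.strand == "+" else -1

        def span(lo_off: int, hi_off: int) -> tuple[int, int]:
            a, b = g.tss + sgn * lo_off, g.tss + sgn * hi_off
            return (min(a, b), max(a, b))

        if state in (GeneState.H3K4ME3_ONLY_TSS.value, GeneState.BIVALENT_TSS.value):
            if cat == 1:
                lo, hi = span(cfg.secondary_offset - 200, cfg.main_offset + 200)
            else:
                lo, hi = span(cfg.c2_offset - 250, cfg.c2_offset + 250)
            k4_rec.append((g.chrom, max(lo, 0), hi, 100.0, None))
        if state in (GeneState.H3K27ME3_ONLY_TSS.value, GeneState.BIVALENT_TSS.value):
            hw = cfg.tss_block_halfwidth
            k27_rec.append((g.chrom, max(g.tss - hw, 0), g.tss + hw, 100.0, None))
        if state == GeneState.H3K27ME3_GENE_BODY.value:
            lo, hi = _body_domain(g, cfg)
            k27_rec.append((g.chrom, max(lo, 0), hi, 100.0, None))
    for chrom, slot_start in domain_slots:
        lo = slot_start + 500
        hi = min(lo + cfg.intergenic_domain_length, cfg.chrom_length)
        k27_rec.append((chrom, lo, hi, 100.0, None))
    return {
        "H3K4me3": make_peakset(k4_rec, mark="H3K4me3", shape="narrow"),
        "H3K27me3": make_peakset(k27_rec, mark="H3K27me3", shape="broad"),
    }


def _expression(rng: np.random.Generator, cfg: SimConfig, genome: GenomeModel,
                truth: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    expected = []
    counts = []
    for g in genome.genes:
        state = truth.loc[g.id, "state"]
        log2rpkm = rng.normal(cfg.expression_means[state], cfg.expression_sd)
        lam = (2.0 ** log2rpkm) * g.exonic_length * cfg.rna_library_size / 1e9
        counts.append(int(rng.poisson(lam)))
        expected.append(log2rpkm)
    idx = genome.gene_ids()
    return (pd.Series(counts, index=idx, dtype=float, name="count"),
            pd.Series(expected, index=idx, name="expected_log2rpkm"))


def _candidate_lists(rng: np.random.Generator, cfg: SimConfig, truth: pd.DataFrame):
    from .flight_genes import CandidateGeneList

    # bivalent genes carry both marks and would blur the configured
    # concordance on either side, so the candidate pools exclude them
    k4_states = {GeneState.H3K4ME3_ONLY_TSS.value}
    k27_states = {GeneState.H3K27ME3_ONLY_TSS.value, GeneState.H3K27ME3_GENE_BODY.value}
    k4_genes = [g for g in truth.index if truth.loc[g, "state"] in k4_states]
    k27_genes = [g for g in truth.index if truth.loc[g, "state"] in k27_states]
    unmarked = [g for g in truth.index if truth.loc[g, "state"] == GeneState.UNMARKED.value]

    def take(pool: list[str], n: int) -> list[str]:
        n = min(n, len(pool))
        return list(rng.choice(pool, size=n, replace=False)) if n else []

    up: list[str] = []
    down: list[str] = []
    k4_members = take(k4_genes, cfg.candidate_list_size)
    n_conc = int(round(cfg.concordance * len(k4_members)))
    up.extend(k4_members[:n_conc])
    down.extend(k4_members[n_conc:])
    k27_members = take(k27_genes, cfg.candidate_list_size)
    n_conc = int(round(cfg.concordance * len(k27_members)))
    down.extend(k27_members[:n_conc])
    up.extend(k27_members[n_conc:])
    # wing-development-like list enriched in marked genes (80/20); it is an
    # independent hypothesis, so overlap with the up/down lists is allowed
    biv = [g for g in truth.index if truth.loc[g, "state"] == GeneState.BIVALENT_TSS.value]
    n_marked = int(round(0.8 * 40))
    wing = take(k4_genes + k27_genes + biv, n_marked) + take(unmarked, 40 - n_marked)
    return {
        "up": CandidateGeneList("upregulated", tuple(sorted(up)), source="synthetic"),
        "down": CandidateGeneList("downregulated", tuple(sorted(down)), source="synthetic"),
        "wing": CandidateGeneList("wing_development", tuple(sorted(wing)), source="synthetic"),
    }


def simulate(config: SimConfig | None = None) -> SimResult:
    """Run the full simulation for a configuration (deterministic per seed)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    states = _allocate_states(rng, cfg.n_genes, cfg.state_proportions)
    genome, domain_slots = _build_genome(rng, cfg, states)
    categories = _assign_categories(rng, states)
    weak = [
        s == GeneState.UNMARKED.value and c == 4 and rng.random() < 0.5
        for s, c in zip(states, categories)
    ]
    truth = pd.DataFrame(
        {"state": states, "category": categories, "weak_peak": weak},
        index=genome.gene_ids(),
    )
    f = density_scale(cfg.depth_per_mark, cfg.genome_size) if cfg.depth_per_mark else 1.0
    k4_comp, k27_comp = _gene_components(cfg, genome, truth, domain_slots, f)

    tags: dict[tuple[str, int], TagCollection] = {}
    for mark, comps in (("H3K4me3", k4_comp), ("H3K27me3", k27_comp)):
        # top the library up with extra uniform background so the realized
        # depth matches depth_per_mark and density calibration stays exact
        expected = sum(c.n_expected for c in comps)
        expected += cfg.background_rate * cfg.genome_size
        target = cfg.depth_per_mark / (1.0 + cfg.duplicate_rate)
        filler = max(0.0, target - expected) / max(cfg.genome_size, 1)
        for rep in (1, 2):
            tags[(mark, rep)] = _emit_tags(
                rng, cfg, genome, comps,
                background_rate=cfg.background_rate + filler,
            )
    for rep in (1, 2):
        tags[("input", rep)] = _emit_input(rng, cfg, genome)

    truth_peaks = _truth_peaks(cfg, genome, truth, domain_slots)
    counts, expected = _expression(rng, cfg, genome, truth)
    truth = truth.join(expected)
    lists = _candidate_lists(rng, cfg, truth)
    return SimResult(
        config=cfg, genome=genome, tags=tags, truth_peaks=truth_peaks,
        counts=counts, truth=truth.drop(columns=["weak_peak"]), lists=lists,
    )


def _emit_input(rng: np.random.Generator, cfg: SimConfig, genome: GenomeModel) -> TagCollection:
    """Uniform control track at the same depth as a ChIP replicate."""
    rate = cfg.depth_per_mark / max(genome.size, 1) if genome.size else 0.0
    return _emit_tags(rng, cfg, genome, [], background_rate=rate)


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------


def regenerate_fixture(
    seed: int,
    out_dir,
    config: SimConfig | None = None,
    write_fasta: bool = True,
) -> Path:
    """Write the complete fixture for a seed, deterministically, to a directory.

    Emits genome.gff3, genome.fa (random sequence), six tagAlign files,
    truth narrowPeak/broadPeak, counts.tsv, truth.tsv and the candidate
    gene lists.  The same seed always produces byte-identical files.
    """
    cfg = replace(config or SimConfig(), seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate(cfg)
    formats_io.write_gff3(result.genome, out / "genome.gff3")
    for (name, rep), tc in sorted(result.tags.items()):
        formats_io.write_tags(tc, out / f"{name}_rep{rep}.tagAlign")
    formats_io.write_peaks(result.truth_peaks["H3K4me3"], out / "truth_H3K4me3.narrowPeak")
    formats_io.write_peaks(result.truth_peaks["H3K27me3"], out / "truth_H3K27me3.broadPeak")
    with open(out / "counts.tsv", "w") as fh:
        for gene, c in result.counts.items():
            fh.write(f"{gene}\t{int(c)}\n")
    result.truth.to_csv(out / "truth.tsv", sep="\t")
    for key, lst in result.lists.items():
        with open(out / f"genes_{key}.tsv", "w") as fh:
            for g in lst.genes:
                fh.write(g + "\n")
    if write_fasta:
        rng = np.random.default_rng(seed + 7_000_003)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(result.genome.chroms):
                fh.write(f">{chrom}\n")
                length = result.genome.chroms[chrom]
                seq = rng.choice(list("ACGT"), size=length)
                line = "".join(seq)
                for i in range(0, length, 60):
                    fh.write(line[i : i + 60] + "\n")
    return out
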