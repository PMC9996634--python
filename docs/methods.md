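# Methods

`markscape` analyzes the promoter-centric regulatory landscape drawn by two
histone modifications — H3K4me3, a narrow mark of active promoters, and
H3K27me3, a broad repressive mark over gene bodies and intergenic domains —
from ChIP-seq tag alignments, replicate peak calls and a gene-level
expression table. This note describes the models and procedures, the
numerical choices, what the built-in synthetic study does and does not
emulate, and the known limitations.

## Coordinate conventions and gene models

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted on read and back-converted on write. Each gene is collapsed to one
representative transcript — the one with the largest summed exon length —
because every downstream statistic is computed at gene level. The TSS is the
gene start on the plus strand and `end − 1` on the minus strand; the gene
body is the full genomic span from TSS to TTS.

## Library QC

The QC panel follows the standard ENCODE-style metrics:

- **NRF** — distinct (chromosome, 5′ end, strand) tag positions over total
  tags; **PBC1** — one-read positions over distinct positions; **PBC2** —
  one-read over two-read positions. A library with no two-read positions
  reports PBC2 = +∞ (and passes the "> 1" gate, flagged).
- **Strand cross-correlation** — per candidate shift *k*, the Pearson
  correlation between plus-strand and *k*-shifted minus-strand 5′-end
  counts in 10-bp bins, pooled over chromosomes. 10-bp binning (rather than
  per-bp) keeps the scan fast at desk scale without moving the argmax by
  more than one bin. The fragment-length estimate is the argmax shift
  outside an exclusion zone of one read length either side of the read
  length, which prevents the read-length "phantom" peak from winning.
  NSC = cc(fragment)/min(cc); RSC = (cc(fragment) − min)/(cc(read length) −
  min). On unstructured input (e.g. a uniform synthetic control) the curve
  minimum reaches zero or below and the NSC ratio is not meaningful; it is
  then reported as +∞. Real chromatin always yields a positive baseline, so
  this situation itself signals that the library carries no positional
  structure.
- **FRiP** — the fraction of tags whose *midpoint* lies inside a peak.
  Midpoint membership gives each tag exactly one deterministic assignment,
  so FRiP over a partition of the genome sums to 1.
- **Replicate correlation** — Pearson and Spearman correlations of raw
  per-bin tag counts in non-overlapping 500-bp windows. Raw counts are used
  (no input subtraction); the report header says so. On sparse synthetic
  backgrounds most bins hold 0–3 tags, which makes the Spearman coefficient
  (rank-based, dominated by ties) much smaller than the Pearson one; the
  Pearson value is the meaningful replicate-agreement readout here.

Gate defaults: NRF ≥ 0.8 and FRiP ≥ 0.01 are inclusive ("at least"); PBC1
> 0.5, PBC2 > 1, NSC > 1.05 and RSC > 0.8 are strict ("higher than"). All
thresholds are configurable.

## Signal tracks and TSS matrices

Coverage extends each tag from its strand-aware 5′ end to the expected
fragment length (default 200 bp), counts extended-fragment overlaps per
10-bp bin, and scales by 1e6/library size (CPM). TSS matrices extract
±3 kb windows around every TSS, one row per gene, columns ordered 5′→3′ in
gene orientation (minus-strand rows are reversed, with a one-bin shift so
the TSS-containing bin maps to the offset-0 column). Cells whose window
hangs off a chromosome end are zero-filled and masked; masked cells are
excluded from cluster means rather than diluting them as zeros.

## Occupancy density units

The promoter-category rules use absolute occupancy bands (high ≥ 200,
moderate 20–200, low 10–20, very low < 10). Such absolute per-bin read
densities are meaningful only at a fixed sequencing rate, so the package
defines **density = per-bin fragment coverage rescaled to a reference rate
of 10 million fragments per 468 Mb of genome** (one fragment per 46.8 bp):
`density = CPM × genome_size / 46.8e6`. The unit is invariant to both
library depth and genome size, reduces to the plain 10M-library rescale on
a 468-Mb genome, and makes the printed band thresholds portable to the
desk-scale synthetic genome. `signal.density_scale` exposes the factor.

## Promoter-profile clustering and the four categories

Rows of the concatenated [H3K4me3 | H3K27me3] matrix are linearly scaled to
their own maximum (zero rows untouched) and clustered with k-means (10
restarts, fixed seed). The default is **k = 10**, deliberately larger than
the number of categories: k-means only has to isolate profile archetypes,
and the categorizer then maps each cluster's *mean density profile* onto
one of four categories, so several clusters may share a category. With k
forced to 4 the heterogeneous non-promoter archetypes (gene-body-marked,
silent) get merged into promoter clusters and recovery degrades.

Category rules, evaluated on each cluster's mean profile within ±500 bp of
the TSS (apexes are local maxima of the 5-bin-smoothed profile):

1. **Dual-peak active** — two H3K4me3 apexes: a high apex (< 200 bp
   downstream) and a moderate apex (< 400 bp upstream) separated by a
   central notch (the valley must fall below 80 % of the smaller apex),
   with very low H3K27me3.
2. **Single-peak active** — one high H3K4me3 apex < 200 bp upstream, very
   low H3K27me3. The position test is evaluated only when the apex is at
   least a low-band peak: the "position" of a noise apex (density ~2)
   carries no information, and without this guard silent clusters tie into
   category 2.
3. **Weakly marked** — both marks in the low band around the TSS.
4. **Weak/absent promoter mark** — a low-band H3K4me3 apex with very low
   H3K27me3.

Categories are tried in order 1→4; the first with zero violated rules wins.
A cluster matching none is assigned the category with the fewest violations
(ties to the lower number), with a warning. Genes inherit their cluster's
category; whether the underlying study categorized clusters or individual
genes is ambiguous, and cluster-level assignment is the choice here.

## Peak landscape

- **Stand-in caller** (plumbing; external narrowPeak/broadPeak files are
  the first-class input): sliding windows of 200 bp (narrow) or 1 kb
  (broad), stepped by half a window; a window is significant when its tag
  count beats a Poisson upper tail at p < 1e-5 against the maximum of the
  control-scaled window-local, 5-kb-local and genome-wide rates;
  significant windows merge within 100 bp (narrow) / 1 kb (broad); narrow
  peaks carry a summit at the maximum-coverage 10-bp bin. This is not a
  MACS2 reimplementation and makes no claim of numerical parity.
- **Reproducibility** replaces IDR for both marks: pooled replicate peaks
  are chained into maximal connected overlap groups; groups supported by
  both replicates are emitted as their union interval with the minimum
  member score.
- **Bivalent domains** are intersections of an H3K4me3 peak and an
  H3K27me3 peak of at least 100 bp — roughly one nucleosome. The domain
  interval is the intersection itself.
- **Feature annotation** classifies each peak by a single point (summit if
  present, else midpoint) with precedence promoter (TSS ± 1 kb) > 5′ UTR >
  3′ UTR > exon > intron > downstream (300 bp past the gene end) >
  intergenic. Point classification avoids the area-weighting question that
  interval classification would raise. The genome-wide null for the feature
  G-test classifies a 50-bp grid of points with the same rules.
- **G-test**: G = 2 Σ O·ln(O/E), zero observed cells contribute nothing,
  df = classes − 1, p from the χ² upper tail. No Williams correction. The
  2×2 independence variant takes expected counts from the marginals.
- **Gene states**: within TSS ± 1 kb, a gene is bivalent if a bivalent
  domain overlaps the window, else H3K4me3-only / H3K27me3-only by
  exclusive single-mark overlap; any gene whose body is overlapped by an
  H3K27me3 peak is additionally flagged gene-body-marked. The primary
  state follows the precedence bivalent > K4-only > K27-only > K27 gene
  body > unmarked. The state-assignment promoter window (±1 kb) is
  narrower than the TSS-matrix window (±3 kb); both are configurable.

## Expression linkage

RPKM = count × 1e9 / (library × summed exon length); log2(RPKM + 1) with a
pseudocount of 1, since the handling of zero counts is otherwise undefined.
When the count table covers a genome subset (as with the synthetic study),
the true sequencing library size should be passed explicitly — the default
(sum of supplied counts) would inflate RPKM by the subset factor. Group
comparisons use ordinary one-way ANOVA on log2 RPKM; group means are
reported with standard errors (sd/√n). Groups with fewer than two members
are excluded with a warning; zero within-group variance is flagged as
degenerate rather than reported as an F value. No post-hoc pairwise tests
are run. A gene is "poised" when its RPKM is strictly below 10.

## Candidate-list tests

Enrichment of marked genes in a curated list is a 2×2 G-test of
independence — (marked, unmarked) × (in list, rest of genome) — reported
with the signed difference of marked proportions as the direction.
Direction concordance takes the candidate genes carrying H3K4me3 at the
TSS and reports the fraction in the upregulated list, and likewise for
H3K27me3 (TSS or body) versus the downregulated list. Motif-discovery
input is the top 500 TSS-proximal peaks by score (ties broken by
chromosome, then start), each contributing the ±50 bp around its summit
as FASTA; windows clipped at chromosome ends are flagged in the header.

## The synthetic study

The generator emulates the study design end to end: a 3×1.5-Mb genome with
500 genes in regularly spaced slots (~9 kb per gene, matching a
one-gene-per-21-kb-scaled layout closely enough for isolated promoters);
truth states allocated by largest remainder at proportions 0.30 / 0.08 /
0.06 / 0.12 / 0.44 for H3K4me3-only, H3K27me3-only, bivalent,
H3K27me3-gene-body and unmarked; two replicates per mark plus two uniform
input libraries at 100k tags each.

Signal shapes, in density units so the category bands apply unchanged:

- Active promoters (H3K4me3-only, bivalent): two-thirds carry the
  dual-peak shape — a high apex (220) 100 bp downstream and a 4×-smaller
  moderate apex (55) 300 bp upstream, Gaussian σ = 75 bp of fragment
  centers — one-third a single high apex 100 bp upstream.
- Repressed promoters (H3K27me3-only): a low-band H3K27me3 block (15) over
  TSS ± 500 bp. This density is inside the printed "low" band *and* still
  reliably callable, because a 1-kb broad window integrates ~70 tags
  against a background λ of ~22.
- Gene-body repression: an H3K27me3 block (25) from TSS + 2 kb to the gene
  end (such genes are drawn 4.5–6.5 kb long). The 2-kb margin keeps the
  called broad peak — which can extend up to ~1 window beyond the signal —
  clear of the ±1 kb TSS window, so the state stays "gene body", not "TSS".
- Bivalency: the dual-peak H3K4me3 shape plus the H3K27me3 TSS block; the
  truth intervals overlap by ≥ 800 bp.
- Half of the unmarked genes carry a low-band H3K4me3 bump (14) that sits
  deliberately in the caller's stochastic zone — a realistic weak-promoter
  class; the miscall rate it induces (a few genes per study) is part of
  the noise budget.
- 30 intergenic H3K27me3 domains (3 kb, density 25) and a uniform
  background of 0.0074 fragment starts/bp everywhere. Each ChIP library is
  topped up with extra uniform background so its realized depth matches
  the nominal 100k; without the top-up, CPM-normalized densities drift off
  the calibrated bands by the depth shortfall.

Each fragment (200 bp) is reported as a 50-bp single-end read from a
randomly chosen end, so plus/minus read 5′ ends sit one fragment length
apart and the cross-correlation argmax lands at 190–200 bp (10-bp bin
resolution). PCR duplicates are injected by appending copies of randomly
chosen tags at the configured rate (default 5 %).

Expression: each gene's log2 RPKM is drawn Normal(state mean, 0.8) with
state means 6.6 / 3.8 / 3.3 / 2.7 / 2.1 for H3K4me3-only / bivalent /
unmarked / gene-body / H3K27me3-only — the ordering the analysis must
recover — and converted to a Poisson count at a nominal 5M-read RNA
library. Candidate lists: H3K4me3-only genes are allocated to the
"up" list at exactly the configured concordance (deterministic rounding,
default 0.8), H3K27me3 genes to "down" likewise; bivalent genes are
excluded from both pools because they carry both marks and would blur the
measured concordance. A 40-gene "wing-development" list samples marked
genes at 80/20 over unmarked.

What the generator does **not** emulate: base-level sequence composition,
mappability and GC bias, chromatin-state autocorrelation along the genome
(the background is white noise), copy-number structure, fragment-length
dispersion, and overlapping/nested genes. Consequently, passing recovery
tests demonstrate that the algorithms implement their definitions
correctly under the stated noise model — not that the pipeline is robust
to every artifact of real libraries.

Problem sizes were chosen so the full pipeline (six 100k-tag libraries,
500 genes) runs in well under a minute and the complete test suite in
about half a minute on one CPU.

## Numerical choices and degenerate inputs

- Single global RNG per simulation seed; k-means uses the same seed with
  10 restarts; reruns are bit-identical, and the pipeline's TSV outputs
  are byte-identical across reruns of the same configuration.
- Peak scores are −log10 of the best window p (floored at 1e-300);
  G-test p-values are floored at the smallest positive double.
- Empty peak sets, empty tag collections, zero-gene genomes, all-unmarked
  simulations and zero-variance correlation inputs are all defined: they
  return empty/zero/NaN-flagged results rather than raising, except where
  a computation is genuinely undefined (complexity of an empty library,
  ANOVA with fewer than two usable groups), which raises with a message.
- Tie-breaks are explicit everywhere ranking matters: category fallback
  (lower category number), motif ranking (score desc, then chromosome,
  then start), peak sorting (chromosome, start, end).

## Limitations

- The stand-in caller is a convenience for closed-loop testing; for real
  data, import MACS2/IDR outputs instead (the readers accept standard
  narrowPeak/broadPeak).
- Overlap-based reproducibility is laxer than IDR for narrow marks.
- Cluster-level categorization can mislabel individual genes whose
  profiles sit far from their cluster mean; recovery on synthetic data
  runs 97–100 %, and the residual is exactly this effect.
- The density unit presumes roughly uniform mappability; on real genomes
  with large unmappable fractions the effective genome size should be
  used for the rescale.
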