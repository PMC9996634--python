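"""End-to-end orchestration of the analysis stages.

Stage order: qc -> coverage -> tss_matrix -> cluster -> peaks ->
bivalent -> annotate -> states -> expression -> flight.  Every output
TSV carries a header with the package version, the seed and a parameter
hash; a rerun with the same configuration is byte-identical.  A failing
stage aborts the run with the stage named; its partial outputs keep a
``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, expression_link, flight_genes, formats_io, landscape
from . import qc_metrics as qc
from . import signal as sig
from . import synthetic_data, tss_clusters

logger = logging.getLogger("markscape.pipeline")

STAGES = [
    "qc",
    "coverage",
    "tss_matrix",
    "cluster",
    "peaks",
    "bivalent",
    "annotate",
    "states",
    "expression",
    "flight",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of a run.

    With ``simulate = true`` the synthetic generator provides every input
    from ``seed``; otherwise the explicit file paths are used.  Threshold
    defaults follow the conventional values used throughout the package.
    """

    out_dir: str = "markscape_out"
    seed: int = 1
    simulate: bool = True
    write_fixture: bool = False
    # external inputs (used when simulate is false)
    gff3: str | None = None
    fasta: str | None = None
    tags_h3k4me3: list[str] = field(default_factory=list)  # two replicates
    tags_h3k27me3: list[str] = field(default_factory=list)
    tags_input: list[str] = field(default_factory=list)
    counts: str | None = None
    genes_up: str | None = None
    genes_down: str | None = None
    genes_candidates: str | None = None
    # thresholds (defaults as conventionally printed)
    bin: int = 10
    extend: int = 200
    window: int = 3000
    promoter: int = 1000
    downstream: int = 300
    bivalent_min_overlap: int = 100
    kmeans_k: int = 10
    caller_pvalue: float = 1e-5
    rna_library_size: float | None = None
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def param_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        params = dataclasses.asdict(self)
        params.pop("out_dir", None)
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.ctx: dict = {}
        self._header = (
            f"markscape {__version__} seed={config.seed} params={config.param_hash()}"
        )

    # -- helpers ----------------------------------------------------------

    def _write_tsv(self, name: str, frame: pd.DataFrame, extra: list[str] = ()) -> None:
        path = self.out / name
        tmp = path.with_suffix(path.suffix + ".partial")
        with open(tmp, "w") as fh:
            fh.write(f"# {self._header}\n")
            for line in extra:
                fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t")
        tmp.rename(path)

    def _log(self, stage: str, message: str) -> None:
        logger.info("[%s] %s", stage, message)

    # -- inputs -----------------------------------------------------------

    def load_inputs(self) -> None:
        cfg = self.cfg
        self.out.mkdir(parents=True, exist_ok=True)
        snapshot = self.out / "config.json"
        snapshot.write_text(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, indent=2, default=str)
            + "\n"
        )
        if cfg.simulate:
            sim_cfg = synthetic_data.SimConfig(seed=cfg.seed, **cfg.sim)
            result = synthetic_data.simulate(sim_cfg)
            if cfg.write_fixture:
                synthetic_data.regenerate_fixture(
                    cfg.seed, self.out / "fixture", config=sim_cfg
                )
            self.ctx["genome"] = result.genome
            self.ctx["tags"] = result.tags
            self.ctx["counts"] = result.counts
            self.ctx["truth"] = result.truth
            self.ctx["lists"] = result.lists
            self.ctx["rna_library_size"] = (
                cfg.rna_library_size or sim_cfg.rna_library_size
            )
        else:
            if cfg.gff3 is None:
                raise PipelineError("stage inputs: no GFF3 given and simulate disabled")
            genome = formats_io.read_gff3(cfg.gff3)
            tags = {}
            for mark, paths in (
                ("H3K4me3", cfg.tags_h3k4me3),
                ("H3K27me3", cfg.tags_h3k27me3),
                ("input", cfg.tags_input),
            ):
                if len(paths) != 2:
                    raise PipelineError(
                        f"stage inputs: expected two {mark} tag files, got {len(paths)}"
                    )
                for rep, p in enumerate(paths, start=1):
                    tags[(mark, rep)] = formats_io.read_tags(p, "tagAlign", genome)
            self.ctx["genome"] = genome
            self.ctx["tags"] = tags
            self.ctx["counts"] = (
                formats_io.read_counts(cfg.counts) if cfg.counts else None
            )
            lists = {}
            for key, p in (
                ("up", cfg.genes_up),
                ("down", cfg.genes_down),
                ("wing", cfg.genes_candidates),
            ):
                if p:
                    lists[key] = formats_io.read_gene_list(p, name=key)
            self.ctx["lists"] = lists
            self.ctx["rna_library_size"] = cfg.rna_library_size

    # -- stages -----------------------------------------------------------

    def stage_qc(self) -> None:
        tags = self.ctx["tags"]
        genome = self.ctx["genome"]
        reports: dict[str, qc.QcReport] = {}
        for (mark, rep), tc in sorted(tags.items()):
            rep_name = f"{mark}_rep{rep}"
            report = qc.QcReport()
            if tc.library_size:
                report.nrf, report.pbc1, report.pbc2 = qc.library_complexity(tc)
                strands = set(tc.df["strand"])
                if {"+", "-"} <= strands:
                    _, report.frag_len_est, report.nsc, report.rsc = qc.cross_correlation(tc)
            reports[rep_name] = report
        for mark in ("H3K4me3", "H3K27me3", "input"):
            a, b = tags.get((mark, 1)), tags.get((mark, 2))
            if a is not None and b is not None and a.library_size and b.library_size:
                pcc, scc = qc.replicate_correlation(a, b, genome)
                for rep in (1, 2):
                    reports[f"{mark}_rep{rep}"].pcc = pcc
                    reports[f"{mark}_rep{rep}"].scc = scc
        for report in reports.values():
            qc.qc_gate(report)
        self.ctx["qc_reports"] = reports
        self._write_qc()
        self._log("qc", f"{len(reports)} libraries")

    def _write_qc(self) -> None:
        frames = []
        for name, report in sorted(self.ctx["qc_reports"].items()):
            frame = report.to_frame()
            frame.insert(0, "library", name)
            frames.append(frame)
        table = pd.concat(frames, ignore_index=True).set_index("library")
        self._write_tsv(
            "qc_report.tsv", table, ["replicate correlations computed on raw counts"]
        )

    def stage_coverage(self) -> None:
        genome = self.ctx["genome"]
        cfg = self.cfg
        tracks = {}
        for mark in ("H3K4me3", "H3K27me3", "input"):
            tc = self.ctx["tags"].get((mark, 1))
            if tc is None:
                continue
            track = sig.coverage(tc, genome, bin=cfg.bin, extend=cfg.extend)
            tracks[mark] = track
            path = self.out / f"coverage_{mark}.bedGraph.partial"
            formats_io.write_bedgraph(track, path)
            path.rename(self.out / f"coverage_{mark}.bedGraph")
        self.ctx["tracks"] = tracks
        self._log("coverage", f"{len(tracks)} tracks, bin={cfg.bin} extend={cfg.extend}")

    def stage_tss_matrix(self) -> None:
        genome = self.ctx["genome"]
        matrices = {}
        for mark in ("H3K4me3", "H3K27me3"):
            track = self.ctx["tracks"][mark]
            m = sig.tss_matrix(track, genome, window=self.cfg.window, mark=mark)
            matrices[mark] = m
            path = self.out / f"tss_matrix_{mark}.tsv.partial"
            sig.write_matrix_tsv(m, path)
            path.rename(self.out / f"tss_matrix_{mark}.tsv")
        self.ctx["matrices"] = matrices
        self._log("tss_matrix", f"{len(genome.genes)} genes x {2 * self.cfg.window // self.cfg.bin} bins")

    def stage_cluster(self) -> None:
        genome = self.ctx["genome"]
        if not genome.genes:
            self.ctx["assignment"] = None
            self._log("cluster", "no genes; skipped")
            return
        m4 = self.ctx["matrices"]["H3K4me3"]
        m27 = self.ctx["matrices"]["H3K27me3"]
        k = min(self.cfg.kmeans_k, len(genome.genes))
        raw = tss_clusters.kmeans_cluster(
            m4, m27, genome.size, k=k, seed=self.cfg.seed
        )
        assignment = tss_clusters.categorize(raw)
        self.ctx["assignment"] = assignment
        active, inactive = tss_clusters.active_poised_fraction(assignment)
        props = assignment.proportions
        self._write_tsv(
            "clusters.tsv",
            assignment.to_frame(),
            [
                "category proportions: "
                + " ".join(f"C{c}={props[c]:.4f}" for c in (1, 2, 3, 4)),
                f"active_or_poised={active:.4f} weak_or_inactive={inactive:.4f}",
            ],
        )
        self._log("cluster", f"k={k}, proportions {props}")

    def stage_peaks(self) -> None:
        genome = self.ctx["genome"]
        tags = self.ctx["tags"]
        control_parts = [
            tags[k].df for k in (("input", 1), ("input", 2)) if k in tags and tags[k].library_size
        ]
        control = (
            formats_io.TagCollection(pd.concat(control_parts, ignore_index=True))
            if control_parts
            else None
        )
        called: dict[tuple[str, int], landscape.PeakSet] = {}
        for mark, shape in (("H3K4me3", "narrow"), ("H3K27me3", "broad")):
            for rep in (1, 2):
                called[(mark, rep)] = landscape.standin_call_peaks(
                    tags[(mark, rep)], control, genome, shape=shape,
                    pvalue=self.cfg.caller_pvalue, mark=mark,
                )
        reproducible = {
            mark: landscape.reproducible_peaks(called[(mark, 1)], called[(mark, 2)])
            for mark in ("H3K4me3", "H3K27me3")
        }
        self.ctx["called"] = called
        self.ctx["peaks"] = reproducible
        for (mark, rep), ps in sorted(called.items()):
            ext = "narrowPeak" if ps.shape == "narrow" else "broadPeak"
            path = self.out / f"peaks_{mark}_rep{rep}.{ext}.partial"
            formats_io.write_peaks(ps, path)
            path.rename(self.out / f"peaks_{mark}_rep{rep}.{ext}")
        for mark, ps in sorted(reproducible.items()):
            ext = "narrowPeak" if ps.shape == "narrow" else "broadPeak"
            path = self.out / f"peaks_{mark}_reproducible.{ext}.partial"
            formats_io.write_peaks(ps, path)
            path.rename(self.out / f"peaks_{mark}_reproducible.{ext}")
        # FRiP against each replicate's own peaks completes the QC report
        for (mark, rep), ps in called.items():
            report = self.ctx["qc_reports"].get(f"{mark}_rep{rep}")
            if report is not None and tags[(mark, rep)].library_size:
                report.frip = qc.frip(tags[(mark, rep)], ps)
                qc.qc_gate(report)
        self._write_qc()
        self._log(
            "peaks",
            " ".join(f"{m}={len(p)}" for m, p in sorted(reproducible.items())),
        )

    def stage_bivalent(self) -> None:
        biv = landscape.detect_bivalent(
            self.ctx["peaks"]["H3K4me3"],
            self.ctx["peaks"]["H3K27me3"],
            min_overlap=self.cfg.bivalent_min_overlap,
        )
        self.ctx["bivalent"] = biv
        path = self.out / "bivalent_domains.bed.partial"
        with open(path, "w") as fh:
            for i, row in enumerate(biv.df.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tbivalent_{i + 1}\n")
        path.rename(self.out / "bivalent_domains.bed")
        self._log("bivalent", f"{len(biv)} domains")

    def stage_annotate(self) -> None:
        genome = self.ctx["genome"]
        rows = []
        for mark in ("H3K4me3", "H3K27me3"):
            ann = landscape.annotate_peaks(
                self.ctx["peaks"][mark], genome,
                promoter=self.cfg.promoter, downstream=self.cfg.downstream,
            )
            ann.insert(0, "mark", mark)
            rows.append(ann)
        table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        self.ctx["annotation"] = table
        extra = []
        if len(table) and genome.genes:
            null = landscape.feature_null_proportions(
                genome, promoter=self.cfg.promoter, downstream=self.cfg.downstream
            )
            for mark in ("H3K4me3", "H3K27me3"):
                obs = (
                    table[table["mark"] == mark]["feature"]
                    .value_counts()
                    .reindex(formats_io.FEATURE_CLASSES, fill_value=0)
                )
                if obs.sum() == 0:
                    continue
                nonzero = {c: p for c, p in null.items() if p > 0 or obs[c] == 0}
                res = landscape.gtest_features(
                    obs[list(nonzero)], pd.Series(nonzero) / sum(nonzero.values())
                )
                extra.append(
                    f"{mark} feature G-test: G={res.g:.4g} df={res.df} p={res.p:.4g}"
                )
        self._write_tsv("annotation.tsv", table, extra)
        self._log("annotate", f"{len(table)} peaks annotated")

    def stage_states(self) -> None:
        states = landscape.assign_gene_states(
            self.ctx["peaks"]["H3K4me3"],
            self.ctx["peaks"]["H3K27me3"],
            self.ctx["bivalent"],
            self.ctx["genome"],
            promoter=self.cfg.promoter,
        )
        assignment = self.ctx.get("assignment")
        if assignment is not None:
            states = states.join(assignment.to_frame()[["category"]])
        self.ctx["states"] = states
        self._write_tsv("states.tsv", states)
        counts = states["state"].value_counts().to_dict() if len(states) else {}
        self._log("states", f"{counts}")

    def stage_expression(self) -> None:
        counts = self.ctx.get("counts")
        genome = self.ctx["genome"]
        if counts is None or not len(counts):
            self.ctx["expr"] = None
            self._log("expression", "no counts; skipped")
            return
        expr = expression_link.rpkm(
            counts, genome, library_size=self.ctx.get("rna_library_size")
        )
        expr["poised"] = expression_link.poised_flag(expr)
        states = self.ctx["states"]
        expr = expr.join(states[["state"]])
        extra = []
        try:
            anova = expression_link.group_anova(expr, expr["state"])
            self.ctx["anova"] = anova
            order = anova.group_stats.sort_values("mean", ascending=False)
            extra.append(
                "state means (log2 RPKM): "
                + " ".join(f"{s}={m:.3f}" for s, m in order["mean"].items())
            )
            extra.append(
                f"ANOVA F={anova.f:.4g} df=({anova.df_between},{anova.df_within}) "
                f"p={anova.p:.4g}"
            )
        except ValueError:
            self.ctx["anova"] = None
        self.ctx["expr"] = expr
        self._write_tsv("expression.tsv", expr, extra)
        self._log("expression", extra[0] if extra else f"{len(expr)} genes")

    def stage_flight(self) -> None:
        states = self.ctx["states"]
        lists = self.ctx.get("lists") or {}
        genome = self.ctx["genome"]
        rows = []
        wing = lists.get("wing")
        if wing is not None and len(states):
            overlap, res, direction = flight_genes.category_enrichment(
                states, wing, genome
            )
            rows.append(
                {
                    "test": f"enrichment:{wing.name}", "n_list": len(wing),
                    "overlap": overlap, "G": res.g, "df": res.df, "p": res.p,
                    "direction": direction,
                }
            )
        up, down = lists.get("up"), lists.get("down")
        if up is not None and down is not None and len(states):
            k4_up, k27_down = flight_genes.direction_concordance(states, up, down)
            rows.append(
                {"test": "concordance:H3K4me3_up", "n_list": len(up), "overlap": None,
                 "G": None, "df": None, "p": None, "direction": k4_up}
            )
            rows.append(
                {"test": "concordance:H3K27me3_down", "n_list": len(down), "overlap": None,
                 "G": None, "df": None, "p": None, "direction": k27_down}
            )
        table = pd.DataFrame(rows).set_index("test") if rows else pd.DataFrame()
        self._write_tsv("flight.tsv", table)
        if self.cfg.fasta:
            import pyfaidx

            seqs = pyfaidx.Fasta(self.cfg.fasta)
            path = self.out / "motif_input.fa.partial"
            flight_genes.motif_input(
                self.ctx["peaks"]["H3K4me3"], seqs, genome, out_path=path
            )
            path.rename(self.out / "motif_input.fa")
        self._log("flight", f"{len(rows)} tests")

    # -- driver -----------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> Path:
        wanted = stages or STAGES
        unknown = set(wanted) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        try:
            self.load_inputs()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage inputs failed: {exc}") from exc
        for name in STAGES:
            if name not in wanted:
                continue
            method = getattr(self, f"stage_{name}")
            try:
                method()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return self.out


def run_all(
    config: PipelineConfig, stages: list[str] | None = None, log_file=None
) -> Path:
    """Run the pipeline; returns the output directory."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    for h in handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(logging.INFO)
    try:
        return Pipeline(config).run(stages=stages)
    finally:
        for h in handlers:
            logger.removeHandler(h)
            h.close()
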