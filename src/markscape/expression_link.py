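"""Linking modification states to expression: RPKM, group means and
one-way ANOVA across state or cluster groups, and the poised-gene flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GenomeModel

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_stats: pd.DataFrame  # index: group; columns: n, mean, se
    degenerate: bool = False  # zero within-group variance


def rpkm(
    counts: pd.Series,
    genome: GenomeModel,
    library_size: float | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, and log2(RPKM + 1).

    Gene length is the summed exon length of the representative
    transcript.  ``library_size`` defaults to the sum of the supplied
    counts; pass the sequencing library total when the count table is a
    genome subset.
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(
        {g.id: g.exonic_length for g in genome.genes}, dtype=float
    ).reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise KeyError(f"counts for genes absent from the genome model: {missing}")
    if (lengths <= 0).any():
        raise ValueError("zero-length gene in RPKM computation")
    lib = float(library_size) if library_size is not None else float(counts.sum())
    if lib <= 0:
        raise ValueError("library size must be positive")
    vals = counts * 1e9 / (lib * lengths)
    return pd.DataFrame(
        {
            "count": counts,
            "rpkm": vals,
            "log2_rpkm": np.log2(vals + PSEUDOCOUNT),
        }
    )


def group_anova(expr: pd.DataFrame, groups: pd.Series | dict) -> AnovaResult:
    """One-way ANOVA of log2 RPKM across gene groups, with means +/- SE.

    Groups with fewer than two members are excluded (warning); at least
    two groups must remain.  Zero within-group variance is flagged as
    degenerate (F undefined).
    """
    groups = pd.Series(groups)
    values = expr["log2_rpkm"].reindex(groups.index).dropna()
    groups = groups.reindex(values.index)
    samples: dict[str, np.ndarray] = {}
    for label, sub in values.groupby(groups):
        if len(sub) < 2:
            logger.warning("group_anova: group %r has <2 members; excluded", label)
            continue
        samples[label] = sub.to_numpy()
    if len(samples) < 2:
        raise ValueError("group_anova: fewer than two usable groups")
    arrays = list(samples.values())
    stats_rows = {
        label: {
            "n": len(arr),
            "mean": float(arr.mean()),
            "se": float(arr.std(ddof=1) / math.sqrt(len(arr))),
        }
        for label, arr in samples.items()
    }
    group_stats = pd.DataFrame(stats_rows).T[["n", "mean", "se"]]
    group_stats["n"] = group_stats["n"].astype(int)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0:
        logger.warning("group_anova: zero within-group variance; F undefined")
        return AnovaResult(
            f=math.nan,
            df_between=df_between,
            df_within=df_within,
            p=math.nan,
            group_stats=group_stats,
            degenerate=True,
        )
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(
        f=float(f),
        df_between=df_between,
        df_within=df_within,
        p=float(p),
        group_stats=group_stats,
    )


def poised_flag(expr: pd.DataFrame, threshold: float = 10.0) -> pd.Series:
    """Poised genes: transcript level strictly below ``threshold`` RPKM."""
    return expr["rpkm"] < threshold


def write_anova_tsv(result: AnovaResult, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("group\tn\tmean\tse\n")
        for label, row in result.group_stats.iterrows():
            fh.write(f"{label}\t{int(row['n'])}\t{row['mean']:.6g}\t{row['se']:.6g}\n")
        fh.write(f"# F={result.f:.6g} df=({result.df_between},{result.df_within}) "
                 f"p={result.p:.6g}\n")
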