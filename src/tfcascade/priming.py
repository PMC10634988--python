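"""Bulk RNA/ATAC integration: are injury-induced genes already accessible?

Early-response genes are selected from a pre/post-injury bulk expression
table (silent before, upregulated after).  Chromatin accessibility is
quantified as CPM-normalized fragment counts in a window around each TSS,
and each gene is classified by the accessibility log2 fold change after
injury:

- ``primed``: induced, pre-accessible, |log2FC| within the +-0.5 window —
  the chromatin was open before the gene turned on;
- ``induced_accessible``: induced with log2FC > 0.5 from a closed start —
  accessibility arrives with expression;
- ``constitutive``: accessible but not induced;
- ``silent_closed``: everything else.

All genomic intervals are handled 0-based half-open (BED convention);
1-based TSS annotations are converted at the boundary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges as pr
from scipy.stats import median_abs_deviation

logger = logging.getLogger(__name__)

__all__ = [
    "select_early_response",
    "tss_windows",
    "count_fragments",
    "tss_profile",
    "accessibility_lfc",
    "accessibility_floor",
    "classify_priming",
    "control_gene_sets",
]

#: defaults for the early-response predicate (configuration, not estimates):
#: silent pre-injury means expr_pre <= 1 (RPKM-like), upregulated means
#: log2FC >= 1 at FDR <= 0.05.
BASELINE_MAX = 1.0
LFC_MIN = 1.0
FDR_MAX = 0.05
WINDOW_THRESHOLD = 0.5
PSEUDOCOUNT = 1.0
DEFAULT_FLANK = 2_000

PRIMING_CLASSES = ("primed", "induced_accessible", "constitutive", "silent_closed")


def select_early_response(
    expr: pd.DataFrame,
    baseline_max: float = BASELINE_MAX,
    lfc_min: float = LFC_MIN,
    fdr_max: float = FDR_MAX,
) -> set[str]:
    """Genes silent pre-injury and significantly upregulated post-injury."""
    required = {"gene", "expr_pre", "lfc", "fdr"}
    missing = required - set(expr.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    keep = (
        (expr["expr_pre"] <= baseline_max)
        & (expr["lfc"] >= lfc_min)
        & (expr["fdr"] <= fdr_max)
    )
    return set(expr.loc[keep, "gene"])


def tss_windows(annotation: pd.DataFrame, flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Symmetric windows around each TSS as 0-based half-open intervals.

    ``annotation`` carries gene, chrom, tss (1-based), strand.  Windows
    extending below position 0 are clipped (logged); strand is kept for
    profile orientation.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns {sorted(missing)}")
    bad = ~annotation["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("strand must be '+' or '-'")
    tss0 = annotation["tss"].to_numpy(dtype=int) - 1  # to 0-based
    start = tss0 - flank
    clipped = start < 0
    if clipped.any():
        logger.info("clipped %d windows at position 0", int(clipped.sum()))
    return pd.DataFrame(
        {
            "gene": annotation["gene"].to_numpy(),
            "chrom": annotation["chrom"].to_numpy(),
            "start": np.maximum(start, 0),
            "end": tss0 + flank,
            "strand": annotation["strand"].to_numpy(),
            "tss0": tss0,
        }
    )


def _as_pyranges(df: pd.DataFrame, extra: list[str] | None = None) -> pr.PyRanges:
    cols = {"Chromosome": df["chrom"], "Start": df["start"], "End": df["end"]}
    for c in extra or []:
        cols[c] = df[c]
    return pr.PyRanges(pd.DataFrame(cols))


def read_bed(path) -> pd.DataFrame:
    """Read the first three columns of a BED file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    if not (np.issubdtype(df["start"].dtype, np.integer) and np.issubdtype(df["end"].dtype, np.integer)):
        bad = df[~df["start"].astype(str).str.fullmatch(r"\d+")].index
        raise ValueError(f"{path}: malformed BED line {int(bad[0]) + 1 if len(bad) else '?'}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def count_fragments(
    fragments: pd.DataFrame,
    windows: pd.DataFrame,
    normalize: bool = True,
) -> pd.DataFrame:
    """Fragments overlapping (>= 1 bp) each window, optionally CPM-normalized.

    CPM uses the total number of fragments in the library, not only those
    overlapping a window; an empty library yields zero CPM everywhere.
    """
    out = windows[["gene", "chrom", "start", "end"]].copy()
    if fragments.empty:
        out["count"] = 0
        if normalize:
            out["cpm"] = 0.0
        return out
    win = _as_pyranges(windows, extra=["gene"])
    frag = _as_pyranges(fragments)
    counted = win.count_overlaps(frag).df
    counts = counted.set_index("gene")["NumberOverlaps"]
    out["count"] = counts.loc[out["gene"]].to_numpy()
    if normalize:
        out["cpm"] = out["count"] * 1e6 / len(fragments)
    return out


def tss_profile(
    fragments: pd.DataFrame,
    windows: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Fragment-start counts in position bins around each TSS.

    Rows are bin offsets relative to the TSS (upstream negative), columns
    genes; minus-strand genes are mirrored so upstream/downstream are
    comparable across strands.
    """
    if (2 * flank) % bin_size:
        raise ValueError("bin size must divide the window width")
    n_bins = 2 * flank // bin_size
    offsets = -flank + bin_size * np.arange(n_bins)
    arr = np.zeros((n_bins, len(windows)), dtype=int)
    by_chrom = {c: np.sort(sub["start"].to_numpy()) for c, sub in fragments.groupby("chrom")}
    for ci, (_, w) in enumerate(windows.iterrows()):
        starts = by_chrom.get(w["chrom"])
        if starts is None:
            continue
        sel = starts[(starts >= w["tss0"] - flank) & (starts < w["tss0"] + flank)]
        rel = sel - w["tss0"]
        if w["strand"] == "-":
            rel = -rel - 1  # mirror; keeps rel in [-flank, flank)
        np.add.at(arr[:, ci], (rel + flank) // bin_size, 1)
    return pd.DataFrame(arr, index=offsets, columns=windows["gene"].to_numpy())


def accessibility_lfc(
    acc_pre: pd.Series | np.ndarray,
    acc_post: pd.Series | np.ndarray,
    pseudocount: float = PSEUDOCOUNT,
) -> np.ndarray:
    """log2 accessibility fold change with a CPM pseudocount."""
    return np.log2(
        (np.asarray(acc_post, dtype=float) + pseudocount)
        / (np.asarray(acc_pre, dtype=float) + pseudocount)
    )


def accessibility_floor(acc: pd.DataFrame, silent_genes: set[str]) -> float:
    """Data-adaptive open-chromatin floor: median + 2 MADs of the silent
    controls' pre-injury CPM."""
    vals = acc.loc[acc["gene"].isin(silent_genes), "acc_pre"].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("no silent control genes found in the accessibility table")
    return float(np.median(vals) + 2.0 * median_abs_deviation(vals))


def classify_priming(
    expr: pd.DataFrame,
    acc: pd.DataFrame,
    accessibility_floor: float,
    window_threshold: float = WINDOW_THRESHOLD,
    baseline_max: float = BASELINE_MAX,
    lfc_min: float = LFC_MIN,
    fdr_max: float = FDR_MAX,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Join expression and accessibility tables and assign priming classes.

    ``expr`` needs gene, expr_pre, lfc, fdr; ``acc`` needs gene, acc_pre,
    acc_post (CPM).  Genes present in only one table are excluded (logged).
    """
    merged = expr.merge(acc[["gene", "acc_pre", "acc_post"]], on="gene", how="inner")
    n_dropped = len(set(expr["gene"]).symmetric_difference(acc["gene"]))
    if n_dropped:
        logger.info("excluded %d genes present in only one table", n_dropped)
    induced_set = select_early_response(merged, baseline_max, lfc_min, fdr_max)
    merged["induced"] = merged["gene"].isin(induced_set)
    merged["acc_lfc"] = accessibility_lfc(merged["acc_pre"], merged["acc_post"], pseudocount)

    open_pre = merged["acc_pre"] >= accessibility_floor
    stable = merged["acc_lfc"].abs() <= window_threshold
    opening = merged["acc_lfc"] > window_threshold
    cls = np.select(
        [
            merged["induced"] & stable & open_pre,
            merged["induced"] & opening,
            ~merged["induced"] & open_pre,
        ],
        ["primed", "induced_accessible", "constitutive"],
        default="silent_closed",
    )
    merged["class"] = cls
    return merged[["gene", "induced", "acc_pre", "acc_post", "acc_lfc", "class"]]


def control_gene_sets(
    expr: pd.DataFrame,
    high_quantile: float = 0.1,
    silent_ids: set[str] | None = None,
    baseline_max: float = BASELINE_MAX,
) -> tuple[set[str], set[str]]:
    """Positive/negative control gene sets from a bulk expression table.

    The high set is the top ``high_quantile`` fraction of pre-injury
    expression; the silent set is the supplied identifier set (e.g.
    olfactory receptor symbols) restricted to genes below the baseline
    expression floor.
    """
    if not 0 < high_quantile <= 1:
        raise ValueError("high_quantile must be in (0, 1]")
    cutoff = expr["expr_pre"].quantile(1.0 - high_quantile)
    high = set(expr.loc[expr["expr_pre"] >= cutoff, "gene"])
    if not silent_ids:
        logger.warning("empty silent identifier set; silent controls empty")
        return high, set()
    silent = set(
        expr.loc[expr["gene"].isin(silent_ids) & (expr["expr_pre"] <= baseline_max), "gene"]
    )
    return high, silent
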