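"""Derivative-based transcription-factor cascade analysis.

Given fitted NB spline smoothers, the first derivative of each smoother is
approximated by central finite differences on a grid of J equally spaced
pseudotimes per lineage.  At each grid point a thresholded statistic

    T_glj = max(0, delta_glj - c) / se_glj        (default c = 0.1)

is referenced to a standard normal, one-sided; Benjamini-Hochberg
adjustment is applied across the J grid points within each (gene, lineage).
A gene is *involved* in a lineage when its minimum adjusted p-value falls
below alpha.  Its expression peak is the first zero crossing of the
derivative after the most significant grid point, localized by linear
interpolation; a derivative that never crosses zero puts the peak at the
lineage end.

On top of the per-gene records the module orders TFs into a cascade matrix,
classifies TFs as lineage-specific (1.5x smoother-maximum rule) or shared
(peak-time spread < 1 pseudotime unit), clusters cascade rows, and scores
cluster membership against named gene sets with hypergeometric tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

from .nbgam import GeneFit, build_basis, predict_smoother

logger = logging.getLogger(__name__)

__all__ = [
    "DerivativeGrid",
    "PeakRecord",
    "bh_adjust",
    "estimate_derivatives",
    "derivative_test",
    "detect_peak",
    "test_gene",
    "cascade_table",
    "build_cascade",
    "lineage_specific_tfs",
    "shared_tfs",
    "cluster_cascade",
    "enrich_hypergeom",
]

DEFAULT_J = 100
DEFAULT_EPSILON = 1e-7
DEFAULT_C = 0.1
DEFAULT_ALPHA = 0.05


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


@dataclass
class DerivativeGrid:
    """Gridwise derivative estimates and test results for one (gene, lineage)."""

    gene: str
    lineage: int
    grid: np.ndarray
    delta: np.ndarray
    se: np.ndarray
    epsilon: float
    boundary: np.ndarray        # one-sided difference used at these points
    c: float = DEFAULT_C
    stat: np.ndarray | None = None
    p: np.ndarray | None = None
    p_adj: np.ndarray | None = None


@dataclass
class PeakRecord:
    gene: str
    lineage: int
    involved: bool
    min_p_adj: float
    peak_time: float | None = None
    peak_rule: str | None = None   # "zero_crossing" or "lineage_end"


def _fd_weights(fit: GeneFit, grid: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference weights over the K basis coefficients at each grid point.

    Central differences where t +- epsilon stays inside the knot span,
    one-sided at the boundary (flagged).
    """
    lo, hi = fit.spec.domain
    boundary = (grid - epsilon < lo) | (grid + epsilon > hi)
    t_hi = np.minimum(grid + epsilon, hi)
    t_lo = np.maximum(grid - epsilon, lo)
    span = t_hi - t_lo
    if np.any(span <= 0):
        raise ValueError("epsilon too large for the knot span")
    D = (build_basis(t_hi, fit.spec) - build_basis(t_lo, fit.spec)) / span[:, None]
    return D, boundary


def estimate_derivatives(
    fit: GeneFit,
    lineage: int,
    J: int = DEFAULT_J,
    epsilon: float = DEFAULT_EPSILON,
) -> DerivativeGrid:
    """Finite-difference derivative of the smoother with pointwise SEs.

    delta_j = sum_k [b_k(t_j + eps) - b_k(t_j - eps)] / (2 eps) * beta_lk;
    the SE is sqrt(d' V d) with d the same weight vector, V the coefficient
    covariance of the lineage block.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if fit.degenerate:
        raise ValueError(f"gene {fit.gene}: degenerate fit has no derivatives")
    lo, hi = fit.lineage_ranges[lineage]
    grid = np.linspace(lo, hi, J)
    D, boundary = _fd_weights(fit, grid, epsilon)
    delta = D @ fit.beta[lineage]
    Vl = fit.lineage_cov(lineage)
    se = np.sqrt(np.maximum(np.einsum("jk,kl,jl->j", D, Vl, D), 0.0))
    return DerivativeGrid(fit.gene, lineage, grid, delta, se, epsilon, boundary)


def derivative_test(
    dgrid: DerivativeGrid,
    alpha: float = DEFAULT_ALPHA,
    c: float = DEFAULT_C,
) -> tuple[bool, float]:
    """Thresholded one-sided derivative test with BH adjustment across the grid.

    Returns (involved, min adjusted p).  Grid points with a zero SE get
    p = 1 (conservative) and are logged.
    """
    dgrid.c = c
    zero_se = dgrid.se == 0
    if zero_se.any():
        logger.info(
            "gene %s lineage %d: %d grid points with zero SE set to p=1",
            dgrid.gene, dgrid.lineage, int(zero_se.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(zero_se, 0.0, np.maximum(0.0, dgrid.delta - c) / dgrid.se)
    p = norm.sf(stat)
    p[zero_se] = 1.0
    dgrid.stat, dgrid.p, dgrid.p_adj = stat, p, bh_adjust(p)
    min_p_adj = float(dgrid.p_adj.min())
    return min_p_adj < alpha, min_p_adj


def detect_peak(dgrid: DerivativeGrid, alpha: float = DEFAULT_ALPHA) -> PeakRecord:
    """Locate the expression peak of an involved gene.

    Scans grid points after the lowest adjusted p-value (first index on
    ties) for the first sign change of the derivative and interpolates the
    zero linearly; a derivative with no later sign change places the peak
    at the lineage end.
    """
    if dgrid.p_adj is None:
        raise ValueError("run derivative_test before detect_peak")
    min_p_adj = float(dgrid.p_adj.min())
    if min_p_adj >= alpha:
        return PeakRecord(dgrid.gene, dgrid.lineage, False, min_p_adj)
    jmin = int(np.argmin(dgrid.p_adj))  # argmin takes the first index on ties
    d, t = dgrid.delta, dgrid.grid
    for j in range(jmin, t.size - 1):
        if d[j] == 0.0:
            return PeakRecord(dgrid.gene, dgrid.lineage, True, min_p_adj,
                              float(t[j]), "zero_crossing")
        if d[j] * d[j + 1] < 0:
            tz = t[j] + d[j] * (t[j + 1] - t[j]) / (d[j] - d[j + 1])
            return PeakRecord(dgrid.gene, dgrid.lineage, True, min_p_adj,
                              float(tz), "zero_crossing")
    return PeakRecord(dgrid.gene, dgrid.lineage, True, min_p_adj,
                      float(t[-1]), "lineage_end")


def test_gene(
    fit: GeneFit,
    lineage: int,
    J: int = DEFAULT_J,
    epsilon: float = DEFAULT_EPSILON,
    c: float = DEFAULT_C,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[DerivativeGrid, PeakRecord]:
    """Derivatives, test and peak for one (gene, lineage)."""
    dgrid = estimate_derivatives(fit, lineage, J=J, epsilon=epsilon)
    derivative_test(dgrid, alpha=alpha, c=c)
    return dgrid, detect_peak(dgrid, alpha=alpha)


def cascade_table(
    fits: list[GeneFit],
    lineages: list[int] | None = None,
    J: int = DEFAULT_J,
    epsilon: float = DEFAULT_EPSILON,
    c: float = DEFAULT_C,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Run the cascade test over genes x lineages; one row per pair."""
    rows = []
    for fit in fits:
        lins = lineages if lineages is not None else range(fit.n_lineages)
        for l in lins:
            if fit.degenerate:
                rows.append(PeakRecord(fit.gene, l, False, np.nan))
                continue
            _, rec = test_gene(fit, l, J=J, epsilon=epsilon, c=c, alpha=alpha)
            rows.append(rec)
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "lineage": r.lineage, "involved": r.involved,
                "min_p_adj": r.min_p_adj, "peak_time": r.peak_time,
                "peak_rule": r.peak_rule,
            }
            for r in rows
        ]
    )


def build_cascade(
    fits: dict[str, GeneFit],
    peaks: pd.DataFrame,
    lineage: int,
    n_bins: int = 100,
) -> pd.DataFrame:
    """TF x pseudotime-bin matrix of fitted expression, z-scaled per row.

    Rows (involved TFs only) are ordered by peak time, ties broken by the
    minimum adjusted p-value then gene id, reproducing the cascade reading
    order of the heatmaps.
    """
    sub = peaks[(peaks["lineage"] == lineage) & peaks["involved"]].copy()
    if sub.empty:
        logger.warning("no involved TFs in lineage %d; empty cascade", lineage)
        return pd.DataFrame()
    sub = sub.sort_values(["peak_time", "min_p_adj", "gene"], kind="mergesort")
    some_fit = fits[sub["gene"].iloc[0]]
    lo, hi = some_fit.lineage_ranges[lineage]
    mids = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    mat = np.vstack(
        [predict_smoother(fits[g], lineage, mids, scale="response") for g in sub["gene"]]
    )
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-12, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=list(sub["gene"]), columns=mids)


def _smoother_maxima(fit: GeneFit, n_grid: int = DEFAULT_J) -> np.ndarray:
    """Max of the response-scale smoother per lineage, on each lineage's grid."""
    out = np.empty(fit.n_lineages)
    for l in range(fit.n_lineages):
        lo, hi = fit.lineage_ranges[l]
        out[l] = predict_smoother(fit, l, np.linspace(lo, hi, n_grid)).max()
    return out


def lineage_specific_tfs(
    fits: dict[str, GeneFit],
    involvement: pd.DataFrame,
    ratio: float = 1.5,
    n_grid: int = DEFAULT_J,
) -> dict[int, set[str]]:
    """TFs most active in a single lineage.

    A TF involved in lineage l is *specific* to l when the maximum of its
    response-scale smoother there is at least ``ratio`` times the
    corresponding maximum in every other lineage.
    """
    lineages = sorted(involvement["lineage"].unique())
    if len(lineages) < 2:
        raise ValueError("lineage specificity needs at least two lineages")
    inv = involvement.set_index(["gene", "lineage"])["involved"]
    out: dict[int, set[str]] = {l: set() for l in lineages}
    for gene, fit in fits.items():
        if fit.degenerate:
            continue
        maxima = _smoother_maxima(fit, n_grid)
        for l in lineages:
            if not inv.get((gene, l), False):
                continue
            others = [maxima[m] for m in lineages if m != l]
            if all(maxima[l] >= ratio * o for o in others):
                out[l].add(gene)
    return out


def shared_tfs(peaks: pd.DataFrame, delta: float = 1.0) -> set[str]:
    """TFs with a peak in every lineage whose peak times differ by < delta."""
    n_lineages = peaks["lineage"].nunique()
    shared = set()
    for gene, sub in peaks.groupby("gene"):
        pt = sub.loc[sub["involved"], "peak_time"].dropna()
        if len(pt) == n_lineages and pt.max() - pt.min() < delta:
            shared.add(gene)
    return shared


def cluster_cascade(matrix: pd.DataFrame, k: int, method: str = "ward") -> pd.Series:
    """Cut a hierarchical tree (Euclidean distance) of cascade rows at k clusters."""
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds {matrix.shape[0]} rows")
    if k == matrix.shape[0]:
        labels = np.arange(1, k + 1)
    else:
        labels = fcluster(linkage(matrix.to_numpy(), method=method), t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")


def enrich_hypergeom(
    cluster_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a cluster.

    p = P(X >= overlap) with X ~ Hypergeom(|universe|, |set n universe|,
    |cluster|).  Gene sets are intersected with the universe before testing;
    the table is BH-adjusted, sorted by p, and truncated to ``top_n``.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = cluster_genes - universe
    if extra:
        raise ValueError(f"cluster genes outside the universe: {sorted(extra)[:5]}")
    M, n_draw = len(universe), len(cluster_genes)
    rows = []
    for name, members in gene_sets.items():
        inset = members & universe
        overlap = len(inset & cluster_genes)
        p = float(hypergeom.sf(overlap - 1, M, len(inset), n_draw))
        rows.append({"gene_set": name, "set_size": len(inset), "overlap": overlap, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return (
        table.sort_values(["p", "gene_set"], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
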