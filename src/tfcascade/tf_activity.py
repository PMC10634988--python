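"""Deconvolution of gene expression into per-cell TF activities.

The observed count of target gene g in cell i is modelled as the sum of
latent molecule counts contributed by its regulators in a gene regulatory
network (GRN):

    X_tgi ~ Poisson(N_i * beta_tg * a_ti),   Y_gi = sum_{t in pa(g)} X_tgi,

so Y_gi ~ Poisson(N_i * sum_t beta_tg a_ti).  beta_tg is a TF -> target
production rate supported only on GRN edges, a_ti a nonnegative per-cell TF
activity, N_i a depth offset.  The EM algorithm reduces to multiplicative
KL-factorization updates restricted to the GRN support; the E-step
responsibilities xi_tgi = beta_tg a_ti / sum_t' beta_t'g a_t'i also define
the expected number of molecules each TF produced in each cell, which is
the per-cell activity readout.

The likelihood only identifies beta and a up to a per-TF scale; after
fitting, rates are normalized to sum_g beta_tg = 1 with the scale absorbed
into the activities, making activities comparable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GRNModel",
    "ActivityFit",
    "load_grn",
    "em_fit",
    "assign_molecules",
    "activity_over_pseudotime",
]

_FLOOR = 1e-12


@dataclass
class GRNModel:
    """A directed TF -> target network with nonnegative edge weights."""

    edges: pd.DataFrame  # columns tf, target, weight; duplicates pre-summed

    def __post_init__(self) -> None:
        required = {"tf", "target", "weight"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.edges["target"].unique())

    def support(self, tfs: list[str], targets: list[str]) -> np.ndarray:
        """Boolean TF x target adjacency restricted to the given orderings."""
        ti = {t: i for i, t in enumerate(tfs)}
        gi = {g: i for i, g in enumerate(targets)}
        S = np.zeros((len(tfs), len(targets)), dtype=bool)
        for tf, tg in zip(self.edges["tf"], self.edges["target"]):
            if tf in ti and tg in gi:
                S[ti[tf], gi[tg]] = True
        return S

    def weights(self, tfs: list[str], targets: list[str]) -> np.ndarray:
        ti = {t: i for i, t in enumerate(tfs)}
        gi = {g: i for i, g in enumerate(targets)}
        W = np.zeros((len(tfs), len(targets)))
        for tf, tg, w in zip(self.edges["tf"], self.edges["target"], self.edges["weight"]):
            if tf in ti and tg in gi:
                W[ti[tf], gi[tg]] = w
        return W


def load_grn(edge_table: pd.DataFrame) -> GRNModel:
    """Build a GRNModel from a three-column (tf, target, weight) table.

    Duplicate edges are summed; negative weights are an input error.
    """
    df = edge_table.copy()
    if df.shape[1] >= 3 and not {"tf", "target", "weight"}.issubset(df.columns):
        df.columns = ["tf", "target", "weight", *df.columns[3:]]
    if df.empty:
        logger.warning("empty GRN edge table")
        return GRNModel(pd.DataFrame(columns=["tf", "target", "weight"]))
    if (df["weight"] < 0).any():
        raise ValueError("negative GRN edge weights")
    df = df.groupby(["tf", "target"], as_index=False)["weight"].sum()
    return GRNModel(df)


@dataclass
class ActivityFit:
    """Fitted deconvolution: rates, activities and the likelihood trace."""

    tfs: list[str]
    targets: list[str]
    cells: list[str]
    beta: np.ndarray                 # (T, G), zero off the GRN support
    activity: np.ndarray             # (T, C)
    offsets: np.ndarray              # (C,)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def beta_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.tfs, columns=self.targets)

    @property
    def activity_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.activity, index=self.tfs, columns=self.cells)


def _poisson_loglik(Y: np.ndarray, lam: np.ndarray) -> float:
    lam = np.maximum(lam, _FLOOR)
    return float(np.sum(Y * np.log(lam) - lam - gammaln(Y + 1)))


def em_fit(
    grn: GRNModel,
    counts: pd.DataFrame,
    offsets: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ActivityFit:
    """Fit the Poisson deconvolution model by EM.

    ``counts`` is a gene x cell frame; genes without a GRN parent are
    dropped (logged).  Rates are initialized proportional to GRN weights
    (uniform on the support if all weights are zero) and activities from
    seeded positive draws.  Each iteration updates the rate block, then the
    activity block, each a closed-form M-step given the E-step
    responsibilities, which keeps the likelihood nondecreasing.  Iteration
    stops when the relative log-likelihood change drops below ``tol``.
    """
    targets = [g for g in counts.index if g in set(grn.targets)]
    dropped = counts.shape[0] - len(targets)
    if dropped:
        logger.info("dropping %d genes without a GRN parent", dropped)
    if not targets:
        raise ValueError("no counted gene has a GRN parent")
    tfs = grn.tfs
    cells = list(counts.columns)
    Y = counts.loc[targets].to_numpy(dtype=float)
    if Y.sum() == 0:
        raise ValueError("all-zero count matrix over GRN targets")
    N = np.ones(len(cells)) if offsets is None else np.asarray(offsets, dtype=float)
    if np.any(N <= 0):
        raise ValueError("offsets must be positive")

    S = grn.support(tfs, targets)
    W = grn.weights(tfs, targets)
    beta = np.where(S, W, 0.0)
    if beta.sum() == 0:
        beta = S.astype(float)
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.5, 1.5, (len(tfs), len(cells)))
    # cells with no molecules over the retained targets carry no information
    dead = Y.sum(axis=0) == 0
    a[:, dead] = 0.0

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        lam = beta.T @ a                                  # (G, C), depth-free
        R = np.where(Y > 0, Y / np.maximum(lam, _FLOOR), 0.0)
        beta = beta * (a @ R.T) / np.maximum((a * N).sum(axis=1), _FLOOR)[:, None]
        beta[~S] = 0.0
        lam = beta.T @ a
        R = np.where(Y > 0, Y / np.maximum(lam, _FLOOR), 0.0)
        a = a * (beta @ R) / np.maximum(N[None, :] * beta.sum(axis=1)[:, None], _FLOOR)
        ll = _poisson_loglik(Y, N[None, :] * (beta.T @ a))
        if trace and abs(ll - trace[-1]) < tol * (abs(trace[-1]) + 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    if not converged:
        logger.warning("EM hit max_iter=%d without convergence", max_iter)

    # absorb the per-TF scale into the activities: sum_g beta_tg = 1
    scale = beta.sum(axis=1)
    pos = scale > 0
    beta[pos] /= scale[pos, None]
    a[pos] *= scale[pos, None]
    return ActivityFit(tfs, targets, cells, beta, a, N, trace, converged)


def assign_molecules(fit: ActivityFit, counts: pd.DataFrame) -> pd.DataFrame:
    """Expected molecules per TF per cell: A_ti = sum_g Y_gi xi_tgi.

    The responsibilities xi split each observed count among the gene's GRN
    parents, so activities conserve molecules: sum_t A_ti equals the cell's
    total target count.  Counts of a gene whose fitted rate vanished in a
    cell are split uniformly among its parents.
    """
    Y = counts.loc[fit.targets, fit.cells].to_numpy(dtype=float)
    contrib = fit.beta[:, :, None] * fit.activity[:, None, :]   # (T, G, C)
    tot = contrib.sum(axis=0)                                   # (G, C)
    missing = (tot <= 0) & (Y > 0)
    if missing.any():
        support = (fit.beta > 0).astype(float)
        fallback = support[:, :, None] / np.maximum(support.sum(axis=0), 1.0)[None, :, None]
        contrib = np.where(missing[None, :, :], fallback, contrib)
        tot = contrib.sum(axis=0)
    xi = contrib / np.maximum(tot, _FLOOR)[None, :, :]
    A = np.einsum("tgc,gc->tc", xi, Y)
    return pd.DataFrame(A, index=fit.tfs, columns=fit.cells)


def activity_over_pseudotime(
    activity: pd.DataFrame,
    pseudotime: np.ndarray,
    n_bins: int = 100,
    k: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binned, z-scaled activity curves with early/mid/late clustering.

    Mean activity per equal-width pseudotime bin (empty bins filled by
    linear interpolation between neighbours); rows z-scaled with a variance
    floor; Ward/Euclidean hierarchical clustering into ``k`` groups whose
    labels are ordered by the pseudotime bin of each cluster's mean-activity
    peak.  With the default k = 3 the groups are named early/mid/late.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    pt = np.asarray(pseudotime, dtype=float)
    if pt.size != activity.shape[1]:
        raise ValueError("pseudotime length must match the number of cells")
    edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
    which = np.clip(np.digitize(pt, edges[1:-1]), 0, n_bins - 1)
    A = activity.to_numpy(dtype=float)
    binned = np.full((A.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            binned[:, b] = A[:, mask].mean(axis=1)
    empty = np.isnan(binned[0])
    if empty.any():
        logger.info("interpolating %d empty pseudotime bins", int(empty.sum()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        for r in range(binned.shape[0]):
            binned[r, empty] = np.interp(centers[empty], centers[~empty], binned[r, ~empty])

    mean = binned.mean(axis=1, keepdims=True)
    sd = binned.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-12, (binned - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=activity.index, columns=range(n_bins))

    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds {z.shape[0]} TFs")
    if k == 1 or z.shape[0] == 1:
        raw = np.ones(z.shape[0], dtype=int)
    else:
        raw = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    peak_bin = {c: z[raw == c].mean(axis=0).argmax() for c in np.unique(raw)}
    order = sorted(peak_bin, key=peak_bin.get)
    names = (
        ["early", "mid", "late"] if k == 3 else [f"group{i + 1}" for i in range(len(order))]
    )
    rename = {c: names[i] for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=activity.index, name="cluster")
    return zdf, labels
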