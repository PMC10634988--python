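"""Negative-binomial spline smoothers of gene expression along pseudotime.

Each gene is modelled as

    Y_gi ~ NB(mu_gi, phi_g),
    log mu_gi = sum_l s_gl(T_li) Z_li + U_i alpha_g + log N_i,

with lineage-specific smoothers s_gl(t) = sum_k b_k(t) beta_glk written in a
clamped cubic B-spline basis shared by all genes and lineages.  Cells carry a
hard lineage assignment (Z one-hot), a pseudotime per lineage, a positive
size-factor offset N_i and optional covariates U_i.

Fitting alternates iteratively reweighted least squares for the regression
coefficients at a fixed dispersion with a univariate maximum-likelihood
update of the NB size parameter phi_g.  The coefficient covariance V is the
inverse observed information at the optimum with phi held at its estimate;
downstream derivative tests are linear contrasts of (beta, alpha) and use V
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryDataset",
    "SplineSpec",
    "GeneFit",
    "build_knots",
    "build_basis",
    "fit_gene",
    "select_knots_aic",
    "association_test",
    "predict_smoother",
]

_PHI_MIN = 1e-8
_PHI_MAX = 1e8


@dataclass
class TrajectoryDataset:
    """Counts plus the per-cell annotations the smoother regression needs.

    Attributes
    ----------
    counts : (n_genes, n_cells) integer array.
    genes, cells : identifier lists.
    pseudotime : (n_cells, n_lineages); only the assigned lineage's column
        is used for a given cell.
    lineage : (n_cells,) integer lineage assignment (0-based).
    offsets : (n_cells,) positive size factors N_i.
    covariates : (n_cells, p) design matrix U; may have p = 0 columns.
    """

    counts: np.ndarray
    genes: list[str]
    cells: list[str]
    pseudotime: np.ndarray
    lineage: np.ndarray
    offsets: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.pseudotime = np.atleast_2d(np.asarray(self.pseudotime, dtype=float))
        if self.pseudotime.shape[0] != len(self.cells):
            self.pseudotime = self.pseudotime.T
        self.lineage = np.asarray(self.lineage, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if np.any(self.offsets <= 0):
            raise ValueError("offsets must be positive")
        t_assigned = self.assigned_pseudotime()
        if not np.all(np.isfinite(t_assigned)) or np.any(t_assigned < 0):
            raise ValueError("assigned pseudotimes must be finite and nonnegative")

    @property
    def n_lineages(self) -> int:
        return self.pseudotime.shape[1]

    @property
    def lineage_onehot(self) -> np.ndarray:
        """Cell x lineage one-hot assignment matrix Z."""
        z = np.zeros((len(self.cells), self.n_lineages))
        z[np.arange(len(self.cells)), self.lineage] = 1.0
        return z

    def assigned_pseudotime(self) -> np.ndarray:
        """Pseudotime of each cell on its assigned lineage."""
        return self.pseudotime[np.arange(len(self.cells)), self.lineage]

    def lineage_range(self, lineage: int) -> tuple[float, float]:
        t = self.assigned_pseudotime()[self.lineage == lineage]
        if t.size == 0:
            raise ValueError(f"no cells assigned to lineage {lineage}")
        return float(t.min()), float(t.max())

    def gene_counts(self, gene: str) -> np.ndarray:
        try:
            idx = self.genes.index(gene)
        except ValueError as exc:
            raise KeyError(f"gene {gene!r} not in dataset") from exc
        return np.asarray(self.counts[idx], dtype=float)


@dataclass
class SplineSpec:
    """Clamped cubic B-spline vocabulary: K basis functions per lineage.

    ``n_basis`` counts regression coefficients per lineage (default 6).
    Interior knots (K - degree - 1 of them) sit at quantiles of the assigned
    cells' pseudotimes; boundary knots at the min/max, each repeated
    degree + 1 times so the basis is clamped.
    """

    n_basis: int = 6
    degree: int = 3
    knots: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_basis < self.degree + 1:
            raise ValueError(f"need at least {self.degree + 1} basis functions for degree {self.degree}")

    @property
    def domain(self) -> tuple[float, float]:
        if self.knots is None:
            raise ValueError("knots not realized yet")
        return float(self.knots[0]), float(self.knots[-1])


def build_knots(pseudotimes: np.ndarray, spec: SplineSpec) -> SplineSpec:
    """Realize the knot vector for ``spec`` from observed pseudotimes."""
    t = np.asarray(pseudotimes, dtype=float)
    n_unique = np.unique(t).size
    if n_unique < spec.n_basis:
        raise ValueError(
            f"{n_unique} distinct pseudotimes cannot support {spec.n_basis} basis functions"
        )
    n_interior = spec.n_basis - spec.degree - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(t, qs) if n_interior else np.empty(0)
    lo, hi = float(t.min()), float(t.max())
    full = np.r_[[lo] * (spec.degree + 1), interior, [hi] * (spec.degree + 1)]
    if np.any(np.diff(np.r_[lo, interior, hi]) <= 0):
        raise ValueError("interior knots are not strictly increasing; too few distinct pseudotimes")
    return replace(spec, knots=full)


def build_basis(pseudotimes: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the clamped B-spline basis; rows are b_1(t) .. b_K(t)."""
    if spec.knots is None:
        spec = build_knots(pseudotimes, spec)
    t = np.atleast_1d(np.asarray(pseudotimes, dtype=float))
    lo, hi = spec.domain
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError("pseudotimes outside the knot span; extrapolation not supported")
    return BSpline.design_matrix(t, spec.knots, spec.degree, extrapolate=False).toarray()


@dataclass
class GeneFit:
    """A fitted per-gene NB spline smoother."""

    gene: str
    beta: np.ndarray                 # (L, K) spline coefficients
    alpha: np.ndarray                # (p,) covariate coefficients
    phi: float                       # NB size (dispersion) parameter
    V: np.ndarray                    # covariance of (vec(beta), alpha)
    loglik: float
    aic: float
    n_params: int
    converged: bool
    degenerate: bool
    spec: SplineSpec
    lineage_ranges: list[tuple[float, float]]
    n_iter: int = 0

    @property
    def n_lineages(self) -> int:
        return self.beta.shape[0]

    @property
    def n_basis(self) -> int:
        return self.beta.shape[1]

    def coef_vector(self) -> np.ndarray:
        return np.r_[self.beta.ravel(), self.alpha]

    def lineage_cov(self, lineage: int) -> np.ndarray:
        """Covariance block of the lineage's spline coefficients."""
        k = self.n_basis
        sl = slice(lineage * k, (lineage + 1) * k)
        return self.V[sl, sl]


def _design_matrix(data: TrajectoryDataset, spec: SplineSpec) -> np.ndarray:
    """Block design: lineage-specific basis columns (zeroed off-lineage) then covariates."""
    n = len(data.cells)
    k = spec.n_basis
    L = data.n_lineages
    X = np.zeros((n, L * k + data.covariates.shape[1]))
    t = data.assigned_pseudotime()
    for l in range(L):
        mask = data.lineage == l
        if mask.any():
            X[np.ix_(mask, range(l * k, (l + 1) * k))] = build_basis(t[mask], spec)
    X[:, L * k:] = data.covariates
    return X


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-300)
    return float(
        np.sum(
            gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
            + phi * np.log(phi / (phi + mu))
            + y * np.log(mu / (phi + mu))
        )
    )


def _irls(y, X, log_offset, phi, coef, max_iter=50, tol=1e-10):
    """IRLS for the NB log-link GLM at fixed dispersion phi."""
    eta = X @ coef + log_offset
    mu = np.exp(np.clip(eta, -500, 500))
    ll = _nb_loglik(y, mu, phi)
    for _ in range(max_iter):
        w = mu / (1.0 + mu / phi)          # Fisher weights, log link
        z = (eta - log_offset) + (y - mu) / np.maximum(mu, 1e-300)
        sw = np.sqrt(np.maximum(w, 1e-300))
        coef_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta_new = X @ coef_new + log_offset
        mu_new = np.exp(np.clip(eta_new, -500, 500))
        ll_new = _nb_loglik(y, mu_new, phi)
        # step-halving keeps the likelihood moving uphill; the slack term
        # absorbs float noise in the gammaln terms at extreme phi
        step = 1.0
        while ll_new < ll - 1e-8 * (abs(ll) + 1.0) and step > 1e-4:
            step /= 2.0
            trial = coef + step * (coef_new - coef)
            eta_new = X @ trial + log_offset
            mu_new = np.exp(np.clip(eta_new, -500, 500))
            ll_new = _nb_loglik(y, mu_new, phi)
            coef_new = trial
        done = np.max(np.abs(coef_new - coef)) < 1e-10 * (1.0 + np.max(np.abs(coef_new)))
        coef, eta, mu, ll = coef_new, eta_new, mu_new, ll_new
        if done:
            break
    return coef, mu, ll


def _update_phi(y: np.ndarray, mu: np.ndarray, phi0: float) -> float:
    res = minimize_scalar(
        lambda lp: -_nb_loglik(y, mu, np.exp(lp)),
        bounds=(np.log(_PHI_MIN), np.log(_PHI_MAX)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x)) if res.success else phi0


def fit_gene(
    data: TrajectoryDataset,
    gene: str,
    spec: SplineSpec | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GeneFit:
    """Fit the NB spline smoother for one gene.

    An all-zero gene yields a fit flagged ``degenerate`` (excluded from
    downstream testing) rather than an exception.
    """
    spec = spec or SplineSpec()
    if spec.knots is None:
        spec = build_knots(data.assigned_pseudotime(), spec)
    y = data.gene_counts(gene)
    L, k, p = data.n_lineages, spec.n_basis, data.covariates.shape[1]
    n_coef = L * k + p
    ranges = [data.lineage_range(l) for l in range(L)]
    n_params = n_coef + 1  # + dispersion
    if y.sum() == 0:
        return GeneFit(
            gene, np.zeros((L, k)), np.zeros(p), np.nan,
            np.full((n_coef, n_coef), np.nan), -np.inf, np.inf, n_params,
            converged=False, degenerate=True, spec=spec, lineage_ranges=ranges,
        )

    X = _design_matrix(data, spec)
    log_off = np.log(data.offsets)
    # moment start for dispersion
    rate = y / data.offsets
    m, v = rate.mean(), rate.var()
    phi = float(np.clip(m * m / max(v - m, 1e-6), 0.01, _PHI_MAX))
    coef = np.zeros(n_coef)
    coef, mu, ll = _irls(y, X, log_off, phi, coef)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        phi = _update_phi(y, mu, phi)
        coef, mu, ll_new = _irls(y, X, log_off, phi, coef)
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("gene %s: dispersion alternation hit %d iterations", gene, max_iter)

    # observed information for the NB log-link likelihood at the optimum
    w_obs = (y + phi) * phi * mu / (mu + phi) ** 2
    info = X.T @ (X * w_obs[:, None])
    V = np.linalg.pinv(info)
    aic = -2.0 * ll + 2.0 * n_params
    return GeneFit(
        gene, coef[: L * k].reshape(L, k), coef[L * k:], phi, V, ll, aic,
        n_params, converged=converged, degenerate=False, spec=spec,
        lineage_ranges=ranges, n_iter=it,
    )


def select_knots_aic(
    data: TrajectoryDataset,
    genes: list[str],
    candidates: list[int],
) -> int:
    """Pick the basis dimension K minimizing mean AIC over a gene subset."""
    if len(candidates) == 1:
        return candidates[0]
    rows = []
    for k in candidates:
        try:
            spec = build_knots(data.assigned_pseudotime(), SplineSpec(n_basis=k))
        except ValueError as exc:
            logger.warning("candidate K=%d infeasible: %s", k, exc)
            continue
        aics = [f.aic for g in genes if np.isfinite((f := fit_gene(data, g, spec)).aic)]
        if aics:
            rows.append((k, float(np.mean(aics))))
    if not rows:
        raise ValueError("no feasible candidate K")
    table = pd.DataFrame(rows, columns=["K", "mean_aic"])
    logger.info("AIC by basis dimension:\n%s", table.to_string(index=False))
    return int(table.loc[table["mean_aic"].idxmin(), "K"])


def _eval_design_row(fit: GeneFit, lineage: int, t: np.ndarray) -> np.ndarray:
    """Rows of the full-coefficient design evaluating eta on one lineage."""
    B = build_basis(t, fit.spec)
    k, L, p = fit.n_basis, fit.n_lineages, fit.alpha.size
    rows = np.zeros((len(np.atleast_1d(t)), L * k + p))
    rows[:, lineage * k:(lineage + 1) * k] = B
    return rows


def predict_smoother(
    fit: GeneFit,
    lineage: int,
    grid: np.ndarray,
    scale: str = "response",
) -> np.ndarray:
    """Evaluate the fitted smoother s_gl on a pseudotime grid.

    ``link`` returns s_gl(t); ``response`` returns exp(s_gl(t)) with offsets
    excluded and covariates at their reference (zero) row, which is the scale
    used for cross-lineage comparisons.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    lo, hi = fit.spec.domain
    if np.any(grid < lo) or np.any(grid > hi):
        raise ValueError("grid outside the fitted knot span")
    s = build_basis(grid, fit.spec) @ fit.beta[lineage]
    if scale == "link":
        return s
    if scale == "response":
        return np.exp(s)
    raise ValueError(f"unknown scale {scale!r}")


@dataclass
class AssociationResult:
    gene: str
    lineage: int
    wald_stat: float
    df: int
    p_value: float
    upregulated: bool


def association_test(fit: GeneFit, lineage: int, n_eval: int = 100) -> AssociationResult:
    """Wald test of a constant smoother along one lineage.

    Contrasts the linear predictor at ``n_eval`` equally spaced pseudotimes
    against their mean; the statistic is referenced to a chi-square with the
    contrast rank as degrees of freedom.  ``upregulated`` compares the
    predicted mean at the lineage end versus its start.
    """
    if fit.degenerate:
        return AssociationResult(fit.gene, lineage, np.nan, 0, np.nan, False)
    lo, hi = fit.lineage_ranges[lineage]
    pts = np.linspace(lo, hi, n_eval)
    Xe = _eval_design_row(fit, lineage, pts)
    C = Xe - Xe.mean(axis=0, keepdims=True)
    est = C @ fit.coef_vector()
    W = C @ fit.V @ C.T
    Winv = np.linalg.pinv(W, rcond=1e-10)
    df = int(np.linalg.matrix_rank(W, tol=1e-10))
    stat = float(est @ Winv @ est)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    pred = predict_smoother(fit, lineage, np.array([lo, hi]))
    return AssociationResult(fit.gene, lineage, stat, df, p, bool(pred[1] > pred[0]))
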