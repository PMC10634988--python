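# Methods

## Trajectory smoothers

Per gene g and lineage l we fit a negative-binomial regression with log
link,

    Y_gi ~ NB(μ_gi, φ_g),
    log μ_gi = Σ_l s_gl(T_li) Z_li + U_i α_g + log N_i,

with `s_gl(t) = Σ_k b_k(t) β_glk` written in a clamped cubic B-spline
basis. The basis is shared by all genes and lineages: interior knots
(K − 4 of them) sit at quantiles of the assigned cells' pseudotimes,
boundary knots at the min/max. K counts regression coefficients per
lineage and defaults to 6; `select_knots_aic` can re-derive this choice by
minimizing mean AIC over a gene subset, and does so on data generated with
6-coefficient complexity.

The spline is deliberately *unpenalized*. With K = 6 the basis itself
restricts flexibility, and an unpenalized fit has an exact coefficient
covariance (no effective-degrees-of-freedom machinery), which the
derivative test consumes directly. This is a departure from penalized
GAM fitting; the practical consequence is slightly wigglier fits near
sparsely populated pseudotime ranges, which the derivative threshold c
absorbs (see below).

Estimation alternates iteratively reweighted least squares for (β, α) at
fixed φ with a univariate maximum-likelihood update of φ (bounded in
[1e−8, 1e8]); the outer loop stops when the relative log-likelihood change
drops below 1e−8 (at most 200 alternations). IRLS itself stops on
coefficient change (1e−10 relative), which pins the optimum much tighter
than a likelihood-change criterion — the likelihood is second-order flat
at the optimum. Step-halving guards ascent; its tolerance contains a
relative slack (1e−8·|ℓ|) because the gammaln terms of the NB likelihood
carry float noise of that order when φ is effectively infinite (Poisson
limit, e.g. for constant counts). The covariance V is the inverse
*observed* information at the optimum with φ fixed at its estimate; for
the NB log link the observed-information weights are
`(y + φ) φ μ / (μ + φ)²`, which coincide with the Fisher weights at y = μ.

Cells carry a hard lineage assignment (one-hot Z); soft weights are out of
scope. All-zero genes yield a fit flagged `degenerate` and are excluded
downstream rather than raising.

The association test contrasts the linear predictor at `n_eval` equally
spaced pseudotimes against their mean and refers the Wald quadratic form
(pseudo-inverse, rank degrees of freedom) to a chi-square. A gene is
"upregulated" when the predicted response at the lineage end exceeds the
start.

## Derivative test and peak calling

Derivatives are estimated per lineage on J = 100 equally spaced grid
points by central finite differences of the basis functions with
ε = 1e−7:

    δ̂_glj = Σ_k [b_k(t_j + ε) − b_k(t_j − ε)]/(2ε) · β_glk,
    σ̂_glj = sqrt(dᵀ V_l d),

with d the same difference weights and V_l the lineage block of the
coefficient covariance. At the two boundary grid points t ± ε leaves the
knot span; there a one-sided difference over the clipped span is used and
the point flagged. Central differencing is exact for affine functions and
agrees with the analytic (degree-lowering) B-spline derivative to < 1e−4
relative error — both are test oracles.

The test statistic `T = max(0, δ̂ − c)/σ̂` with threshold c = 0.1 is
referenced one-sided to N(0, 1); p-values are Benjamini–Hochberg-adjusted
*across the J grid points within one (gene, lineage)* — not across genes —
and the gene is involved when the minimum adjusted p-value is below
α = 0.05. These p-values are ranking devices more than calibrated error
rates: the thresholding at c makes the procedure conservative (flat genes
are declared involved well below the nominal level, which the null
calibration check bounds at 0.07).

Numerical choices: a grid point with σ̂ = 0 gets p = 1 (conservative,
logged); ties in argmin(p_adj) resolve to the earliest pseudotime,
consistent with reading a cascade from early to late; the peak is the
first sign change of δ̂ after that point, localized by linear
interpolation between the bracketing grid points; a derivative that never
crosses zero puts the peak at the lineage end, flagged `lineage_end`
(monotone increase means maximum observed expression at the end).

Cross-lineage rules operate on the response-scale smoother with offsets
excluded and covariates at the zero reference row: a TF is specific to a
lineage when its smoother maximum there is ≥ 1.5× the corresponding
maximum in *every* other lineage (inclusive at the boundary), and shared
when it has a peak in every lineage with peak-time spread strictly below
1 raw pseudotime unit (lineages are assumed to share a trajectory origin;
no rescaling). Cascade matrices z-scale each TF's binned fitted
expression within a lineage (population variance), order rows by peak
time with ties broken by minimum adjusted p then gene id, and are
clustered by Ward linkage on Euclidean distance — Ward is a choice; the
linkage is configurable. Enrichment uses the exact hypergeometric upper
tail on sets intersected with the universe, BH-adjusted across sets.

## Activity deconvolution

The deconvolution model attributes each target-gene molecule to one of the
gene's network parents:

    X_tgi ~ Poisson(N_i β_tg a_ti),   Y_gi = Σ_{t∈pa(g)} X_tgi.

EM gives responsibilities ξ_tgi = β_tg a_ti / Σ_t' β_t'g a_t'i and
closed-form M-steps which reduce to multiplicative KL-factorization
updates restricted to the network support. One iteration updates the full
β block, then the full a block (recomputing responsibilities in between);
each block update is an exact M-step given the other block, so the
likelihood is nondecreasing — asserted on random instances. Denominators
are floored at 1e−12; cells with zero total target count get zero
activity and drop out of the denominators. Convergence: relative
log-likelihood change < 1e−8 (default), at most 500 iterations. Because
multiplicative updates have slow tails, moderate-size fits routinely use
the full budget; the monotone trace makes the stopping point benign.

The likelihood identifies (β, a) only up to a per-TF scale, so after
fitting rates are normalized to Σ_g β_tg = 1 with the scale absorbed into
the activities. Network weights serve as support and initialization only
(uniform if all zero) — the likelihood is unweighted, since nothing in
the model requires weights to be rates. Genes with no network parent are
dropped before fitting (logged). The activity readout is the expected
molecule count A_ti = Σ_g Y_gi ξ_tgi, which conserves molecules exactly:
Σ_t A_ti equals the cell's total target count. For a gene whose fitted
rate vanished in a cell that still shows counts, the count is split
uniformly among its parents to preserve conservation.

Pseudotime summaries average activity in equal-width bins (empty bins
linearly interpolated from neighbours, logged), z-scale per TF with a
variance floor, and cut a Ward tree at k = 3 groups, named early/mid/late
by the bin of each cluster's mean-activity peak.

## Priming classification

Early-response genes satisfy expr_pre ≤ 1 (RPKM-like), log2FC ≥ 1,
FDR ≤ 0.05 — configuration defaults encoding "silent before, upregulated
after", not estimates. Accessibility is quantified as fragments
overlapping (≥ 1 bp; midpoint counting rejected for simplicity) a
±2,000 bp TSS window, CPM-normalized by the library total; the
accessibility change is log2((CPM_post + 1)/(CPM_pre + 1)). Classes:

- primed: induced ∧ |acc_lfc| ≤ 0.5 ∧ acc_pre ≥ floor;
- induced_accessible: induced ∧ acc_lfc > 0.5;
- constitutive: not induced ∧ acc_pre ≥ floor;
- silent_closed: otherwise.

The open-chromatin floor is data-adaptive by default — median + 2 MADs of
the silent-control genes' pre-injury CPM — anchored to a negative control
set (e.g. olfactory receptor genes); an explicit floor can be passed
instead. All intervals are 0-based half-open internally; 1-based TSS
annotations are converted at the boundary (lossless round trip is
tested). Quantification is TSS-window based; gene-body quantification is
not implemented.

## Synthetic data

`sim` generates the three modalities the analysis consumes, each with a
ground-truth table and bit-reproducible under a fixed seed.

*Trajectory counts.* Per-lineage log-means are Gaussian bumps,
`baseline + amplitude·exp(−(t−peak)²/2w²)`: a unique interior maximum and
a one-signed derivative before it, which makes the true peak well defined
for recovery scoring. Pseudotimes are uniform per lineage over a shared
[0, 10] range (so the < 1 shared-peak rule compares like with like),
offsets log-normal(0, 0.3²), counts NB with per-gene size φ. Default
programs draw baseline U(0.5, 1.5), amplitude U(1.5, 2.5) (a 4.5–12-fold
induction, typical of a strongly regulated TF), peak U(1, 9), width
U(1.2, 1.8) and φ = 2. A gene is flagged involved in the truth table when
its amplitude reaches 0.5 on the log scale; below that the expected
derivative stays under the test threshold c = 0.1 for these widths, so
"not involved" is the correct label. The generator does not emulate UMI
chemistry, doublets, ambient RNA or batch effects — passing tests show
the statistics behave as designed on clean NB data, not that they are
robust to those artifacts.

*Network counts.* TF out-degrees are log-normal around a median of 27
targets (a typical single-cell regulon size); one edge per degree slot,
with the first shuffled slots pinning a parent on every target, so the
median out-degree matches the parameter without orphan-repair inflating
it. The degree budget must cover all targets, otherwise generation
refuses. Activities are smooth positive bumps over a pseudotime ordering;
counts are Poisson with log-normal offsets.

*Priming data.* Gene classes are generated strictly outside the
classification margins: primed/constitutive genes get TSS fragment counts
15–25× the floor with |log2FC| ≤ 0.2, de-novo genes open from near zero
to ≥ 1.5 log2 units, silent genes stay at 0–2 fragments. Both libraries
are padded to exactly 20,000 fragments on a decoy contig so CPM ratios
equal count ratios. This makes 100% class recovery the correct
expectation — the end-to-end check verifies the plumbing and the
predicates, not classifier robustness near the margins.

## Verification problem sizes

The verification script and acceptance tests use desk-scale sizes chosen
to make each property measurable in seconds: 100 random fits for the
derivative oracle; 5 × 200 flat genes at 300 cells for null calibration;
50 bump genes at 300 cells for peak recovery; 20 + 10 random network
instances for EM monotonicity/conservation and oracle parity; one
10-TF × 100-target × 500-cell network (median out-degree 27) for activity
recovery, scored on 50-bin activity curves; 4 × 25 genes for priming
recovery.

## Known limitations

- Unpenalized splines wiggle where cells are sparse; with K = 6 this is
  mild, but peak localization degrades toward the extreme ends of a
  lineage's pseudotime range.
- The derivative test's p-values are conservative by construction and
  should be read as ranking scores.
- The deconvolution ignores edge signs (repression) and weight
  magnitudes, and reports no uncertainty on activities; TFs with heavily
  overlapping regulons are identified mainly through their activity
  dynamics, so per-cell (unbinned) activities are noisy.
- Hard lineage assignment discards cells' partial membership near
  branch points.
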