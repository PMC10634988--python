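"""Derivative test, peak localization, cascade ordering and TF classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline
from sklearn.metrics import adjusted_rand_score

from tfcascade import cascade, nbgam

from conftest import random_gene_fit


def analytic_derivative(fit, lineage, grid):
    """Independent oracle: exact B-spline derivative via degree lowering."""
    return BSpline(fit.spec.knots, fit.beta[lineage], fit.spec.degree).derivative()(grid)


class TestDerivatives:
    def test_constant_smoother_zero_derivative(self):
        fit = random_gene_fit(np.random.default_rng(0))
        fit.beta[:] = 0.7
        dg = cascade.estimate_derivatives(fit, 0)
        assert np.allclose(dg.delta, 0.0, atol=1e-7)

    def test_affine_smoother_exact_slope(self):
        """Central differences are exact on affine functions; coefficients
        reproducing a line of slope m follow from the Greville abscissae."""
        fit = random_gene_fit(np.random.default_rng(1))
        kn, d = fit.spec.knots, fit.spec.degree
        greville = np.array([kn[k + 1:k + 1 + d].mean() for k in range(fit.n_basis)])
        m, b = 0.4, -1.0
        fit.beta[0] = m * greville + b
        dg = cascade.estimate_derivatives(fit, 0, J=50)
        interior = ~dg.boundary
        assert np.allclose(dg.delta[interior], m, atol=1e-6)

    def test_matches_analytic_bspline_derivative(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(20):
            fit = random_gene_fit(rng)
            dg = cascade.estimate_derivatives(fit, 0)
            exact = analytic_derivative(fit, 0, dg.grid[~dg.boundary])
            rel = np.abs(dg.delta[~dg.boundary] - exact) / np.maximum(np.abs(exact), 1e-3)
            worst = max(worst, rel.max())
        assert worst < 1e-4

    def test_boundary_points_flagged(self):
        fit = random_gene_fit(np.random.default_rng(3))
        dg = cascade.estimate_derivatives(fit, 0, J=10)
        assert dg.boundary[0] and dg.boundary[-1]
        assert not dg.boundary[1:-1].any()

    def test_epsilon_must_be_positive(self):
        fit = random_gene_fit(np.random.default_rng(4))
        with pytest.raises(ValueError):
            cascade.estimate_derivatives(fit, 0, epsilon=0.0)


def bh_oracle(p):
    """Step-up BH by hand: p_(i) * n / i, cumulative min from the largest."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBH:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.5])
        expected = np.array([0.04, 0.04, 4 * 0.04 / 3, 0.5])
        assert np.allclose(cascade.bh_adjust(p), expected, atol=1e-12)
        assert np.allclose(bh_oracle(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_matches_oracle_and_is_monotone(self, p):
        adj = cascade.bh_adjust(np.array(p))
        assert np.allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= np.array(p) - 1e-15).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(cascade.bh_adjust(p)[perm], cascade.bh_adjust(p[perm]))


class TestDerivativeTest:
    def test_default_threshold(self):
        assert cascade.DEFAULT_C == 0.1

    def test_subthreshold_derivative_not_involved(self):
        fit = random_gene_fit(np.random.default_rng(6))
        fit.beta[:] = 0.0  # flat: delta = 0 <= c everywhere
        dg = cascade.estimate_derivatives(fit, 0)
        involved, _ = cascade.derivative_test(dg)
        assert not involved
        assert np.allclose(dg.stat, 0.0)
        assert np.allclose(dg.p, 0.5)

    def test_zero_se_conservative(self):
        fit = random_gene_fit(np.random.default_rng(7))
        fit.V[:] = 0.0
        dg = cascade.estimate_derivatives(fit, 0)
        involved, min_p = cascade.derivative_test(dg)
        assert not involved and min_p == 1.0


class TestDetectPeak:
    def _grid_with(self, delta, p_adj, t=None):
        J = len(delta)
        g = cascade.DerivativeGrid(
            "g", 0, np.linspace(0, 10, J) if t is None else t,
            np.asarray(delta, dtype=float), np.ones(J), 1e-7, np.zeros(J, bool),
        )
        g.stat = np.zeros(J)
        g.p = np.asarray(p_adj, dtype=float)
        g.p_adj = np.asarray(p_adj, dtype=float)
        return g

    def test_interpolated_zero_crossing(self):
        # derivative +1 at t=4, -1 at t=6 -> zero at t=5 by interpolation
        t = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        delta = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        p_adj = np.array([0.5, 0.01, 0.2, 0.3, 0.4, 0.5])
        rec = cascade.detect_peak(self._grid_with(delta, p_adj, t))
        assert rec.involved and rec.peak_rule == "zero_crossing"
        assert rec.peak_time == pytest.approx(5.0)

    def test_monotone_increase_peaks_at_lineage_end(self):
        delta = np.ones(6)
        p_adj = np.array([0.5, 0.01, 0.2, 0.3, 0.4, 0.5])
        rec = cascade.detect_peak(self._grid_with(delta, p_adj))
        assert rec.peak_rule == "lineage_end"
        assert rec.peak_time == pytest.approx(10.0)

    def test_not_involved_no_peak(self):
        rec = cascade.detect_peak(self._grid_with(np.ones(5), np.full(5, 0.9)))
        assert not rec.involved and rec.peak_time is None

    def test_crossing_before_argmin_ignored(self):
        # sign change at index 1 precedes the most significant point (index 3)
        t = np.linspace(0, 10, 6)
        delta = np.array([1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        p_adj = np.array([0.5, 0.4, 0.2, 0.001, 0.3, 0.5])
        rec = cascade.detect_peak(self._grid_with(delta, p_adj, t))
        assert rec.peak_time == pytest.approx(7.0)  # zero between t=6 and t=8


class TestCascadeMatrix:
    def test_single_tf_scaling_contract(self, fitted_bump, bump_dataset):
        programs, *_ = bump_dataset
        gene = next(p.gene_id for p in programs if p.amplitude[0] > 0)
        peaks = pd.DataFrame(
            [{"gene": gene, "lineage": 0, "involved": True,
              "min_p_adj": 1e-5, "peak_time": 5.0, "peak_rule": "zero_crossing"}]
        )
        mat = cascade.build_cascade(fitted_bump, peaks, 0)
        assert mat.shape == (1, 100)
        assert mat.iloc[0].mean() == pytest.approx(0.0, abs=1e-9)
        assert mat.iloc[0].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_rows_ordered_by_simulated_peak(self):
        from tfcascade import sim

        progs = [
            sim.GeneProgram("early", [1.0], [2.0], [2.0], [1.2], 10.0),
            sim.GeneProgram("late", [1.0], [2.0], [8.0], [1.2], 10.0),
        ]
        data, _ = sim.simulate_trajectory_counts(progs, 300, seed=11)
        fits = {p.gene_id: nbgam.fit_gene(data, p.gene_id) for p in progs}
        peaks = cascade.cascade_table(list(fits.values()))
        mat = cascade.build_cascade(fits, peaks, 0)
        assert list(mat.index) == ["early", "late"]

    def test_empty_when_nothing_involved(self, fitted_bump):
        peaks = pd.DataFrame(
            [{"gene": "g0002", "lineage": 0, "involved": False,
              "min_p_adj": 0.9, "peak_time": None, "peak_rule": None}]
        )
        assert cascade.build_cascade(fitted_bump, peaks, 0).empty


def _constructed_fits_with_maxima(maxima_by_gene, rng):
    """Synthetic fits whose response-scale maxima per lineage are prescribed."""
    fits, rows = {}, []
    for gene, maxima in maxima_by_gene.items():
        fit = random_gene_fit(rng)
        L = len(maxima)
        fit.beta = np.zeros((L, fit.n_basis))
        fit.lineage_ranges = [fit.lineage_ranges[0]] * L
        for l, m in enumerate(maxima):
            # constant smoother at log(m): its maximum is exactly m
            fit.beta[l] = math.log(m)
        fits[gene] = fit
        for l in range(L):
            rows.append({"gene": gene, "lineage": l, "involved": True,
                         "min_p_adj": 0.01, "peak_time": 5.0, "peak_rule": "zero_crossing"})
    return fits, pd.DataFrame(rows)


class TestSpecificAndShared:
    def test_identical_smoothers_specific_nowhere(self):
        fits, inv = _constructed_fits_with_maxima({"a": (4.0, 4.0, 4.0)}, np.random.default_rng(8))
        spec = cascade.lineage_specific_tfs(fits, inv)
        assert all(len(s) == 0 for s in spec.values())

    def test_ratio_rule_arithmetic(self):
        # maxima (10, 4, 4): 10 >= 1.5*4 -> specific to lineage 0 only
        fits, inv = _constructed_fits_with_maxima({"a": (10.0, 4.0, 4.0)}, np.random.default_rng(9))
        spec = cascade.lineage_specific_tfs(fits, inv)
        assert spec[0] == {"a"} and not spec[1] and not spec[2]

    def test_ratio_boundary_exclusive(self):
        # 5.9 < 1.5*4 -> not specific anywhere
        fits, inv = _constructed_fits_with_maxima({"a": (5.9, 4.0, 4.0)}, np.random.default_rng(10))
        spec = cascade.lineage_specific_tfs(fits, inv)
        assert all(len(s) == 0 for s in spec.values())

    def test_single_lineage_rejected(self):
        fits, inv = _constructed_fits_with_maxima({"a": (4.0,)}, np.random.default_rng(11))
        with pytest.raises(ValueError):
            cascade.lineage_specific_tfs(fits, inv)

    @staticmethod
    def _peaks(by_gene):
        rows = []
        for gene, times in by_gene.items():
            for l, t in enumerate(times):
                rows.append({"gene": gene, "lineage": l, "involved": t is not None,
                             "min_p_adj": 0.01, "peak_time": t, "peak_rule": "zero_crossing"})
        return pd.DataFrame(rows)

    def test_identical_peaks_shared(self):
        assert cascade.shared_tfs(self._peaks({"a": (2.0, 2.0, 2.0)})) == {"a"}

    def test_spread_peaks_not_shared(self):
        assert cascade.shared_tfs(self._peaks({"a": (2.0, 3.5, 2.2)})) == set()

    def test_spread_exactly_delta_not_shared(self):
        assert cascade.shared_tfs(self._peaks({"a": (2.0, 3.0, 2.5)})) == set()

    def test_missing_peak_not_shared(self):
        assert cascade.shared_tfs(self._peaks({"a": (2.0, None, 2.2)})) == set()

    def test_permutation_invariance(self):
        by_gene = {"a": (2.0, 2.1, 2.3), "b": (1.0, 5.0, 1.2), "c": (7.0, 7.4, 7.9)}
        peaks = self._peaks(by_gene)
        shuffled = peaks.sample(frac=1.0, random_state=0)
        assert cascade.shared_tfs(peaks) == cascade.shared_tfs(shuffled) == {"a", "c"}


class TestClusterCascade:
    def test_singletons_when_k_equals_rows(self):
        mat = pd.DataFrame(np.random.default_rng(12).normal(size=(4, 10)),
                           index=list("abcd"))
        labels = cascade.cluster_cascade(mat, 4)
        assert labels.nunique() == 4

    def test_separable_groups_recovered(self):
        rng = np.random.default_rng(13)
        a = np.tile([5.0, 5, 5, 0, 0, 0], (6, 1)) + rng.normal(0, 0.1, (6, 6))
        b = np.tile([0.0, 0, 0, 5, 5, 5], (6, 1)) + rng.normal(0, 0.1, (6, 6))
        mat = pd.DataFrame(np.vstack([a, b]))
        labels = cascade.cluster_cascade(mat, 2)
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_too_large_rejected(self):
        mat = pd.DataFrame(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            cascade.cluster_cascade(mat, 4)


def hypergeom_tail_oracle(overlap, M, K, n):
    """P(X >= overlap) by enumerating the hypergeometric pmf with math.comb."""
    total = 0.0
    for x in range(overlap, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
    return total


class TestEnrichment:
    universe = {f"g{i}" for i in range(20)}

    def test_zero_overlap_p_one(self):
        cluster = {"g0", "g1"}
        table = cascade.enrich_hypergeom(cluster, {"s": {"g10", "g11"}}, self.universe)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        cluster = {f"g{i}" for i in range(5)}
        gene_set = {"g0", "g1", "g2", "g3", "g10"}
        table = cascade.enrich_hypergeom(cluster, {"s": gene_set}, self.universe)
        assert table["p"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(4, 20, 5, 5), abs=1e-12
        )

    def test_cluster_equals_universe_degenerate(self):
        sets = {"a": {"g0", "g3"}, "b": {"g5"}}
        table = cascade.enrich_hypergeom(set(self.universe), sets, self.universe)
        assert np.allclose(table["p"], 1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cascade.enrich_hypergeom(set(), {"s": {"x"}}, set())

    def test_top_n_truncation_sorted(self):
        rng = np.random.default_rng(14)
        sets = {f"s{i}": set(rng.choice(sorted(self.universe), 4, replace=False))
                for i in range(15)}
        table = cascade.enrich_hypergeom({"g0", "g1", "g2"}, sets, self.universe, top_n=10)
        assert len(table) == 10
        assert (table["p"].diff().dropna() >= 0).all()
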