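import numpy as np
import pytest

from tfcascade import nbgam, sim


@pytest.fixture(scope="session")
def bump_dataset():
    """One-lineage dataset of 8 bump genes + 2 null genes, 300 cells."""
    programs = sim.make_programs(10, n_lineages=1, frac_null=0.2, seed=42)
    data, truth = sim.simulate_trajectory_counts(programs, 300, seed=42)
    return programs, data, truth


@pytest.fixture(scope="session")
def fitted_bump(bump_dataset):
    """Fits for every gene of the bump dataset, keyed by gene id."""
    programs, data, _ = bump_dataset
    spec = nbgam.build_knots(data.assigned_pseudotime(), nbgam.SplineSpec())
    return {p.gene_id: nbgam.fit_gene(data, p.gene_id, spec) for p in programs}


@pytest.fixture(scope="session")
def three_lineage_dataset():
    """Three-lineage dataset of 6 bump genes, 150 cells per lineage."""
    programs = sim.make_programs(6, n_lineages=3, seed=7)
    data, truth = sim.simulate_trajectory_counts(programs, 150, seed=7)
    return programs, data, truth


def random_gene_fit(rng, n_basis=6, domain=(0.0, 10.0)):
    """A synthetic GeneFit with random coefficients and a random SPD covariance."""
    lo, hi = domain
    interior = np.sort(rng.uniform(lo + 1, hi - 1, n_basis - 4))
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    spec = nbgam.SplineSpec(n_basis=n_basis, knots=knots)
    beta = rng.normal(0, 1.5, (1, n_basis))
    A = rng.normal(0, 0.3, (n_basis, n_basis))
    V = A @ A.T + 0.01 * np.eye(n_basis)
    return nbgam.GeneFit(
        gene="synthetic", beta=beta, alpha=np.zeros(0), phi=5.0, V=V,
        loglik=0.0, aic=0.0, n_params=n_basis + 1, converged=True,
        degenerate=False, spec=spec, lineage_ranges=[(lo, hi)],
    )
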