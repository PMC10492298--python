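"""Likelihood, symmetric NPMLE, and posterior-mean denoising."""

import math

import numpy as np
import pytest

from trialref import (
    ComparisonRecord,
    ContingencyTable,
    EffectGrid,
    PriorEstimate,
    denoise_all,
    fit_symmetric_npmle,
    likelihood_matrix,
    log_likelihood,
    make_comparison_id,
    marginal_log_likelihood,
    posterior_mean,
    prior_cdf,
)

from conftest import oracle_log_likelihood, oracle_simplex_search, random_table

LOG2 = math.log(2.0)


def record_for(table: ContingencyTable, name: str = "R1") -> ComparisonRecord:
    return ComparisonRecord(
        comparison_id=make_comparison_id("X", "Y", name),
        drug_a="X", drug_b="Y", ae=name, nct_ids=("N1",), table=table,
    )


class TestEffectGrid:
    def test_default_grid_shape(self):
        grid = EffectGrid.symmetric()
        assert grid.atoms.size == 279
        assert grid.atoms[grid.center] == 0.0
        assert grid.atoms[-1] >= math.log(1000.0) - 1e-9

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError):
            EffectGrid(np.array([-1.0, 0.0, 2.0]))

    def test_grid_without_zero_rejected(self):
        with pytest.raises(ValueError):
            EffectGrid(np.array([-1.0, -0.5, 0.5, 1.0]))


class TestLogLikelihood:
    def test_central_case_balanced_table(self):
        # at omega=0 the law is central hypergeometric: C(2,1)C(2,1)/C(4,2) = 2/3
        assert log_likelihood(ContingencyTable(1, 1, 1, 1), 0.0) == pytest.approx(
            math.log(2 / 3), abs=1e-12
        )

    def test_no_events_means_flat_likelihood(self):
        table = ContingencyTable(0, 50, 0, 70)
        for omega in (-3.0, 0.0, 2.5):
            assert log_likelihood(table, omega) == 0.0

    def test_matches_exact_enumeration_oracle_on_zero_cell_table(self):
        table = ContingencyTable(35, 225, 0, 264)
        expected = oracle_log_likelihood(table, LOG2)
        assert log_likelihood(table, LOG2) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("omega", [-1.7, -LOG2, 0.3, 1.1, 2 * LOG2])
    def test_matches_oracle_on_random_tables(self, omega, rng):
        for _ in range(10):
            table = random_table(rng, max_n=60)
            assert log_likelihood(table, omega) == pytest.approx(
                oracle_log_likelihood(table, omega), rel=1e-9, abs=1e-9
            )

    def test_pmf_normalizes_over_support(self, rng):
        for _ in range(20):
            table = random_table(rng, max_n=80)
            for omega in (-2.0, 0.0, 0.7, 3.0):
                lo = max(0, table.m - table.n_b)
                hi = min(table.n_a, table.m)
                total = sum(
                    math.exp(log_likelihood(
                        ContingencyTable(x, table.n_a - x, table.m - x,
                                         table.n_b - (table.m - x)),
                        omega,
                    ))
                    for x in range(lo, hi + 1)
                )
                assert total == pytest.approx(1.0, abs=1e-12)


class TestLikelihoodMatrix:
    def test_zero_column_is_zero(self, rng):
        grid = EffectGrid(np.array([-1.0, 0.0, 1.0]))
        mat = likelihood_matrix([random_table(rng) for _ in range(5)], grid)
        assert np.all(mat[:, 1] == 0.0)

    def test_matches_elementwise_calls_up_to_row_shift(self, rng):
        grid = EffectGrid(np.array([-2.0, -0.5, 0.0, 0.5, 2.0]))
        tables = [random_table(rng) for _ in range(4)]
        mat = likelihood_matrix(tables, grid)
        for i, table in enumerate(tables):
            shift = log_likelihood(table, 0.0)
            for j, atom in enumerate(grid.atoms):
                assert mat[i, j] == pytest.approx(
                    log_likelihood(table, atom) - shift, abs=1e-9
                )

    def test_flat_rows_for_zero_event_tables(self):
        grid = EffectGrid.symmetric(step=0.5, max_abs=2.0)
        mat = likelihood_matrix([ContingencyTable(0, 10, 0, 12)], grid)
        assert np.all(mat == 0.0)


class TestSymmetricNpmle:
    def test_flat_likelihoods_leave_weights_uniform(self):
        grid = EffectGrid(np.array([-1.0, 0.0, 1.0]))
        prior = fit_symmetric_npmle([ContingencyTable(0, 10, 0, 10)], grid)
        # uniform over the half grid, reflected: w(0)=1/2, w(+-1)=1/4
        assert prior.weights == pytest.approx([0.25, 0.5, 0.25])

    def test_objective_beats_point_mass_at_zero(self, rng):
        tables = [random_table(rng) for _ in range(20)]
        grid = EffectGrid.symmetric(step=0.25, max_abs=3.0)
        prior = fit_symmetric_npmle(tables, grid)
        delta0 = PriorEstimate.point_mass_at_zero(grid)
        assert marginal_log_likelihood(prior, tables) >= (
            marginal_log_likelihood(delta0, tables) - 1e-9
        )

    def test_em_matches_exhaustive_simplex_search(self, rng):
        """On a 3-atom half-grid the EM optimum equals brute-force search."""
        tables = [random_table(rng, max_n=40) for _ in range(5)]
        grid = EffectGrid(np.array([-2.0, -0.8, 0.0, 0.8, 2.0]))
        prior = fit_symmetric_npmle(tables, grid, tol=1e-13, max_iter=200000)
        # independent kernels from the enumeration oracle
        kernels = np.empty((5, 3))
        for i, table in enumerate(tables):
            l0 = math.exp(oracle_log_likelihood(table, 0.0))
            lp = [
                0.5 * (math.exp(oracle_log_likelihood(table, +g))
                       + math.exp(oracle_log_likelihood(table, -g)))
                for g in (0.8, 2.0)
            ]
            kernels[i] = [l0, lp[0], lp[1]]
        oracle_obj = oracle_simplex_search(kernels)
        # put the EM objective on the oracle's (unshifted) scale
        em_obj = marginal_log_likelihood(prior, tables) + sum(
            oracle_log_likelihood(t, 0.0) for t in tables
        )
        assert em_obj == pytest.approx(oracle_obj, abs=1e-6)

    def test_em_objective_nondecreasing(self, rng):
        tables = [random_table(rng) for _ in range(10)]
        grid = EffectGrid.symmetric(step=0.5, max_abs=2.0)
        objs = []
        for iters in (1, 2, 5, 10, 50):
            prior = fit_symmetric_npmle(tables, grid, tol=0.0, max_iter=iters)
            objs.append(marginal_log_likelihood(prior, tables))
        assert all(b >= a - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_weights_exactly_symmetric(self, rng):
        tables = [random_table(rng) for _ in range(15)]
        prior = fit_symmetric_npmle(tables, EffectGrid.symmetric(step=0.2, max_abs=3.0))
        assert np.array_equal(prior.weights, prior.weights[::-1])
        assert abs(prior.weights.sum() - 1.0) <= 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_symmetric_npmle([], EffectGrid.symmetric(step=0.5, max_abs=1.0))


class TestPosteriorMean:
    def test_point_mass_prior_gives_zero(self, rng):
        grid = EffectGrid.symmetric(step=0.5, max_abs=2.0)
        delta0 = PriorEstimate.point_mass_at_zero(grid)
        for _ in range(5):
            assert posterior_mean(delta0, random_table(rng)) == 0.0

    def test_flat_table_gives_zero_under_any_symmetric_prior(self):
        grid = EffectGrid(np.array([-1.5, 0.0, 1.5]))
        prior = PriorEstimate(grid, np.array([0.3, 0.4, 0.3]))
        assert posterior_mean(prior, ContingencyTable(0, 30, 0, 40)) == 0.0

    def test_two_atom_prior_closed_form(self):
        """Two-atom prior at +-log 4: posterior mean has a closed form."""
        log4 = math.log(4.0)
        grid = EffectGrid(np.array([-log4, 0.0, log4]))
        prior = PriorEstimate(grid, np.array([0.5, 0.0, 0.5]))
        table = ContingencyTable(3, 7, 1, 9)
        lp = math.exp(oracle_log_likelihood(table, log4))
        lm = math.exp(oracle_log_likelihood(table, -log4))
        expected = log4 * (lp - lm) / (lp + lm)
        assert posterior_mean(prior, table) == pytest.approx(expected, rel=1e-10)

    def test_column_swap_negates_exactly(self, rng):
        tables = [random_table(rng) for _ in range(25)]
        prior = fit_symmetric_npmle(tables, EffectGrid.symmetric(step=0.1, max_abs=4.0))
        for table in tables:
            pm = posterior_mean(prior, table)
            assert posterior_mean(prior, table.swapped()) == -pm

    def test_magnitude_bounded_by_grid(self, rng):
        grid = EffectGrid.symmetric(step=0.5, max_abs=2.0)
        prior = PriorEstimate(grid, np.full(grid.atoms.size, 1.0 / grid.atoms.size))
        for _ in range(10):
            assert abs(posterior_mean(prior, random_table(rng))) <= 2.0 + 1e-12


class TestDenoiseAll:
    def test_matches_per_record_calls_and_preserves_order(self, rng):
        records = [record_for(random_table(rng), f"R{i}") for i in range(8)]
        prior = fit_symmetric_npmle(
            [r.table for r in records], EffectGrid.symmetric(step=0.25, max_abs=2.0)
        )
        effects = denoise_all(prior, records)
        assert [e.record for e in effects] == records
        for e in effects:
            assert e.omega_eb == posterior_mean(prior, e.record.table)
            assert e.or_eb == math.exp(e.omega_eb)
            assert math.isfinite(e.or_eb)


class TestPriorCdf:
    @pytest.fixture
    def prior(self):
        grid = EffectGrid(np.array([-1.0, -0.5, 0.0, 0.5, 1.0]))
        return PriorEstimate(grid, np.array([0.1, 0.2, 0.4, 0.2, 0.1]))

    def test_bounds(self, prior):
        assert prior_cdf(prior, 1.0) == 1.0
        assert prior_cdf(prior, 5.0) == 1.0
        assert prior_cdf(prior, -1.5) == 0.0

    def test_right_continuity_and_symmetry_split(self, prior):
        w0 = 0.4
        assert prior_cdf(prior, 0.0) == pytest.approx((1 - w0) / 2 + w0)
        assert prior_cdf(prior, -1e-9) == pytest.approx((1 - w0) / 2)
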