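import numpy as np
import pytest

from memchain import (Monomial, Potential, SpectralData, build_transfer,
                      empirical_average, expectation, kse, memc_from_potential,
                      memc_from_spectral, memoryless_memc, perron, pressure,
                      sample)
from memchain.transfer import sample_chain, stationary_distribution

from conftest import ONE_OBS, random_potential


class TestTransferConstruction:
    def test_one_observable_matrix_structure(self, one_obs_chain):
        T, _, _ = one_obs_chain(-1.0)
        mat = T.matrix
        e = np.exp(-1.0)
        # rows for states with neuron 2 active (indices 2, 3) read (1, e, 1, e)
        for row in (2, 3):
            np.testing.assert_allclose(mat[row], [1, e, 1, e])
        for row in (0, 1):
            np.testing.assert_allclose(mat[row], np.ones(4))

    def test_zero_potential_all_ones(self):
        H = Potential(1, 2, [])
        mat = build_transfer(H).matrix
        np.testing.assert_array_equal(mat, np.ones((2, 2)))

    def test_memory_two_de_bruijn_sparsity(self):
        H = Potential(1, 3, [(0.3, Monomial([(1, 0), (1, 2)]))])
        mat = build_transfer(H).matrix
        assert mat.shape == (4, 4)
        assert ((mat > 0).sum(axis=1) == 2).all()
        # state (a, b) can only reach states starting with b
        for ell in range(4):
            b = ell >> 1
            allowed = np.nonzero(mat[ell])[0]
            assert all((lp & 1) == b for lp in allowed)

    def test_nonfinite_coefficient_rejected(self):
        m = Monomial([(1, 0)])
        with pytest.raises(ValueError):
            H = Potential(1, 2, [(1.0, m)])
            H.terms[0] = (np.inf, m)
            build_transfer(H)


class TestPerron:
    @pytest.mark.parametrize("h1", [-2.0, -1.0, 0.0, 1.0])
    def test_one_observable_eigenvalue(self, one_obs_chain, h1):
        _, S, _ = one_obs_chain(h1)
        assert S.rho == pytest.approx(np.exp(h1) + 3.0, abs=1e-10)

    def test_all_ones_two_state(self):
        T = build_transfer(Potential(1, 2, []))
        S = perron(T)
        assert S.rho == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(S.left, S.left[0])
        assert np.allclose(S.right, S.right[0])

    def test_residuals_small(self, one_obs_chain):
        T, S, _ = one_obs_chain(-1.3)
        assert np.max(np.abs(T.matrix @ S.right - S.rho * S.right)) < 1e-10
        assert np.max(np.abs(S.left @ T.matrix - S.rho * S.left)) < 1e-10
        assert S.left.min() > 0 and S.right.min() > 0

    def test_agrees_with_full_spectrum(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            H = random_potential(rng, 2, 2, n_terms=5)
            T = build_transfer(H)
            S = perron(T)
            evals = np.linalg.eigvals(T.matrix)
            assert S.rho == pytest.approx(np.max(np.abs(evals)), rel=1e-10)
            # strict spectral gap
            second = np.sort(np.abs(evals))[-2]
            assert S.rho > second


class TestMarkovChain:
    def test_uniform_chain_at_zero_coupling(self, one_obs_chain):
        _, _, M = one_obs_chain(0.0)
        np.testing.assert_allclose(M.transition, np.full((4, 4), 0.25), atol=1e-12)
        np.testing.assert_allclose(M.stationary, np.full(4, 0.25), atol=1e-12)

    @pytest.mark.parametrize("h1", [-2.0, -1.0, 0.7])
    def test_invariant_measure_closed_form(self, one_obs_chain, h1):
        _, S, M = one_obs_chain(h1)
        rho = S.rho
        expected = np.array(
            [4, 2 * (rho - 2), 2 * (rho - 2), (rho - 2) ** 2]) / rho**2
        np.testing.assert_allclose(M.stationary, expected, atol=1e-10)

    def test_eigenvector_scaling_invariance(self, one_obs_chain):
        T, S, M = one_obs_chain(-0.8)
        scaled = SpectralData(rho=S.rho, left=3.7 * S.left, right=0.2 * S.right)
        M2 = memc_from_spectral(T, scaled)
        np.testing.assert_allclose(M2.transition, M.transition, atol=1e-12)
        np.testing.assert_allclose(M2.stationary, M.stationary, atol=1e-12)

    def test_stationarity_oracle_linear_solve(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            M = memc_from_potential(random_potential(rng, 2, 2, 6))
            n = M.state_space.n_states
            A = np.vstack([M.transition.T - np.eye(n), np.ones(n)])
            b = np.zeros(n + 1)
            b[-1] = 1.0
            pi, *_ = np.linalg.lstsq(A, b, rcond=None)
            np.testing.assert_allclose(M.stationary, pi, atol=1e-10)


class TestPressureAndExpectations:
    def test_pressure_uniform(self, one_obs_chain):
        _, S, _ = one_obs_chain(0.0)
        assert pressure(S) == pytest.approx(np.log(4.0), abs=1e-12)

    def test_pressure_zero_potential_scales_with_n(self):
        for n in (1, 2, 3):
            T = build_transfer(Potential(n, 2, []))
            assert pressure(perron(T)) == pytest.approx(n * np.log(2.0), abs=1e-10)

    def test_constant_observable_expectation(self, one_obs_chain):
        _, _, M = one_obs_chain(-1.0)
        assert expectation(M, Monomial([])) == pytest.approx(1.0, abs=1e-12)

    def test_constrained_expectation_closed_form(self, one_obs_chain):
        _, _, M = one_obs_chain(-1.0)
        assert expectation(M, ONE_OBS) == pytest.approx(
            np.exp(-1) / (np.exp(-1) + 3), abs=1e-10)

    def test_pressure_gradient_is_expectation(self):
        # d ln rho / dh at h = -1 equals the model average of the monomial
        h, eps = -1.0, 1e-6
        def lnrho(x):
            T = build_transfer(Potential(2, 2, [(x, ONE_OBS)]))
            return pressure(perron(T))
        fd = (lnrho(h + eps) - lnrho(h - eps)) / (2 * eps)
        T = build_transfer(Potential(2, 2, [(h, ONE_OBS)]))
        M = memc_from_spectral(T, perron(T))
        assert fd == pytest.approx(expectation(M, ONE_OBS), abs=1e-8)

    def test_variational_identity(self):
        # S(mu) + mu[H] = ln rho for random potentials
        rng = np.random.default_rng(33)
        combos = [(1, 2), (2, 2), (3, 2), (1, 3), (2, 3)]
        for _ in range(20):
            n, r = combos[rng.integers(len(combos))]
            H = random_potential(rng, n, r, n_terms=5)
            T = build_transfer(H)
            S = perron(T)
            M = memc_from_spectral(T, S)
            lhs = kse(M) + expectation(M, H)
            assert lhs == pytest.approx(pressure(S), abs=1e-8)


class TestMemoryless:
    def test_uniform_when_flat(self):
        M = memoryless_memc(Potential(3, 1, []))
        np.testing.assert_allclose(M.stationary, np.full(8, 1 / 8), atol=1e-12)
        assert np.allclose(M.transition, M.transition[0])

    def test_two_state_logistic(self):
        h = 0.7
        M = memoryless_memc(Potential(1, 1, [(h, Monomial([(1, 0)]))]))
        assert M.stationary[1] == pytest.approx(np.exp(h) / (1 + np.exp(h)))

    def test_rho_is_partition_function(self):
        rng = np.random.default_rng(8)
        H = random_potential(rng, 2, 1, n_terms=3)
        M = memoryless_memc(H)
        Z = np.exp(H.eval_on_indices(np.arange(4))).sum()
        assert M.spectral.rho == pytest.approx(Z, abs=1e-12)
        # transfer matrix route: rho = Z and remaining spectrum is 0
        T = build_transfer(H)
        evals = np.sort(np.abs(np.linalg.eigvals(T.matrix)))
        assert evals[-1] == pytest.approx(Z, abs=1e-10)
        assert evals[:-1].max() < 1e-10

    def test_matches_general_construction(self):
        rng = np.random.default_rng(9)
        H = random_potential(rng, 2, 1, n_terms=3)
        M1 = memoryless_memc(H)
        M2 = memc_from_potential(H)
        np.testing.assert_allclose(M1.transition, M2.transition, atol=1e-10)
        np.testing.assert_allclose(M1.stationary, M2.stationary, atol=1e-10)

    def test_wrong_range_rejected(self):
        with pytest.raises(ValueError):
            memoryless_memc(Potential(1, 2, []))


class TestSampling:
    def test_deterministic_given_seed(self, one_obs_chain):
        _, _, M = one_obs_chain(-1.0)
        assert sample(M, 500, seed=4) == sample(M, 500, seed=4)
        assert sample(M, 500, seed=4) != sample(M, 500, seed=5)

    def test_uniform_memoryless_frequencies(self):
        M = memoryless_memc(Potential(2, 1, []))
        train = sample(M, 40000, seed=7)
        for k in (1, 2):
            avg = empirical_average(train, Monomial([(k, 0)]))
            assert abs(avg - 0.5) < 3 * 0.5 / np.sqrt(40000)

    def test_sampled_average_matches_model(self, one_obs_chain):
        _, _, M = one_obs_chain(-1.0)
        train = sample(M, 100_000, seed=13)
        target = np.exp(-1) / (np.exp(-1) + 3)
        avg = empirical_average(train, ONE_OBS)
        # generous 3-sigma bound treating windows as independent
        assert abs(avg - target) < 3 * np.sqrt(target * (1 - target) / 1e5) * 2

    def test_chain_path_respects_transitions(self):
        rng = np.random.default_rng(5)
        M = memc_from_potential(random_potential(rng, 1, 3, n_terms=3))
        path = sample_chain(M.transition, M.stationary, 200, seed=1)
        for a, b in zip(path[:-1], path[1:]):
            assert M.transition[a, b] > 0


def test_stationary_distribution_doubly_stochastic():
    P = np.full((4, 4), 0.25)
    np.testing.assert_allclose(stationary_distribution(P), np.full(4, 0.25),
                               atol=1e-12)
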