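import numpy as np
import pytest

from memchain import (Monomial, Potential, build_transfer, memc_from_spectral,
                      perron)

ONE_OBS = Monomial([(1, 1), (2, 0)])  # neuron 2 at time 0 drives neuron 1 at time 1


@pytest.fixture
def one_obs_chain():
    """Factory for the two-neuron, one-observable chain H = h1 * s1^1 s2^0."""

    def make(h1):
        H = Potential(2, 2, [(float(h1), ONE_OBS)])
        T = build_transfer(H)
        S = perron(T)
        return T, S, memc_from_spectral(T, S)

    return make


def random_potential(rng, n_neurons, rng_r, n_terms, scale=1.0):
    """Random potential with distinct nonempty monomials and N(0, scale) coefs."""
    n_mono = (1 << (n_neurons * rng_r)) - 1
    n_terms = min(n_terms, n_mono)
    idx = rng.choice(np.arange(1, n_mono + 1), size=n_terms, replace=False)
    from memchain.potentials import monomial_from_index

    terms = [
        (scale * rng.standard_normal(), monomial_from_index(int(i), n_neurons, rng_r))
        for i in idx
    ]
    return Potential(n_neurons, rng_r, terms)


def random_cross_monomials(rng, n_neurons, n_terms):
    """Distinct range-2 monomials touching both time slices of the window.

    Coefficients of such monomials are identifiable: no linear combination
    of cross-temporal indicator masks is a coboundary (which only involves
    single-slice functions), so the pressure Hessian is nondegenerate.
    """
    from memchain.potentials import monomial_from_index

    lo = (1 << n_neurons) - 1
    hi = lo << n_neurons
    pool = [i for i in range(1, 1 << (2 * n_neurons))
            if (i & lo) and (i & hi)]
    idx = rng.choice(pool, size=min(n_terms, len(pool)), replace=False)
    return [monomial_from_index(int(i), n_neurons, 2) for i in idx]
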