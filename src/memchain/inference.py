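"""Constrained maximum-entropy inference of Markov chains.

Given K observables f_k (monomials over a spike window) with target averages
C_k in (0, 1), the maximum-entropy Markov chain matching the constraints is
found by minimizing the smooth convex dual

    g(h) = ln rho(h) - sum_k h_k C_k,

where ln rho(h) is the topological pressure of the potential
H = sum_k h_k f_k.  The gradient is exact: dg/dh_k = mu_h[f_k] - C_k, with
mu_h the chain induced by h, so at the optimum the model expectations match
every target.  Convexity of the pressure makes the solution unique.

The module follows the Model -> Results pattern: construct a
:class:`MaxentMarkovModel` from constraints (or from a spike train via
:meth:`MaxentMarkovModel.from_train`), call :meth:`~MaxentMarkovModel.fit`,
and read estimates, diagnostics and derived quantities off the returned
:class:`MaxentMarkovResults`.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.optimize

from . import entropy_production as ep
from .potentials import Potential
from .spike_data import SpikeTrain, empirical_average
from .transfer import (MarkovChain, build_transfer, expectation,
                       memc_from_spectral, perron, sample)

__all__ = ["MaxentMarkovModel", "MaxentMarkovResults"]


class MaxentMarkovModel:
    """Maximum-entropy Markov chain model for binary spike data.

    Parameters
    ----------
    observables : sequence of Monomial
        The K constrained observables; must be distinct.
    targets : sequence of float
        Target averages C_k, each strictly inside (0, 1).
    n_neurons : int, optional
        Population size; inferred from the observables if omitted.
    potential_range : int, optional
        Range R of the fitted potential; defaults to the maximum observable
        range.  The induced chain has memory D = max(R - 1, 1).
    """

    def __init__(self, observables, targets, n_neurons=None, potential_range=None):
        observables = list(observables)
        targets = np.asarray(targets, dtype=float)
        if len(observables) != targets.size:
            raise ValueError("observables and targets must have equal length")
        if len(observables) == 0:
            raise ValueError("at least one constraint is required")
        if len({m.pairs for m in observables}) != len(observables):
            raise ValueError("observables must be distinct")
        if np.any(targets <= 0.0) or np.any(targets >= 1.0):
            raise ValueError(
                "targets must lie strictly in (0, 1); boundary averages are "
                "unattainable with finite coefficients"
            )
        self.observables = observables
        self.targets = targets
        self.n_neurons = int(n_neurons or max(m.max_neuron for m in observables))
        self.potential_range = int(
            potential_range or max(m.range for m in observables)
        )
        if any(m.range > self.potential_range for m in observables):
            raise ValueError("an observable exceeds the declared potential range")
        if any(m.max_neuron > self.n_neurons for m in observables):
            raise ValueError("an observable references a neuron beyond n_neurons")
        if self.n_neurons * self.potential_range > 20:
            warnings.warn(
                f"N*R = {self.n_neurons * self.potential_range} > 20: "
                "transfer-matrix inference is unreliable at this scale",
                stacklevel=2,
            )

    @classmethod
    def from_train(cls, train: SpikeTrain, observables, n_neurons=None,
                   potential_range=None) -> "MaxentMarkovModel":
        """Build the model with targets set to the train's empirical averages."""
        targets = [empirical_average(train, m) for m in observables]
        bad = [i for i, c in enumerate(targets) if c <= 0.0 or c >= 1.0]
        if bad:
            labels = ", ".join(observables[i].label() for i in bad)
            raise ValueError(
                f"empirical averages of {labels} are 0 or 1; record a longer "
                "train or drop these observables"
            )
        return cls(observables, targets,
                   n_neurons=n_neurons or train.n_neurons,
                   potential_range=potential_range)

    # -- fitting -----------------------------------------------------------

    def potential_at(self, params) -> Potential:
        return Potential(self.n_neurons, self.potential_range,
                         list(zip(np.asarray(params, dtype=float), self.observables)))

    def chain_at(self, params) -> MarkovChain:
        H = self.potential_at(params)
        T = build_transfer(H)
        return memc_from_spectral(T, perron(T))

    def _dual(self, params):
        H = self.potential_at(params)
        T = build_transfer(H)
        S = perron(T)
        M = memc_from_spectral(T, S)
        mu = np.array([expectation(M, f) for f in self.observables])
        value = float(np.log(S.rho)) - float(params @ self.targets)
        grad = mu - self.targets
        return value, grad, M, H

    def fit(self, start_params=None, gtol: float = 1e-8,
            maxiter: int = 500) -> "MaxentMarkovResults":
        """Minimize the convex dual by quasi-Newton (BFGS) with exact gradient."""
        k = len(self.observables)
        x0 = np.zeros(k) if start_params is None else np.asarray(start_params, float)

        def fun(x):
            value, grad, _, _ = self._dual(x)
            return value, grad

        res = scipy.optimize.minimize(
            fun, x0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        value, grad, M, H = self._dual(res.x)
        gradient_norm = float(np.max(np.abs(grad)))
        converged = gradient_norm < max(gtol, 1e-6)
        if not converged:
            warnings.warn(
                f"maximum-entropy fit did not reach gtol: max |mu - C| = "
                f"{gradient_norm:.3e} after {res.nit} iterations",
                stacklevel=2,
            )
        return MaxentMarkovResults(
            model=self, params=np.asarray(res.x, dtype=float), potential=H,
            chain=M, gradient_norm=gradient_norm, iterations=int(res.nit),
            converged=converged, dual_value=value,
        )


class MaxentMarkovResults:
    """Fitted maximum-entropy Markov chain and its diagnostics."""

    def __init__(self, model, params, potential, chain, gradient_norm,
                 iterations, converged, dual_value):
        self.model = model
        self.params = params
        self.potential = potential
        self.chain = chain
        self.gradient_norm = gradient_norm
        self.iterations = iterations
        self.converged = converged
        self.dual_value = dual_value

    @property
    def fitted_averages(self) -> np.ndarray:
        """Model expectations mu[f_k] of the constrained observables."""
        return np.array([expectation(self.chain, f) for f in self.model.observables])

    @property
    def pressure(self) -> float:
        """Topological pressure ln rho of the fitted potential."""
        return float(np.log(self.chain.spectral.rho))

    @property
    def kse(self) -> float:
        return ep.kse(self.chain)

    @property
    def iep(self) -> float:
        return ep.iep_stationary(self.chain)

    def simulate(self, n_bins: int, seed) -> SpikeTrain:
        """Sample a spike train from the fitted chain."""
        return sample(self.chain, n_bins, seed)

    def summary(self) -> str:
        lines = [
            "Maximum-entropy Markov chain fit",
            "=" * 64,
            f"neurons: {self.model.n_neurons}   potential range: "
            f"{self.model.potential_range}   states: {self.chain.state_space.n_states}",
            f"converged: {self.converged}   iterations: {self.iterations}   "
            f"max |mu - C|: {self.gradient_norm:.3e}",
            f"pressure ln rho: {self.pressure:.6f}   KSE: {self.kse:.6f}   "
            f"IEP: {self.iep:.6f}",
            "-" * 64,
            f"{'observable':<28}{'coef h':>12}{'target C':>12}{'fitted mu':>12}",
        ]
        fitted = self.fitted_averages
        for m, h, c, mu in zip(self.model.observables, self.params,
                               self.model.targets, fitted):
            lines.append(f"{m.label():<28}{h:>12.6f}{c:>12.6f}{mu:>12.6f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"MaxentMarkovResults(K={len(self.params)}, "
            f"converged={self.converged}, gradient_norm={self.gradient_norm:.2e})"
        )
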