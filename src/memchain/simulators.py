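"""Mechanistic spiking-network simulators used as ground truth.

Two discrete-time models whose exact 2^N-state transition matrices are
available in closed form, so their stationary distribution and entropy
production can be computed without any inference step:

* a leaky integrate-and-fire (IF) network with Gaussian voltage noise, whose
  one-step spike-pattern transition probabilities factorize over neurons
  through the Gaussian survival function of the distance to threshold; and
* the kinetic Ising model: synchronous Glauber-type updates with fields h_i
  and (generally asymmetric) couplings J_ij.

Both induce ergodic chains with strictly positive transition matrices for
finite parameters.  Asymmetric couplings generically break detailed balance;
the parameter scans quantify the resulting entropy production as a function
of coupling gain alpha and stimulus gain beta, averaged over random coupling
ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .entropy_production import iep_stationary
from .potentials import build_pairwise_1step
from .spike_data import SpikeTrain
from .transfer import (MarkovChain, StateSpace, memc_from_potential,
                       stationary_distribution)

__all__ = [
    "IFParams",
    "KineticIsingParams",
    "if_transition_matrix",
    "if_sample",
    "kinetic_ising_transition_matrix",
    "stationary_of",
    "markov_iep",
    "iep_scan",
    "gamma_ensemble_iep",
]


@dataclass(frozen=True)
class IFParams:
    """Discrete-time leaky integrate-and-fire network parameters.

    Voltage update (sub-threshold):
        V_i(t+1) = gamma V_i(t) (1 - Z[V_i(t)]) + alpha sum_j W_ij Z[V_j(t)]
                   + beta I_i + sigma_b B_i(t),
    with Z[x] = 1{x >= theta} the firing indicator and B standard Gaussian.
    A firing neuron's leak term is reset to zero at the next step.
    """

    n_neurons: int
    weights: np.ndarray
    leak: float = 0.2
    threshold: float = 1.0
    noise: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    stimulus: np.ndarray = field(default=None)

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("weights must be N x N")
        I = (np.ones(self.n_neurons) if self.stimulus is None
             else np.asarray(self.stimulus, dtype=float))
        if I.shape != (self.n_neurons,):
            raise ValueError("stimulus must be length N")
        if not (0.0 <= self.leak <= 1.0):
            raise ValueError("leak must lie in [0, 1]")
        if self.noise <= 0 or self.threshold <= 0:
            raise ValueError("noise and threshold must be positive")
        for arr in (W, I):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "stimulus", I)


@dataclass(frozen=True)
class KineticIsingParams:
    """Synchronously updated kinetic Ising model parameters.

    P[sigma'|sigma] = prod_i exp[(2 sigma'_i - 1) theta_i(sigma)] /
                      (2 cosh theta_i(sigma)),
    theta_i(sigma) = beta h_i + alpha sum_j J_ij (2 sigma_j - 1).
    """

    n_neurons: int
    fields: np.ndarray
    couplings: np.ndarray
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        h = np.asarray(self.fields, dtype=float)
        J = np.asarray(self.couplings, dtype=float)
        if h.shape != (self.n_neurons,) or J.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("fields must be length N and couplings N x N")
        if not (np.isfinite(h).all() and np.isfinite(J).all()):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "fields", h)
        object.__setattr__(self, "couplings", J)


def _patterns(n: int) -> np.ndarray:
    """All 2^n spike patterns as a (2^n, n) binary array, block-index order."""
    states = np.arange(1 << n)
    return ((states[:, None] >> np.arange(n)) & 1).astype(float)


def if_transition_matrix(p: IFParams) -> np.ndarray:
    """Exact one-step pattern transition matrix of the IF network.

    Row = previous pattern sigma', column = next pattern sigma; the firing
    probability of neuron i is the normalized Gaussian survival function of
    (theta - C_i)/sigma_b with drive
    C_i = gamma * alpha * sum_j W_ij sigma'_j + beta * I_i.
    """
    n = p.n_neurons
    pats = _patterns(n)  # (2^n, n)
    drive = p.leak * p.alpha * pats @ p.weights.T + p.beta * p.stimulus[None, :]
    fire = norm.sf((p.threshold - drive) / p.noise)  # (2^n states, n neurons)
    P = np.ones((1 << n, 1 << n))
    for i in range(n):
        bit = pats[:, i]  # target-pattern bit of neuron i, per column
        P *= np.where(bit[None, :] == 1.0, fire[:, i][:, None],
                      1.0 - fire[:, i][:, None])
    return P


def if_sample(p: IFParams, n_bins: int, seed, v0=None
              ) -> tuple[SpikeTrain, np.ndarray]:
    """Simulate the voltage dynamics; returns (spike train, voltage trace).

    The raster records the firing state Z[V_i(t)] at each step; the voltage
    trace has shape (N, n_bins).
    """
    rng = np.random.default_rng(seed)
    n = p.n_neurons
    V = np.zeros(n) if v0 is None else np.asarray(v0, dtype=float).copy()
    volts = np.empty((n, n_bins))
    raster = np.empty((n, n_bins), dtype=np.uint8)
    for t in range(n_bins):
        volts[:, t] = V
        z = (V >= p.threshold).astype(float)
        raster[:, t] = z.astype(np.uint8)
        V = (p.leak * V * (1.0 - z) + p.alpha * (p.weights @ z)
             + p.beta * p.stimulus + p.noise * rng.standard_normal(n))
    return SpikeTrain(raster), volts


def kinetic_ising_transition_matrix(p: KineticIsingParams,
                                    strict_as_printed: bool = False) -> np.ndarray:
    """Exact transition matrix of the synchronous kinetic Ising model.

    ``strict_as_printed`` replaces the coupling drive sum_j J_ij (2 sigma_j-1)
    with sum_j J_ij (2 sigma_i-1) (a self-referential variant kept for
    auditability; not meaningful as a network model).
    """
    n = p.n_neurons
    pats = _patterns(n)
    spins = 2.0 * pats - 1.0  # (2^n, n)
    if strict_as_printed:
        theta = p.beta * p.fields[None, :] + p.alpha * spins * p.couplings.sum(axis=1)[None, :]
    else:
        theta = p.beta * p.fields[None, :] + p.alpha * spins @ p.couplings.T
    # logP[sigma, sigma'] = sum_i spins'_i theta_i(sigma) - log(2 cosh theta_i(sigma))
    logP = theta @ spins.T - np.sum(np.log(2.0 * np.cosh(theta)), axis=1)[:, None]
    return np.exp(logP)


def stationary_of(P: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unique stationary distribution of an ergodic stochastic matrix."""
    return stationary_distribution(P, tol)


def markov_iep(P: np.ndarray, pi: np.ndarray | None = None) -> float:
    """IEP of an arbitrary pattern chain (memory 1), given or solving pi."""
    if pi is None:
        pi = stationary_of(P)
    space = StateSpace(max(int(np.log2(P.shape[0])), 1), 1, memoryless=False)
    if (1 << space.n_neurons) != P.shape[0]:
        raise ValueError("matrix size must be a power of two")
    M = MarkovChain(space, P, pi)
    return iep_stationary(M, mode="naive")


def iep_scan(model: str, alpha_grid, beta_grid, n_realizations: int = 500,
             seed=0, n_neurons: int = 6, leak: float = 0.2, noise: float = 1.0,
             threshold: float = 1.0, field_mean: float = -3.0,
             field_sd: float = 1.0, coupling_sd: float = 1.0) -> pd.DataFrame:
    """Mean IEP over random coupling ensembles on an (alpha, beta) grid.

    model="if": N=6 IF network, W_ij ~ N(0, 1), I_i = 1, leak 0.2, noise 1,
    threshold 1.  model="ki": kinetic Ising, h_i ~ N(-3, 1), J_ij ~ N(0, 1).
    Returns a tidy frame with columns alpha, beta, mean_iep, stderr_iep, n.
    """
    if model not in ("if", "ki"):
        raise ValueError("model must be 'if' or 'ki'")
    rng = np.random.default_rng(seed)
    rows = []
    for a in np.asarray(alpha_grid, dtype=float):
        for b in np.asarray(beta_grid, dtype=float):
            vals = np.empty(n_realizations)
            for r in range(n_realizations):
                if model == "if":
                    W = rng.standard_normal((n_neurons, n_neurons))
                    P = if_transition_matrix(IFParams(
                        n_neurons=n_neurons, weights=W, leak=leak,
                        threshold=threshold, noise=noise, alpha=a, beta=b))
                else:
                    h = field_mean + field_sd * rng.standard_normal(n_neurons)
                    J = coupling_sd * rng.standard_normal((n_neurons, n_neurons))
                    P = kinetic_ising_transition_matrix(KineticIsingParams(
                        n_neurons=n_neurons, fields=h, couplings=J,
                        alpha=a, beta=b))
                vals[r] = markov_iep(P)
            rows.append({
                "alpha": a, "beta": b,
                "mean_iep": float(vals.mean()),
                "stderr_iep": float(vals.std(ddof=1) / np.sqrt(n_realizations))
                if n_realizations > 1 else 0.0,
                "n": n_realizations,
            })
    return pd.DataFrame(rows)


def gamma_ensemble_iep(h, J, mean: float = 0.0, sd: float = 1.0,
                       symmetric: bool = False, antisymmetric: bool = False,
                       n_matrices: int = 100, seed=0) -> np.ndarray:
    """IEP samples of the one-time-step pairwise model over random gamma draws.

    For each draw, gamma_ij ~ N(mean, sd^2) (optionally symmetrized or
    antisymmetrized), the range-2 potential with the fixed fields h and
    synchronous couplings J is built, its maximum-entropy chain derived, and
    the stationary IEP recorded.
    """
    if symmetric and antisymmetric:
        raise ValueError("choose at most one of symmetric / antisymmetric")
    h = np.asarray(h, dtype=float)
    J = np.asarray(J, dtype=float)
    n = h.size
    rng = np.random.default_rng(seed)
    out = np.empty(n_matrices)
    for r in range(n_matrices):
        g = mean + sd * rng.standard_normal((n, n))
        if symmetric:
            g = 0.5 * (g + g.T)
        elif antisymmetric:
            g = 0.5 * (g - g.T)
        H = build_pairwise_1step(h, J, g)
        M = memc_from_potential(H)
        out[r] = iep_stationary(M, mode="naive")
    return out
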