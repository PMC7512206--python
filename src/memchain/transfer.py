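"""Transfer matrices, Perron eigendata, and maximum-entropy Markov chains.

A finite-range potential H of range R induces a nonnegative *transfer matrix*
over block states of length D = R-1 (memory D):

    L_H(l, l') = exp(H(w))   if the transition l -> l' is allowed,
                 0           otherwise,

where w is the length-(D+1) block obtained by appending the new pattern of l'
to the state l; a transition is allowed iff the trailing D-1 patterns of l
coincide with the leading D-1 patterns of l'.  L_H is primitive, so by
Perron-Frobenius it has a simple dominant eigenvalue rho > 0 with strictly
positive left/right eigenvectors L, R.  These yield the unique
maximum-entropy Markov chain

    P(l, l') = L_H(l, l') R(l') / (rho R(l)),      pi(l) = L(l) R(l) / <L, R>,

and the topological pressure (free energy) P[H] = ln rho, whose gradient in
the potential coefficients equals the model expectations of the
corresponding monomials.

Range-1 potentials are the memoryless limit: all transitions are allowed,
L_H(s, s') = exp(H(s')), rho = Z = sum exp(H), and the chain is a sequence of
i.i.d. Boltzmann-Gibbs draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .potentials import Potential
from .spike_data import SpikeTrain, block_from_index

__all__ = [
    "StateSpace",
    "TransferMatrix",
    "SpectralData",
    "MarkovChain",
    "build_transfer",
    "perron",
    "memc_from_spectral",
    "memc_from_potential",
    "pressure",
    "memoryless_memc",
    "expectation",
    "sample",
    "sample_chain",
    "stationary_distribution",
]

_DENSE_LIMIT = 1024  # above this, the Perron solve switches to power iteration


@dataclass(frozen=True)
class StateSpace:
    """Enumerated block states of a memory-D chain, in increasing block index."""

    n_neurons: int
    memory: int
    memoryless: bool = False

    def __post_init__(self):
        if self.n_neurons < 1 or self.memory < 1:
            raise ValueError("n_neurons and memory must be >= 1")

    @property
    def n_states(self) -> int:
        return 1 << (self.n_neurons * self.memory)

    @property
    def n_patterns(self) -> int:
        return 1 << self.n_neurons

    def state_block(self, index: int):
        return block_from_index(index, self.n_neurons, self.memory)

    def successor(self, state: int, new_pattern: int) -> int:
        """State reached by shifting in ``new_pattern`` (ignores memoryless flag)."""
        if self.memoryless:
            return new_pattern
        return (state >> self.n_neurons) | (
            new_pattern << (self.n_neurons * (self.memory - 1))
        )

    def transition_block_index(self, state: int, new_pattern: int) -> int:
        """Block index of the length-(D+1) window realized by a transition."""
        if self.memoryless:
            return state | (new_pattern << self.n_neurons)
        return state | (new_pattern << (self.n_neurons * self.memory))

    def transition_blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, window indices) of all structurally allowed transitions."""
        n = self.n_neurons
        states = np.arange(self.n_states, dtype=np.int64)
        patterns = np.arange(self.n_patterns, dtype=np.int64)
        rows = np.repeat(states, self.n_patterns)
        pats = np.tile(patterns, self.n_states)
        if self.memoryless:
            cols = pats
            wins = rows | (pats << n)
        else:
            cols = (rows >> n) | (pats << (n * (self.memory - 1)))
            wins = rows | (pats << (n * self.memory))
        return rows, cols, wins


@dataclass(frozen=True)
class TransferMatrix:
    """Dense nonnegative matrix L_H over a block state space."""

    state_space: StateSpace
    matrix: np.ndarray
    potential: Potential | None = None


@dataclass(frozen=True)
class SpectralData:
    """Perron triple (rho, left L, right R) of a transfer matrix.

    Normalization convention: max(R) = 1 and <L, R> = 1.  Everything public
    built from this data (P, pi, rho, pressure, IEP) is invariant under
    rescaling of the eigenvectors.
    """

    rho: float
    left: np.ndarray
    right: np.ndarray

    @property
    def inner(self) -> float:
        return float(self.left @ self.right)


class MarkovChain:
    """A stationary Markov chain (P, pi) over an enumerated block state space."""

    def __init__(self, state_space: StateSpace, transition: np.ndarray,
                 stationary: np.ndarray, potential: Potential | None = None,
                 spectral: SpectralData | None = None) -> None:
        P = np.asarray(transition, dtype=float)
        pi = np.asarray(stationary, dtype=float)
        n = state_space.n_states
        if P.shape != (n, n) or pi.shape != (n,):
            raise ValueError("transition/stationary shapes inconsistent with state space")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows of P must sum to 1")
        if pi.min() < -1e-14 or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector")
        if np.max(np.abs(pi @ P - pi)) > 1e-10:
            raise ValueError("pi is not invariant under P")
        self.state_space = state_space
        self.transition = P
        self.stationary = pi
        self.potential = potential
        self.spectral = spectral

    @property
    def flux(self) -> np.ndarray:
        """Stationary probability flux J[l, l'] = pi_l P_{l,l'}."""
        return self.stationary[:, None] * self.transition

    def __repr__(self) -> str:
        ss = self.state_space
        return (
            f"MarkovChain(N={ss.n_neurons}, D={ss.memory}, "
            f"{ss.n_states} states{', memoryless' if ss.memoryless else ''})"
        )


def build_transfer(H: Potential) -> TransferMatrix:
    """Transfer matrix of a finite-range potential."""
    if not np.isfinite(H.coefficients).all():
        raise ValueError("potential coefficients must be finite")
    n = H.n_neurons
    if H.range == 1:
        space = StateSpace(n, 1, memoryless=True)
        states = np.arange(space.n_states, dtype=np.int64)
        hvals = H.eval_on_indices(states)
        mat = np.tile(np.exp(hvals), (space.n_states, 1))
        return TransferMatrix(space, mat, H)
    space = StateSpace(n, H.range - 1)
    if n * H.range > 20:
        warnings.warn(
            f"N*R = {n * H.range} > 20: the transfer-matrix construction "
            "becomes unreliable/expensive at this scale",
            stacklevel=2,
        )
    rows, cols, wins = space.transition_blocks()
    mat = np.zeros((space.n_states, space.n_states))
    mat[rows, cols] = np.exp(H.eval_on_indices(wins))
    return TransferMatrix(space, mat, H)


def _power_perron(mat: np.ndarray, tol: float, max_iter: int = 100_000):
    n = mat.shape[0]
    v = np.full(n, 1.0 / n)
    rho = 1.0
    for _ in range(max_iter):
        w = mat @ v
        rho_new = np.linalg.norm(w)
        w /= rho_new
        if np.max(np.abs(w - v)) < tol:
            return rho_new, w
        v = w
        rho = rho_new
    raise RuntimeError(f"power iteration did not converge (last rho={rho})")


def perron(T: TransferMatrix, tol: float = 1e-12) -> SpectralData:
    """Perron eigen-triple of a (primitive) transfer matrix.

    Dense eigensolve up to 1024 states, power iteration beyond.
    """
    mat = T.matrix
    n = mat.shape[0]
    if n <= _DENSE_LIMIT:
        vals, vecs = scipy.linalg.eig(mat)
        i = int(np.argmax(vals.real))
        rho = float(vals[i].real)
        right = vecs[:, i].real
        vals_l, vecs_l = scipy.linalg.eig(mat.T)
        j = int(np.argmax(vals_l.real))
        left = vecs_l[:, j].real
        right = np.abs(right)
        left = np.abs(left)
    else:
        rho, right = _power_perron(mat, tol)
        _, left = _power_perron(mat.T, tol)
    if rho <= 0 or right.min() <= 0 or left.min() <= 0:
        raise RuntimeError("Perron data not strictly positive; matrix may not be primitive")
    right = right / right.max()
    left = left / (left @ right)
    res_r = np.max(np.abs(mat @ right - rho * right))
    res_l = np.max(np.abs(left @ mat - rho * left))
    scale = max(rho, 1.0)
    if max(res_r, res_l) > 1e4 * tol * scale:
        raise RuntimeError(
            f"Perron residual too large: {max(res_r, res_l):.3e} (rho={rho:.6g})"
        )
    return SpectralData(rho=rho, left=left, right=right)


def memc_from_spectral(T: TransferMatrix, S: SpectralData) -> MarkovChain:
    """Maximum-entropy chain (P, pi) from a transfer matrix and its Perron data."""
    P = T.matrix * S.right[None, :] / (S.rho * S.right[:, None])
    P /= P.sum(axis=1, keepdims=True)  # remove residual solver error
    pi = S.left * S.right
    pi = pi / pi.sum()
    return MarkovChain(T.state_space, P, pi, potential=T.potential, spectral=S)


def memc_from_potential(H: Potential, tol: float = 1e-12) -> MarkovChain:
    """Convenience: build transfer matrix, solve Perron, return the chain."""
    T = build_transfer(H)
    return memc_from_spectral(T, perron(T, tol))


def pressure(S: SpectralData) -> float:
    """Topological pressure (free energy) P[H] = ln rho."""
    return float(np.log(S.rho))


def memoryless_memc(H: Potential) -> MarkovChain:
    """Closed-form chain for a range-1 potential: i.i.d. Boltzmann-Gibbs draws.

    P(s'|s) = pi(s') = exp(H(s')) / Z with Z = sum_s' exp(H(s')); the transfer
    matrix has rho = Z and all other eigenvalues 0.
    """
    if H.range != 1:
        raise ValueError(
            f"memoryless constructor requires a range-1 potential, got range {H.range}"
        )
    space = StateSpace(H.n_neurons, 1, memoryless=True)
    states = np.arange(space.n_states, dtype=np.int64)
    w = np.exp(H.eval_on_indices(states))
    Z = w.sum()
    pi = w / Z
    P = np.tile(pi, (space.n_states, 1))
    right = w / w.max()
    left = np.full(space.n_states, 1.0)  # constant left eigenvector
    left = left / (left @ right)
    spec = SpectralData(rho=float(Z), left=left, right=right)
    return MarkovChain(space, P, pi, potential=H, spectral=spec)


def _observable_values(M: MarkovChain, f) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate f on every allowed transition window; returns (rows, cols, values)."""
    space = M.state_space
    r = int(getattr(f, "range"))
    if r > space.memory + 1:
        raise ValueError(
            f"observable range {r} exceeds D+1 = {space.memory + 1}"
        )
    rows, cols, wins = space.transition_blocks()
    if hasattr(f, "eval_on_indices"):
        vals = f.eval_on_indices(wins)
    elif hasattr(f, "bitmask"):
        mask = f.bitmask(space.n_neurons)
        vals = ((wins & mask) == mask).astype(float)
    else:
        width = space.memory + 1
        vals = np.array(
            [f(block_from_index(int(w), space.n_neurons, width).values[:, :r])
             for w in wins]
        )
    return rows, cols, vals


def expectation(M: MarkovChain, f) -> float:
    """Stationary expectation of an observable of range <= D+1."""
    rows, cols, vals = _observable_values(M, f)
    J = M.flux
    return float(np.sum(J[rows, cols] * vals))


def stationary_distribution(P: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary vector of a stochastic matrix via a dense eigensolve."""
    P = np.asarray(P, dtype=float)
    vals, vecs = scipy.linalg.eig(P.T)
    i = int(np.argmax(vals.real))
    pi = np.abs(vecs[:, i].real)
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ P - pi)) > max(tol, 1e-10):
        raise RuntimeError("stationary solve did not converge")
    return pi


def _states_to_train(space: StateSpace, first_state: int,
                     new_patterns: np.ndarray) -> SpikeTrain:
    n = space.n_neurons
    d = 1 if space.memoryless else space.memory
    first = block_from_index(first_state, n, d).values
    if len(new_patterns):
        pats = np.asarray(new_patterns, dtype=np.int64)
        bits = ((pats[:, None] >> np.arange(n)) & 1).astype(np.uint8).T
        values = np.concatenate([first, bits], axis=1)
    else:
        values = first
    return SpikeTrain(values)


def sample_chain(P: np.ndarray, pi: np.ndarray, n_steps: int, seed) -> np.ndarray:
    """Sample a state-index path of length n_steps+1 (initial state from pi)."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    path = np.empty(n_steps + 1, dtype=np.int64)
    path[0] = rng.choice(len(pi), p=pi)
    u = rng.random(n_steps)
    for t in range(n_steps):
        path[t + 1] = np.searchsorted(cum[path[t]], u[t], side="right")
    return path


def sample(M: MarkovChain, n_bins: int, seed) -> SpikeTrain:
    """Sample a spike train of n_bins patterns from the stationary chain."""
    space = M.state_space
    d = 1 if space.memoryless else space.memory
    if n_bins < d:
        raise ValueError(f"n_bins must be >= memory D = {d}")
    n_steps = n_bins - d
    path = sample_chain(M.transition, M.stationary, n_steps, seed)
    if space.memoryless:
        new_patterns = path[1:]
    else:
        shift = space.n_neurons * (space.memory - 1)
        new_patterns = path[1:] >> shift
    return _states_to_train(space, int(path[0]), new_patterns)
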