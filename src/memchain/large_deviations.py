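"""Large deviations of additive observables and the Gallavotti-Cohen symmetry.

For an additive observable f of an ergodic finite chain, the scaled cumulant
generating function (SCGF) is the log spectral radius of the tilted matrix

    lambda_f(k) = ln rho(P e^{k f}),

and the rate function governing P(A_n(f) ~ s) ~ exp(-n I_f(s)) is its
Legendre transform I_f(s) = sup_k [k s - lambda_f(k)].

The entropy-production observable W_n is the log-ratio of a trajectory's
probability to that of its time reversal; W_n / n -> IEP almost surely.  Its
tilting matrix uses F = ln(J / J^T) with J = diag(pi) P, and its SCGF obeys
the Gallavotti-Cohen symmetry lambda_W(k) = lambda_W(-1-k), equivalently
I_W(s) = I_W(-s) - s: positive entropy-production fluctuations are
exponentially more probable than negative ones of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .entropy_production import reversed_state_map
from .spike_data import SpikeTrain, sliding_block_indices
from .transfer import MarkovChain, _observable_values

__all__ = [
    "SCGFCurve",
    "RateFunction",
    "tilt",
    "scgf",
    "scgf_value",
    "scgf_derivative_at_zero",
    "legendre",
    "w_matrix",
    "scgf_W",
    "gc_symmetry_residual",
    "rate_W",
    "empirical_W",
    "default_k_grid",
]

_FLUX_FLOOR = 1e-300


def default_k_grid() -> np.ndarray:
    """Default tilt grid: [-2, 1] with 301 points, symmetric about k = -1/2."""
    return np.linspace(-2.0, 1.0, 301)


@dataclass(frozen=True)
class SCGFCurve:
    """lambda_f(k) sampled on an ordered k-grid."""

    k: np.ndarray
    values: np.ndarray
    observable: str = ""

    def __post_init__(self):
        if self.k.shape != self.values.shape:
            raise ValueError("k grid and values must have equal shape")

    def derivative(self) -> np.ndarray:
        return np.gradient(self.values, self.k)


@dataclass(frozen=True)
class RateFunction:
    """I_f(s) on an s-grid; boundary[i] flags points where the Legendre
    maximizer hit an edge of the k-grid (value unreliable there)."""

    s: np.ndarray
    values: np.ndarray
    boundary: np.ndarray = field(default=None)


def _tilted_radius(mat: np.ndarray) -> float:
    vals = scipy.linalg.eigvals(mat)
    return float(np.max(vals.real))


def _transition_values(M: MarkovChain, f) -> np.ndarray:
    """Dense matrix of f evaluated on each allowed transition window."""
    rows, cols, vals = _observable_values(M, f)
    n = M.state_space.n_states
    out = np.zeros((n, n))
    # overlapping (row, col) pairs cannot occur: the new pattern determines col
    out[rows, cols] = vals
    return out


def tilt(M: MarkovChain, f, k: float) -> np.ndarray:
    """Tilted matrix P * exp(k f) with f evaluated per transition window."""
    fv = _transition_values(M, f)
    return M.transition * np.exp(k * fv)


def scgf_value(M: MarkovChain, f, k: float) -> float:
    return float(np.log(_tilted_radius(tilt(M, f, k))))


def scgf(M: MarkovChain, f, k_grid=None, observable: str = "") -> SCGFCurve:
    """SCGF of an additive observable on a k-grid."""
    k_grid = default_k_grid() if k_grid is None else np.asarray(k_grid, float)
    fv = _transition_values(M, f)
    values = np.array(
        [np.log(_tilted_radius(M.transition * np.exp(k * fv))) for k in k_grid]
    )
    return SCGFCurve(k=k_grid, values=values, observable=observable)


def scgf_derivative_at_zero(M: MarkovChain, f, h: float = 1e-5) -> float:
    """Central-difference lambda'(0); equals the stationary mean of f."""
    return (scgf_value(M, f, h) - scgf_value(M, f, -h)) / (2 * h)


def legendre(curve: SCGFCurve, s_grid) -> RateFunction:
    """Legendre transform I(s) = max_k [k s - lambda(k)] by grid maximization."""
    s_grid = np.asarray(s_grid, dtype=float)
    obj = s_grid[:, None] * curve.k[None, :] - curve.values[None, :]
    arg = np.argmax(obj, axis=1)
    vals = obj[np.arange(s_grid.size), arg]
    boundary = (arg == 0) | (arg == curve.k.size - 1)
    return RateFunction(s=s_grid, values=vals, boundary=boundary)


def w_matrix(M: MarkovChain) -> np.ndarray:
    """Per-transition entropy production F = ln(J / J^T), J = diag(pi) P.

    Antisymmetric where defined; the flux-weighted mean sum J * F equals the
    IEP.  Raises if some transition has no reverse (one-way pair), which can
    only happen for memory D >= 2.
    """
    J = M.flux
    fwd = J > _FLUX_FLOOR
    one_way = fwd & ~(J.T > _FLUX_FLOOR)
    if one_way.any():
        l, lp = np.argwhere(one_way)[0]
        raise ValueError(
            f"one-way transition {l} -> {lp}: W observable diverges "
            "(reverse path has zero probability)"
        )
    F = np.zeros_like(J)
    both = fwd & (J.T > _FLUX_FLOOR)
    F[both] = np.log(J[both] / J.T[both])
    return F


def scgf_W(M: MarkovChain, k_grid=None) -> SCGFCurve:
    """SCGF of the entropy-production observable W_n."""
    k_grid = default_k_grid() if k_grid is None else np.asarray(k_grid, float)
    F = w_matrix(M)
    values = np.array(
        [np.log(_tilted_radius(M.transition * np.exp(k * F))) for k in k_grid]
    )
    return SCGFCurve(k=k_grid, values=values, observable="W")


def gc_symmetry_residual(curve: SCGFCurve) -> float:
    """max_k |lambda(k) - lambda(-1-k)| over grid points whose mirror -1-k is
    also on the grid (exact for grids symmetric about -1/2)."""
    k = curve.k
    mirrored = -1.0 - k
    # match mirrored points to nearest grid points
    idx = np.argmin(np.abs(k[None, :] - mirrored[:, None]), axis=1)
    ok = np.abs(k[idx] - mirrored) < 1e-9
    if not ok.any():
        raise ValueError("k-grid has no points symmetric about -1/2")
    return float(np.max(np.abs(curve.values[ok] - curve.values[idx[ok]])))


def rate_W(M: MarkovChain, s_grid, k_grid=None) -> tuple[RateFunction, float]:
    """Rate function of W_n / n plus the fluctuation-relation residual.

    Returns (rate, residual) with residual = max |I(s) - (I(-s) - s)| over
    interior grid points whose mirror -s is also on the grid.
    """
    curve = scgf_W(M, k_grid)
    s_grid = np.asarray(s_grid, dtype=float)
    rate = legendre(curve, s_grid)
    idx = np.argmin(np.abs(s_grid[None, :] + s_grid[:, None]), axis=1)
    ok = (np.abs(s_grid[idx] + s_grid) < 1e-9) & ~rate.boundary & ~rate.boundary[idx]
    if ok.any():
        residual = float(
            np.max(np.abs(rate.values[ok] - (rate.values[idx[ok]] - s_grid[ok])))
        )
    else:
        residual = float("nan")
    return rate, residual


def empirical_W(train: SpikeTrain, M: MarkovChain) -> np.ndarray:
    """Per-prefix series W_n / n of the entropy-production observable.

    W_n = ln P(path of first n patterns) - ln P(time-reversed path), both
    under the stationary chain measure.  Entry i is W_{n} / n for the prefix
    of n = D + i + 1 patterns (i.e. after i transitions ... the first usable
    prefix holds one transition).
    """
    space = M.state_space
    n = space.n_neurons
    d = 1 if space.memoryless else space.memory
    if train.n_neurons != n:
        raise ValueError("train population size does not match the chain")
    states = sliding_block_indices(train, d)
    rev = reversed_state_map(M)
    P = M.transition
    pi = M.stationary
    logpi = np.where(pi > 0, np.log(np.maximum(pi, _FLUX_FLOOR)), -np.inf)
    src = states[:-1]
    dst = states[1:]
    p_fwd = P[src, dst]
    p_bwd = P[rev[dst], rev[src]]
    if (p_fwd <= 0).any() or (p_bwd <= 0).any():
        raise ValueError("zero-probability transition on the (reversed) path")
    A = np.cumsum(np.log(p_fwd))
    B = np.cumsum(np.log(p_bwd))
    m = src.size  # number of transitions
    steps = np.arange(1, m + 1)
    W = logpi[states[0]] + A - (logpi[rev[dst]] + B)
    lengths = steps + d  # patterns in each prefix
    return W / lengths


def empirical_W_final(train: SpikeTrain, M: MarkovChain) -> float:
    return float(empirical_W(train, M)[-1])
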