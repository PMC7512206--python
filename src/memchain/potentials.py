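"""Monomials and finite-range potentials.

A monomial is a product of spike indicators sigma_k^n over a set of
(neuron, time-offset) pairs; it takes values in {0, 1}.  A potential of range
R is a finite linear combination H = sum_l h_l m_l of monomials whose offsets
all lie in 0..R-1.  The potential plays the role of an energy: its
coefficients are the Lagrange multipliers of the maximum-entropy problem and
it parameterizes the transfer matrix.

Monomials are labelled by the same bit scheme as spike blocks: the pair
(k, n) occupies bit n*N + k - 1, so a monomial's integer index doubles as a
bitmask and evaluation on a block index reduces to ``(idx & mask) == mask``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Monomial",
    "Potential",
    "monomial_index",
    "monomial_from_index",
    "build_pairwise_1step",
]


@dataclass(frozen=True)
class Monomial:
    """Product of spike indicators over unique (neuron k>=1, offset n>=0) pairs.

    The empty monomial is the constant observable 1.
    """

    pairs: frozenset

    def __init__(self, pairs):
        pairs = frozenset((int(k), int(n)) for k, n in pairs)
        for k, n in pairs:
            if k < 1:
                raise ValueError(f"neuron index must be >= 1, got {k}")
            if n < 0:
                raise ValueError(f"time offset must be >= 0, got {n}")
        object.__setattr__(self, "pairs", pairs)

    @property
    def range(self) -> int:
        """Number of consecutive time bins the monomial reads (>= 1)."""
        if not self.pairs:
            return 1
        return max(n for _, n in self.pairs) + 1

    @property
    def max_neuron(self) -> int:
        return max((k for k, _ in self.pairs), default=1)

    def bitmask(self, n_neurons: int) -> int:
        return sum(1 << (n * n_neurons + k - 1) for k, n in self.pairs)

    def __call__(self, block_values) -> int:
        arr = np.asarray(block_values)
        for k, n in self.pairs:
            if n >= arr.shape[1]:
                raise ValueError(
                    f"offset {n} exceeds block length {arr.shape[1]}"
                )
            if arr[k - 1, n] == 0:
                return 0
        return 1

    def label(self) -> str:
        if not self.pairs:
            return "1"
        return "*".join(
            f"s[{k}]^{n}" for k, n in sorted(self.pairs, key=lambda p: (p[1], p[0]))
        )


def monomial_index(m: Monomial, n_neurons: int, rng: int) -> int:
    """Integer label of a monomial under the block-index bit scheme."""
    if m.pairs and m.max_neuron > n_neurons:
        raise ValueError("monomial references a neuron beyond n_neurons")
    if m.range > rng:
        raise ValueError("monomial range exceeds declared range")
    return m.bitmask(n_neurons)

def monomial_from_index(index: int, n_neurons: int, rng: int) -> Monomial:
    if not 0 <= index < (1 << (n_neurons * rng)):
        raise ValueError(f"index {index} out of range for N={n_neurons}, R={rng}")
    pairs = [
        (b % n_neurons + 1, b // n_neurons)
        for b in range(n_neurons * rng)
        if (index >> b) & 1
    ]
    return Monomial(pairs)


class Potential:
    """Finite-range potential H = sum_l h_l m_l.

    Parameters
    ----------
    n_neurons : int
        Population size N.
    rng : int
        Range R >= 1 (number of consecutive bins the potential reads).
    terms : sequence of (coefficient, Monomial)
        All coefficients must be finite; monomials must be distinct and fit
        inside (N, R).
    """

    def __init__(self, n_neurons: int, rng: int, terms) -> None:
        if n_neurons < 1 or rng < 1:
            raise ValueError("n_neurons and range must be >= 1")
        self.n_neurons = int(n_neurons)
        self.range = int(rng)
        self.terms = [(float(h), m) for h, m in terms]
        seen = set()
        for h, m in self.terms:
            if not math.isfinite(h):
                raise ValueError("potential coefficients must be finite")
            if m.range > self.range:
                raise ValueError(
                    f"monomial {m.label()} exceeds potential range {self.range}"
                )
            if m.pairs and m.max_neuron > self.n_neurons:
                raise ValueError(
                    f"monomial {m.label()} references neuron beyond N={self.n_neurons}"
                )
            if m.pairs in seen:
                raise ValueError(f"duplicate monomial {m.label()}")
            seen.add(m.pairs)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([h for h, _ in self.terms])

    @property
    def monomials(self) -> list:
        return [m for _, m in self.terms]

    def __call__(self, block_values) -> float:
        return float(sum(h * m(block_values) for h, m in self.terms))

    def eval_on_indices(self, indices: np.ndarray) -> np.ndarray:
        """Vectorized evaluation on an array of block indices."""
        idx = np.asarray(indices, dtype=np.int64)
        out = np.zeros(idx.shape, dtype=float)
        for h, m in self.terms:
            mask = m.bitmask(self.n_neurons)
            out += h * ((idx & mask) == mask)
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "range": self.range,
            "terms": [
                {"h": h, "pairs": sorted([list(p) for p in m.pairs])}
                for h, m in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Potential":
        terms = [(t["h"], Monomial(tuple(map(tuple, t["pairs"])))) for t in d["terms"]]
        return cls(d["n_neurons"], d["range"], terms)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Potential":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:
        return (
            f"Potential(N={self.n_neurons}, R={self.range}, "
            f"{len(self.terms)} terms)"
        )


def build_pairwise_1step(h, J, gamma) -> Potential:
    """One-time-step extension of the pairwise (Ising-type) model.

    H = sum_i h_i s_i^0 + (1/2) sum_{i,j} J_ij s_i^0 s_j^0
        + sum_{i,j} gamma_ij s_i^0 s_j^1.

    The field and synchronous-coupling sums act on the time-0 pattern; gamma
    couples neuron i at time 0 to neuron j at time 1.  The double J sum is
    taken literally, so the diagonal contributes J_ii/2 to the field on s_i
    (since s_i^2 = s_i) and off-diagonal pairs pick up (J_ij + J_ji)/2.
    Returns a range-2 potential.
    """
    h = np.asarray(h, dtype=float)
    J = np.asarray(J, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    n = h.size
    if J.shape != (n, n) or gamma.shape != (n, n):
        raise ValueError("J and gamma must be N x N with N = len(h)")
    if not (np.isfinite(h).all() and np.isfinite(J).all() and np.isfinite(gamma).all()):
        raise ValueError("all parameters must be finite")

    coeffs: dict[frozenset, float] = {}

    def add(pairs, value):
        if value == 0.0:
            return
        key = frozenset(pairs)
        coeffs[key] = coeffs.get(key, 0.0) + value

    for i in range(n):
        add([(i + 1, 0)], h[i] + 0.5 * J[i, i])
    for i in range(n):
        for j in range(i + 1, n):
            add([(i + 1, 0), (j + 1, 0)], 0.5 * (J[i, j] + J[j, i]))
    for i in range(n):
        for j in range(n):
            add([(i + 1, 0), (j + 1, 1)], gamma[i, j])

    terms = [(v, Monomial(tuple(k))) for k, v in coeffs.items() if v != 0.0]
    return Potential(n, 2, terms)
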