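"""Entropy rate, information entropy production, and detailed balance.

For a stationary ergodic chain (P, pi) the Kolmogorov-Sinai entropy is

    S = -sum_{l,l'} pi_l P_{l,l'} ln P_{l,l'}     (nats per time step),

and the information entropy production (IEP)

    IEP = (1/2) sum_{l,l'} (J_{l',l} - J_{l,l'}) ln(J_{l',l} / J_{l,l'}),

with J = diag(pi) P the stationary flux.  IEP >= 0, and IEP = 0 iff the chain
satisfies detailed balance (J symmetric), i.e. iff it is time reversible.  A
positive IEP at stationarity is the signature of a non-equilibrium steady
state: entropy flow exactly balances entropy production while the state
distribution stays fixed.

Memory caveat.  For block chains with memory D >= 2 the transition graph is a
de Bruijn overlap graph whose edges are generically one-way, so the pairwise
formula above diverges structurally.  The *process* mode instead compares
each transition's flux with the flux of the time-reversed window (patterns in
reverse order), which is always an allowed transition; for D = 1 the two
modes coincide exactly.  The process-mode value is the entropy production
rate of the block process as a trajectory measure, which is the physically
meaningful notion for D >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_data import block_from_index, block_index
from .transfer import MarkovChain, SpectralData, TransferMatrix

__all__ = [
    "EntropyReport",
    "DetailedBalanceReport",
    "EntropyChange",
    "kse",
    "iep_stationary",
    "iep_spectral",
    "detailed_balance_residuals",
    "entropy_change_decomposition",
    "entropy_report",
    "reversed_state_map",
]

_FLUX_FLOOR = 1e-300
_DB_TOL = 1e-10


def kse(M: MarkovChain) -> float:
    """Kolmogorov-Sinai entropy of the stationary chain, in nats/step."""
    P = M.transition
    J = M.flux
    mask = P > 0
    return float(-np.sum(J[mask] * np.log(P[mask])))


def reversed_state_map(M: MarkovChain) -> np.ndarray:
    """Index map l -> index of the time-reversed state block."""
    space = M.state_space
    if space.memory == 1:
        return np.arange(space.n_states, dtype=np.int64)
    return np.array(
        [
            block_index(
                block_from_index(l, space.n_neurons, space.memory).values[:, ::-1]
            )
            for l in range(space.n_states)
        ],
        dtype=np.int64,
    )


def iep_stationary(M: MarkovChain, mode: str = "auto") -> float:
    """Information entropy production of the stationary chain, nats/step.

    Parameters
    ----------
    mode : {"auto", "naive", "process"}
        "naive" applies the pairwise flux formula literally and returns +inf
        if any one-way pair carries positive flux.  "process" compares each
        flux against the flux of the time-reversed window (required for
        memory D >= 2, identical to naive for D = 1).  "auto" picks naive
        for D = 1 and process otherwise.
    """
    space = M.state_space
    if mode == "auto":
        mode = "naive" if space.memory == 1 else "process"
    J = M.flux
    if mode == "naive":
        fwd = J > _FLUX_FLOOR
        one_way = fwd & ~(J.T > _FLUX_FLOOR)
        if one_way.any():
            return float("inf")
        both = fwd & (J.T > _FLUX_FLOOR)
        a = J[both]
        b = J.T[both]
        return float(0.5 * np.sum((a - b) * np.log(a / b)))
    if mode == "process":
        rev = reversed_state_map(M)
        rows, cols, _ = space.transition_blocks()
        a = J[rows, cols]
        b = J[rev[cols], rev[rows]]  # flux of the time-reversed window
        keep = a > _FLUX_FLOOR
        a, b = a[keep], b[keep]
        if (b <= _FLUX_FLOOR).any():
            return float("inf")
        return float(np.sum(a * np.log(a / b)))
    raise ValueError(f"unknown mode {mode!r}")


def iep_spectral(T: TransferMatrix, S: SpectralData) -> float:
    """IEP directly from the transfer matrix and its Perron eigendata.

    IEP = sum_{l,l'} (L_l / <L,R>) L_H(l,l') (R_l' / rho)
          * ln[L_l R_l' L_H(l,l') / (L_l' R_l L_H(l',l))].

    Requires memory D = 1 (every reverse entry positive); identical to the
    pairwise stationary formula on the derived chain.
    """
    if T.state_space.memory != 1:
        raise ValueError("spectral IEP formula requires memory D = 1")
    mat = T.matrix
    L, R, rho = S.left, S.right, S.rho
    inner = S.inner
    w = (L[:, None] / inner) * mat * (R[None, :] / rho)
    num = L[:, None] * R[None, :] * mat
    den = (L[None, :] * R[:, None] * mat.T)
    mask = (mat > 0) & (mat.T > 0) & (w > _FLUX_FLOOR)
    if ((mat > 0) & ~(mat.T > 0)).any():
        return float("inf")
    return float(np.sum(w[mask] * np.log(num[mask] / den[mask])))


@dataclass(frozen=True)
class DetailedBalanceReport:
    """Pairwise flux residuals pi_l P_{l,l'} - pi_l' P_{l',l}."""

    residuals: np.ndarray
    max_residual: float
    spectral_max_residual: float | None = None

    @property
    def balanced(self) -> bool:
        return self.max_residual < _DB_TOL


def detailed_balance_residuals(M: MarkovChain,
                               spectral: tuple[TransferMatrix, SpectralData] | None = None,
                               ) -> DetailedBalanceReport:
    """Detailed-balance diagnostics of a stationary chain.

    If (transfer, spectral) data are supplied, additionally checks the
    spectral form L_H(l,l') / L_H(l',l) = R_l L_l' / (R_l' L_l) on pairs with
    both directions allowed.
    """
    J = M.flux
    res = J - J.T
    spec_res = None
    if spectral is not None:
        T, S = spectral
        mat = T.matrix
        both = (mat > 0) & (mat.T > 0)
        lhs = mat * S.right[:, None] * S.left[None, :]
        rhs = mat.T * S.right[None, :] * S.left[:, None]
        spec_res = float(np.max(np.abs(lhs[both] - rhs[both]), initial=0.0))
    return DetailedBalanceReport(
        residuals=res,
        max_residual=float(np.max(np.abs(res))),
        spectral_max_residual=spec_res,
    )


@dataclass(frozen=True)
class EntropyChange:
    """One-step entropy change of a (possibly non-stationary) distribution."""

    delta: float
    flow: float
    production: float
    nu_next: np.ndarray


def entropy_change_decomposition(P: np.ndarray, nu: np.ndarray) -> EntropyChange:
    """Split S_{n+1} - S_n into entropy flow plus entropy production.

    nu_{n+1} = nu_n P;  production is the nonnegative pairwise flux term

        (1/2) sum (nu_l' P_{l',l} - nu_l P_{l,l'}) ln[nu_l' P_{l',l} / (nu_l P_{l,l'})]

    and flow = -sum nu_l' P_{l',l} ln[nu_{n+1}(l) P_{l',l} / (nu_l P_{l,l'})].
    The two add up to the directly computed entropy difference; at
    stationarity delta = 0 and flow = -production.
    """
    P = np.asarray(P, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if abs(nu.sum() - 1.0) > 1e-12 or nu.min() < -1e-14:
        raise ValueError("nu must be a probability vector")
    nu_next = nu @ P
    def _ent(v):
        m = v > 0
        return float(-np.sum(v[m] * np.log(v[m])))
    delta = _ent(nu_next) - _ent(nu)
    # flux a[l',l] = nu(l') P_{l',l}; reverse b[l',l] = nu(l) P_{l,l'}
    a = nu[:, None] * P
    b = a.T
    mask = (a > _FLUX_FLOOR) & (b > _FLUX_FLOOR)
    production = float(0.5 * np.sum((a[mask] - b[mask]) * np.log(a[mask] / b[mask])))
    num = nu_next[None, :] * P  # nu_{n+1}(target) P_{l',l}
    fmask = (a > _FLUX_FLOOR) & (num > _FLUX_FLOOR) & (b > _FLUX_FLOOR)
    flow = float(-np.sum(a[fmask] * np.log(num[fmask] / b[fmask])))
    return EntropyChange(delta=delta, flow=flow, production=production, nu_next=nu_next)


@dataclass(frozen=True)
class EntropyReport:
    """Summary of the entropy structure of a stationary chain."""

    kse: float
    iep: float
    max_db_residual: float
    mode: str


def entropy_report(M: MarkovChain, mode: str = "auto") -> EntropyReport:
    space = M.state_space
    if mode == "auto":
        mode = "naive" if space.memory == 1 else "process"
    return EntropyReport(
        kse=kse(M),
        iep=iep_stationary(M, mode=mode),
        max_db_residual=detailed_balance_residuals(M).max_residual,
        mode=mode,
    )
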