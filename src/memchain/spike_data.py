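"""Binary spike rasters and their block algebra.

A spike train is an N x T binary matrix: row k-1 holds neuron k (neurons are
1-based throughout, matching the usual electrophysiology convention), column n
holds time bin n (0-based).  A *block* is an N x L window of a train.  Every
block maps bijectively to an integer index

    ell = sum_{k=1..N} sum_{n=0..L-1} 2^(n*N + k - 1) * sigma_k^n,

i.e. bit position n*N + (k-1) carries the state of neuron k at offset n.  This
index is the single source of truth for state ordering everywhere in the
package: transfer matrices, Markov chains and monomial labels all enumerate
states in increasing block index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "SpikeBlock",
    "block_index",
    "block_from_index",
    "sliding_blocks",
    "sliding_block_indices",
    "empirical_average",
    "reverse_time",
    "shuffle_time",
    "read_raster",
    "write_raster",
    "RasterFormatError",
]


class RasterFormatError(ValueError):
    """Raised when a raster file does not conform to the expected format."""


def _validate_binary(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"raster must be 2-D (neurons x bins), got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("raster must have at least one neuron and one time bin")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("raster entries must be exactly 0 or 1")
    return arr.astype(np.uint8)


class SpikeTrain:
    """An N-neuron, T-bin binary raster.

    Parameters
    ----------
    values : array_like of shape (n_neurons, n_bins)
        Binary matrix; entry (k-1, n) is 1 iff neuron k spikes in bin n.
    """

    def __init__(self, values) -> None:
        self.values = _validate_binary(values)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other) -> bool:
        return isinstance(other, SpikeTrain) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:
        return f"SpikeTrain(n_neurons={self.n_neurons}, n_bins={self.n_bins})"


@dataclass(frozen=True)
class SpikeBlock:
    """An N x L window of a spike train together with its integer index."""

    values: np.ndarray
    index: int = field(default=-1)

    def __post_init__(self):
        arr = _validate_binary(self.values)
        object.__setattr__(self, "values", arr)
        idx = block_index(arr)
        if self.index == -1:
            object.__setattr__(self, "index", idx)
        elif self.index != idx:
            raise ValueError(f"stored index {self.index} does not match values (index {idx})")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


def block_index(values) -> int:
    """Integer index of a binary N x L block (bit n*N + k - 1 per neuron/offset)."""
    arr = np.asarray(values, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr[:, None]
    bits = arr.ravel(order="F")  # column-major: position (k-1) + n*N
    weights = 1 << np.arange(bits.size, dtype=object)
    return int(np.dot(bits.astype(object), weights))


def block_from_index(index: int, n_neurons: int, length: int) -> SpikeBlock:
    """Inverse of :func:`block_index` for given dimensions."""
    n_bits = n_neurons * length
    if not 0 <= index < (1 << n_bits):
        raise ValueError(f"index {index} out of range for a {n_neurons}x{length} block")
    bits = (index >> np.arange(n_bits)) & 1
    values = np.asarray(bits, dtype=np.uint8).reshape((n_neurons, length), order="F")
    return SpikeBlock(values=values, index=index)


def sliding_blocks(train: SpikeTrain, length: int) -> list[SpikeBlock]:
    """All T-L+1 contiguous windows of a train, in time order."""
    if length > train.n_bins:
        raise ValueError(
            f"window length {length} exceeds train length {train.n_bins}"
        )
    return [
        SpikeBlock(values=train.values[:, i : i + length])
        for i in range(train.n_bins - length + 1)
    ]


def sliding_block_indices(train: SpikeTrain, length: int) -> np.ndarray:
    """Block indices of all sliding windows, vectorized (requires N*length <= 62)."""
    if length > train.n_bins:
        raise ValueError(f"window length {length} exceeds train length {train.n_bins}")
    n = train.n_neurons
    if n * length > 62:
        return np.array([b.index for b in sliding_blocks(train, length)], dtype=object)
    col = (train.values.astype(np.int64).T * (1 << np.arange(n, dtype=np.int64))).sum(axis=1)
    # col[t] = index of the single-pattern block at time t; window index is
    # sum_m col[t+m] * 2^(m*N)
    out = np.zeros(train.n_bins - length + 1, dtype=np.int64)
    for m in range(length):
        out += col[m : m + out.size] << (m * n)
    return out


def empirical_average(train: SpikeTrain, f) -> float:
    """Time average of a finite-range observable over all sliding windows.

    ``f`` must expose a ``range`` attribute (number of consecutive bins it
    reads) and be callable on an N x range binary array.  Observables from
    :mod:`memchain.potentials` additionally expose a bitmask and are evaluated
    vectorized over all windows.
    """
    r = int(getattr(f, "range"))
    if r > train.n_bins:
        raise ValueError(f"observable range {r} exceeds train length {train.n_bins}")
    mask = getattr(f, "bitmask", None)
    terms = getattr(f, "terms", None)
    if terms is not None:  # a Potential: linear in its monomials
        return float(sum(h * empirical_average(train, m) for h, m in terms))
    if mask is not None and train.n_neurons * r <= 62:
        idx = sliding_block_indices(train, r)
        m = mask(train.n_neurons)
        return float(np.mean((idx & m) == m))
    windows = sliding_blocks(train, r)
    return float(np.mean([f(b.values) for b in windows]))


def reverse_time(train: SpikeTrain) -> SpikeTrain:
    """The train with its time axis inverted (an involution)."""
    return SpikeTrain(train.values[:, ::-1])


def shuffle_time(train: SpikeTrain, seed) -> SpikeTrain:
    """The train with its time bins randomly permuted (seeded)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train.n_bins)
    return SpikeTrain(train.values[:, perm])


def write_raster(train: SpikeTrain, path) -> None:
    """Write a train as plain text: one row per neuron, 0/1 tokens."""
    with open(path, "w") as fh:
        fh.write(f"# neurons={train.n_neurons} bins={train.n_bins}\n")
        for row in train.values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_raster(path) -> SpikeTrain:
    """Read a plain-text raster; '#' lines are comments.

    Raises
    ------
    RasterFormatError
        On non-binary tokens or ragged rows, naming the offending line.
    """
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            vals = []
            for tok in tokens:
                if tok not in ("0", "1"):
                    raise RasterFormatError(
                        f"{path}:{lineno}: non-binary token {tok!r}"
                    )
                vals.append(int(tok))
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise RasterFormatError(
                    f"{path}:{lineno}: expected {width} columns, got {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise RasterFormatError(f"{path}: no data rows")
    return SpikeTrain(np.array(rows, dtype=np.uint8))
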