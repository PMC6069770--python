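"""k-mer bag-of-words vectorization of short reads.

A read of length L is mapped to a dense vector of length 4**k counting
every k-length window (stride 1, lexicographic k-mer order with
A<C<G<T); windows containing non-ACGT characters are skipped. Counts are
min-max scaled to [0,1] per vector before classification. The module
also provides the run-length sparsity diagnostics used to motivate small
convolution kernels: at k=5 on 250 bp reads the representation is sparse,
with non-zero entries mostly isolated between runs of zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequence_io import ShortRead

UNINDEXABLE = -1
"""Sentinel returned by :func:`kmer_index` for ambiguous k-mers."""

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True, slots=True)
class KmerVector:
    """Dense k-mer count/frequency vector of length 4**k."""

    k: int
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != 4**self.k:
            raise ValueError(f"expected length {4**self.k} for k={self.k}, got {len(self.values)}")
        if np.any(self.values < 0):
            raise ValueError("k-mer vector entries must be non-negative")
        if self.normalized and self.values.size and self.values.max() > 1.0 + 1e-12:
            raise ValueError("normalized vector has entries > 1")


@dataclass(frozen=True, slots=True)
class RunLengthStats:
    """Mean lengths of maximal zero and non-zero runs of a vector."""

    mean_zero_run: float
    mean_nonzero_run: float


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of *kmer* (A=0, C=1, G=2, T=3, leftmost most
    significant); :data:`UNINDEXABLE` if it contains an ambiguous base."""
    idx = 0
    for c in kmer:
        code = _CODE[ord(c)] if ord(c) < 128 else -1
        if code < 0:
            return UNINDEXABLE
        idx = idx * 4 + code
    return int(idx)


def _encode(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[a]


def count_kmers(seq: str, k: int, k_bounds: tuple[int, int] = (3, 9)) -> KmerVector:
    """Count all k-length windows of *seq* into a 4**k vector.

    Windows containing a non-ACGT character are skipped, so the entries
    sum to ``L - k + 1`` minus the number of skipped windows.
    """
    if not k_bounds[0] <= k <= k_bounds[1]:
        raise ValueError(f"k={k} outside supported range {k_bounds}")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    codes = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=4**k).astype(np.float64)
    return KmerVector(k=k, values=counts, normalized=False)


def minmax_normalize(v: KmerVector) -> KmerVector:
    """Scale entries to [0,1] by the vector's own min and max; a constant
    vector maps to all zeros. Idempotent."""
    x = v.values
    lo, hi = x.min(initial=np.inf), x.max(initial=-np.inf)
    if not np.isfinite(lo) or hi == lo:
        out = np.zeros_like(x, dtype=np.float64)
    else:
        out = (x - lo) / (hi - lo)
    return KmerVector(k=v.k, values=out, normalized=True)


def vectorize_sequences(seqs: Sequence[str], k: int, normalize: bool = True) -> np.ndarray:
    """Stack per-sequence k-mer vectors into a float matrix (rows = input order)."""
    n = len(seqs)
    X = np.empty((n, 4**k), dtype=np.float32)
    for i, s in enumerate(seqs):
        v = count_kmers(s, k)
        if normalize:
            v = minmax_normalize(v)
        X[i] = v.values
    return X


def vectorize_dataset(
    reads: Sequence[ShortRead], k: int, rank: str = "genus", normalize: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorize reads and extract integer-coded labels at *rank*.

    Returns ``(X, y, classes)`` where ``X`` is ``n_reads x 4**k``
    (min-max normalized per row by default), ``y[i]`` indexes into the
    sorted label dictionary ``classes``.
    """
    for r in reads:
        if len(r) < k:
            raise ValueError(f"read {r.id!r} is shorter ({len(r)}) than k={k}")
    X = vectorize_sequences([r.seq for r in reads], k, normalize=normalize)
    labels = [r.lineage.rank(rank) for r in reads]
    classes = sorted(set(labels))
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[l] for l in labels], dtype=np.int64)
    return X, y, classes


def run_length_stats(v: KmerVector | np.ndarray) -> RunLengthStats:
    """Mean lengths of maximal runs of zero / non-zero entries, scanned in
    index order; an absent run kind contributes mean 0."""
    x = v.values if isinstance(v, KmerVector) else np.asarray(v)
    if x.size == 0:
        return RunLengthStats(0.0, 0.0)
    nz = x != 0
    # run boundaries where the zero/non-zero state changes
    change = np.flatnonzero(np.diff(nz.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [x.size]))
    lengths = ends - starts
    kinds = nz[starts]
    zero_runs = lengths[~kinds]
    nonzero_runs = lengths[kinds]
    return RunLengthStats(
        mean_zero_run=float(zero_runs.mean()) if zero_runs.size else 0.0,
        mean_nonzero_run=float(nonzero_runs.mean()) if nonzero_runs.size else 0.0,
    )


def pooled_run_length_stats(vectors: Sequence[KmerVector | np.ndarray]) -> RunLengthStats:
    """Run-length statistics pooling all runs across a set of vectors."""
    zero_tot = zero_n = nonzero_tot = nonzero_n = 0.0
    for v in vectors:
        x = v.values if isinstance(v, KmerVector) else np.asarray(v)
        nz = x != 0
        change = np.flatnonzero(np.diff(nz.astype(np.int8)))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [x.size]))
        lengths = ends - starts
        kinds = nz[starts]
        zero_tot += lengths[~kinds].sum()
        zero_n += (~kinds).sum()
        nonzero_tot += lengths[kinds].sum()
        nonzero_n += kinds.sum()
    return RunLengthStats(
        mean_zero_run=zero_tot / zero_n if zero_n else 0.0,
        mean_nonzero_run=nonzero_tot / nonzero_n if nonzero_n else 0.0,
    )
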