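"""Reference matrix: the size-normalised sum of per-set Gram matrices.

For sequence set i with encoded matrix s_i (m_i x 4s), the position-space
Gram matrix is S_i = s_i' s_i (4s x 4s).  The reference matrix

    R = sum_j S_j / m_j

aggregates every set's base-composition structure and is the "everything
else" each set is contrasted against when computing indicator vectors.
Because R is a plain sum, it can be computed in independent batches and
merged, which is what makes very large datasets tractable.

The on-disk format is a small endian-pinned binary: magic ``BIVR``,
format version, alignment length, the contributing set names, then the
full square matrix as little-endian float64.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodedSet
from .exceptions import FormatError, InputError, MergeError

__all__ = [
    "ReferenceMatrix",
    "set_gram",
    "compute_reference",
    "merge_references",
    "write_reference",
    "read_reference",
]

_MAGIC = b"BIVR"
_VERSION = 1


@dataclass
class ReferenceMatrix:
    """R = sum_j S_j/m_j with the names of the sets that contributed."""

    R: np.ndarray  # (4s, 4s) float64, symmetric PSD
    s: int
    contributing_set_names: list[str]

    def __post_init__(self) -> None:
        if self.R.shape != (4 * self.s, 4 * self.s):
            raise InputError(
                f"reference matrix dimension {self.R.shape} does not match 4*s={4 * self.s}"
            )
        if len(set(self.contributing_set_names)) != len(self.contributing_set_names):
            raise InputError("duplicate contributing set names")
        if not self.contributing_set_names:
            raise InputError("a reference matrix needs at least one contributing set")

    @property
    def N(self) -> int:
        return len(self.contributing_set_names)


def set_gram(es: EncodedSet) -> tuple[np.ndarray, int]:
    """Return (S_i, m_i): the 4s x 4s Gram matrix of a set and its size.

    S_i = transpose(s_i) . s_i accumulates, for every pair of alignment
    positions, the co-occurrence weight of base pairs across the set's
    members; it is symmetric, positive semi-definite and invariant under
    row permutations of the encoded matrix.
    """
    S = es.matrix.T @ es.matrix
    return S, es.m


def compute_reference(sets: Sequence[EncodedSet], workers: int = 1) -> ReferenceMatrix:
    """Compute R = sum_j S_j/m_j over the given encoded sets.

    ``workers`` partitions the sets into batches whose partial sums are
    merged; the result is independent of the partitioning (summation
    reordering stays within 1e-10 relative).
    """
    if not sets:
        raise InputError("compute_reference needs at least one encoded set")
    names = [es.set_name for es in sets]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise InputError(f"duplicate set names: {sorted(dupes)}")
    s = sets[0].s
    for es in sets:
        if es.s != s:
            raise InputError(
                f"set {es.set_name!r} has alignment length {es.s}, expected {s}"
            )

    if workers <= 1 or len(sets) == 1:
        R = np.zeros((4 * s, 4 * s))
        for es in sets:
            S, m = set_gram(es)
            R += S / m
        return ReferenceMatrix(R=R, s=s, contributing_set_names=names)

    # Batch-and-merge path: identical contract, different summation grouping.
    batches = [list(sets[i::workers]) for i in range(workers)]
    partials = [compute_reference(b, workers=1) for b in batches if b]
    ref = partials[0]
    for part in partials[1:]:
        ref = merge_references(ref, part)
    # restore canonical input order of names
    ref = ReferenceMatrix(R=ref.R, s=s, contributing_set_names=names)
    return ref


def merge_references(a: ReferenceMatrix, b: ReferenceMatrix) -> ReferenceMatrix:
    """Merge two references computed on disjoint collections of sets."""
    if a.s != b.s:
        raise InputError(
            f"cannot merge references with different alignment lengths ({a.s} vs {b.s})"
        )
    shared = set(a.contributing_set_names) & set(b.contributing_set_names)
    if shared:
        raise MergeError(f"references share set names: {sorted(shared)}")
    return ReferenceMatrix(
        R=a.R + b.R,
        s=a.s,
        contributing_set_names=a.contributing_set_names + b.contributing_set_names,
    )


def write_reference(ref: ReferenceMatrix, path: str | Path) -> None:
    """Serialise a reference matrix (bit-exact round trip)."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", _VERSION))
        fh.write(struct.pack("<Q", ref.s))
        fh.write(struct.pack("<Q", ref.N))
        for name in ref.contributing_set_names:
            raw = name.encode("utf-8")
            fh.write(struct.pack("<I", len(raw)))
            fh.write(raw)
        fh.write(np.ascontiguousarray(ref.R, dtype="<f8").tobytes())


def _read_exact(fh, n: int, path, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FormatError(f"{path}: truncated file while reading {what}")
    return data


def read_reference(path: str | Path) -> ReferenceMatrix:
    """Read a reference matrix written by :func:`write_reference`."""
    with open(path, "rb") as fh:
        magic = _read_exact(fh, 4, path, "magic")
        if magic != _MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r}, not a reference file")
        (version,) = struct.unpack("<I", _read_exact(fh, 4, path, "version"))
        if version != _VERSION:
            raise FormatError(f"{path}: unsupported format version {version}")
        (s,) = struct.unpack("<Q", _read_exact(fh, 8, path, "alignment length"))
        (n,) = struct.unpack("<Q", _read_exact(fh, 8, path, "set count"))
        names = []
        for i in range(n):
            (ln,) = struct.unpack("<I", _read_exact(fh, 4, path, f"name {i} length"))
            names.append(_read_exact(fh, ln, path, f"name {i}").decode("utf-8"))
        dim = 4 * s
        raw = _read_exact(fh, dim * dim * 8, path, "matrix payload")
        R = np.frombuffer(raw, dtype="<f8").astype(np.float64).reshape(dim, dim)
    return ReferenceMatrix(R=R, s=s, contributing_set_names=names)
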