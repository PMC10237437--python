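"""Structure matrix: pairwise correlations between indicator vectors.

The structure matrix holds, for every pair of sequence sets, the
correlation of their indicator vectors; rendered as a heatmap ordered by
taxonomy it is the Klee diagram.  Two similarity measures are available:
Pearson correlation of the (mean-centred) vectors — the default — and the
raw cosine of the unit vectors.

Two computation modes share one contract.  ``oneshot`` normalises all
vectors and takes a single matrix product (fast, holds the whole matrix);
``streaming`` computes one row at a time, holding at most one row plus two
vectors (slow, constant memory).  ``auto`` switches from oneshot to
streaming above 5,000 vectors.  Both modes agree within 1e-12 elementwise.

The on-disk format is append-only: magic ``BIVS`` and a version, then one
record per vector k holding its name and its k+1 correlations with vectors
0..k (the lower triangle, diagonal included).  Adding new sets appends new
records and never rewrites existing bytes, so a large structure matrix can
grow without being recomputed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .exceptions import ConsistencyError, FormatError, InputError, MergeError
from .indicator import IndicatorVector

__all__ = [
    "StructureMatrix",
    "DEFAULT_SWITCH_THRESHOLD",
    "correlate",
    "compute_structure",
    "write_structure",
    "read_structure",
    "read_structure_names",
    "update_structure",
]

_MAGIC = b"BIVS"
_VERSION = 1

DEFAULT_SWITCH_THRESHOLD = 5000


@dataclass
class StructureMatrix:
    """Named symmetric matrix of pairwise indicator-vector correlations."""

    names: list[str]
    values: np.ndarray  # (n, n) symmetric, unit diagonal

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.values.shape != (n, n):
            raise InputError("structure matrix shape does not match its names")
        if len(set(self.names)) != n:
            raise InputError("duplicate set names in structure matrix")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def _normalise(v: np.ndarray, similarity: str, label: str = "vector") -> np.ndarray:
    if similarity == "pearson":
        v = v - v.mean()
    elif similarity != "cosine":
        raise InputError(f"unknown similarity {similarity!r}")
    norm = np.linalg.norm(v)
    if norm == 0.0 or (similarity == "pearson" and np.ptp(v) == 0.0):
        raise InputError(f"constant indicator vector: {label}")
    return v / norm


def correlate(u: np.ndarray, v: np.ndarray, similarity: str = "pearson") -> float:
    """Correlation between two indicator vectors.

    Pearson (default): both vectors are mean-centred, L2-normalised, and
    their inner product returned; ``cosine`` skips the centring.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise InputError("correlate needs two equal-length vectors of length >= 2")
    return float(_normalise(u, similarity) @ _normalise(v, similarity))


def _prepared_rows(
    vectors: Sequence[IndicatorVector], similarity: str
) -> tuple[list[str], np.ndarray]:
    names = [iv.set_name for iv in vectors]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise InputError(f"duplicate set names: {sorted(dupes)}")
    dim = len(vectors[0].vector)
    Z = np.empty((len(vectors), dim))
    for i, iv in enumerate(vectors):
        if len(iv.vector) != dim:
            raise InputError(f"set {iv.set_name!r}: inconsistent vector length")
        Z[i] = _normalise(np.asarray(iv.vector, float), similarity, iv.set_name)
    return names, Z


def _stream_rows(Z: np.ndarray) -> Iterator[np.ndarray]:
    """Yield lower-triangle rows one at a time (row k: correlations 0..k)."""
    for k in range(Z.shape[0]):
        row = np.empty(k + 1)
        for j in range(k + 1):
            row[j] = float(Z[k] @ Z[j])
        yield row


def compute_structure(
    vectors: Sequence[IndicatorVector],
    mode: str = "auto",
    switch_threshold: int = DEFAULT_SWITCH_THRESHOLD,
    similarity: str = "pearson",
) -> StructureMatrix:
    """Compute the structure matrix of a list of indicator vectors.

    ``mode`` is ``oneshot`` (single matrix product), ``streaming`` (row by
    row) or ``auto`` (oneshot up to ``switch_threshold`` vectors, streaming
    above).  The two modes agree within 1e-12 elementwise.
    """
    if len(vectors) < 2:
        raise InputError("a structure matrix needs at least two indicator vectors")
    if mode == "auto":
        mode = "oneshot" if len(vectors) <= switch_threshold else "streaming"
    names, Z = _prepared_rows(vectors, similarity)
    n = len(names)
    if mode == "oneshot":
        values = Z @ Z.T
    elif mode == "streaming":
        values = np.empty((n, n))
        for k, row in enumerate(_stream_rows(Z)):
            values[k, : k + 1] = row
            values[: k + 1, k] = row
    else:
        raise InputError(f"unknown mode {mode!r}")
    return StructureMatrix(names=names, values=values)


def _pack_record(name: str, row: np.ndarray) -> bytes:
    raw = name.encode("utf-8")
    return (
        struct.pack("<I", len(raw))
        + raw
        + np.ascontiguousarray(row, dtype="<f8").tobytes()
    )


def write_structure(sm: StructureMatrix, path: str | Path) -> None:
    """Write the lower-triangular record layout (appendable binary)."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", _VERSION))
        for k, name in enumerate(sm.names):
            fh.write(_pack_record(name, sm.values[k, : k + 1]))


def _read_records(path: str | Path) -> list[tuple[str, np.ndarray]]:
    records: list[tuple[str, np.ndarray]] = []
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r}, not a structure file")
        ver_raw = fh.read(4)
        if len(ver_raw) != 4:
            raise FormatError(f"{path}: truncated header")
        (version,) = struct.unpack("<I", ver_raw)
        if version != _VERSION:
            raise FormatError(f"{path}: unsupported format version {version}")
        k = 0
        while True:
            len_raw = fh.read(4)
            if not len_raw:
                break
            if len(len_raw) != 4:
                raise FormatError(
                    f"{path}: truncated record {k} (last complete record: {k - 1})"
                )
            (name_len,) = struct.unpack("<I", len_raw)
            name_raw = fh.read(name_len)
            row_raw = fh.read((k + 1) * 8)
            if len(name_raw) != name_len or len(row_raw) != (k + 1) * 8:
                raise FormatError(
                    f"{path}: truncated record {k} (last complete record: {k - 1})"
                )
            records.append(
                (name_raw.decode("utf-8"), np.frombuffer(row_raw, dtype="<f8"))
            )
            k += 1
    return records


def read_structure_names(path: str | Path) -> list[str]:
    """Names stored in a structure file, in record order."""
    return [name for name, _ in _read_records(path)]


def read_structure(path: str | Path) -> StructureMatrix:
    """Read a structure file and reconstruct the full symmetric matrix."""
    records = _read_records(path)
    if len(records) < 2:
        raise FormatError(f"{path}: fewer than two records")
    names = [name for name, _ in records]
    n = len(names)
    values = np.empty((n, n))
    for k, (_, row) in enumerate(records):
        values[k, : k + 1] = row
        values[: k + 1, k] = row
    return StructureMatrix(names=names, values=values)


def update_structure(
    path: str | Path,
    new_vectors: Sequence[IndicatorVector],
    prior_vectors: Sequence[IndicatorVector] | str | Path,
    similarity: str = "pearson",
) -> None:
    """Append new sets to an existing structure file without rewriting it.

    ``prior_vectors`` supplies the indicator vectors of the sets already in
    the file (the file stores correlations, not vectors), either as a list
    or as a path to their indicator CSV; their names and order must match
    the file's records exactly.  One record per new vector is appended —
    its correlations with every prior vector, with the earlier new vectors
    and with itself — leaving all existing bytes untouched.
    """
    if isinstance(prior_vectors, (str, Path)):
        from .indicator import read_indicators

        prior_vectors = read_indicators(prior_vectors)

    file_names = read_structure_names(path)
    prior_names = [iv.set_name for iv in prior_vectors]
    if prior_names != file_names:
        raise ConsistencyError(
            f"{path}: prior vectors ({len(prior_names)} sets) do not match the "
            f"file's records ({len(file_names)} sets)"
        )
    collisions = sorted(
        {iv.set_name for iv in new_vectors} & set(file_names)
    )
    if collisions:
        raise MergeError(f"set names already present in {path}: {collisions}")
    new_names = [iv.set_name for iv in new_vectors]
    if len(set(new_names)) != len(new_names):
        raise InputError("duplicate set names among the new vectors")
    if not new_vectors:
        return

    Z_prior = np.stack(
        [
            _normalise(np.asarray(iv.vector, float), similarity, iv.set_name)
            for iv in prior_vectors
        ]
    )
    with open(path, "ab") as fh:
        Z_new: list[np.ndarray] = []
        for iv in new_vectors:
            z = _normalise(np.asarray(iv.vector, float), similarity, iv.set_name)
            k = Z_prior.shape[0] + len(Z_new)
            row = np.empty(k + 1)
            row[: Z_prior.shape[0]] = Z_prior @ z
            for j, zj in enumerate(Z_new):
                row[Z_prior.shape[0] + j] = float(z @ zj)
            row[k] = float(z @ z)
            fh.write(_pack_record(iv.set_name, row))
            Z_new.append(z)
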