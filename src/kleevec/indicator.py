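"""Indicator vectors: the leading eigenvector of each set's contrast matrix.

A sequence set i that contributed to a reference matrix R built from N sets
is contrasted against all the others through

    M_i = N/(N-1) * S_i/m_i  -  1/(N-1) * R
        = N/(N-1) * (S_i/m_i - R/N),

i.e. the set's own normalised Gram matrix minus the average of the other
sets'.  The indicator vector is the unit eigenvector of M_i with the
largest positive eigenvalue; it condenses what distinguishes the set from
the rest of the data into a single 4s-dimensional direction.

Sets absent from the reference can still be placed in an existing analysis
(extrapolation): M = S_i/m_i - R/N contrasts the new set against the
reference mean.  For a set that *is* in the reference this differs from
M_i only by self-exclusion and a positive scale factor, which leaves
eigenvectors untouched, so the two formulas agree in the limit of a set
that matches the reference structure.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse.linalg

from .encoding import EncodedSet
from .exceptions import (
    ConvergenceError,
    DegenerateContrastError,
    FormatError,
    InputError,
)
from .reference import ReferenceMatrix, set_gram

__all__ = [
    "IndicatorVector",
    "contrast_matrix",
    "leading_eigenpair",
    "compute_indicators",
    "write_indicators",
    "read_indicators",
]

logger = logging.getLogger(__name__)

DENSE_THRESHOLD = 512  # dimensions up to this use a full dense eigendecomposition


@dataclass
class IndicatorVector:
    """One set's indicator vector with its leading eigenvalue."""

    set_name: str
    vector: np.ndarray  # unit 4s-vector, sign-normalised
    eigenvalue: float
    in_reference: bool = True
    m: int = 1  # number of member sequences (carried into the CSV)


def contrast_matrix(
    S_i: np.ndarray, m_i: int, ref: ReferenceMatrix, in_reference: bool
) -> np.ndarray:
    """Build the matrix contrasting one set against the reference.

    In-reference sets use M_i = N/(N-1)*S_i/m_i - 1/(N-1)*R (needs N >= 2);
    sets absent from the reference use the extrapolation form
    M = S_i/m_i - R/N.
    """
    if S_i.shape != ref.R.shape:
        raise InputError(
            f"Gram matrix dimension {S_i.shape} does not match reference {ref.R.shape}"
        )
    N = ref.N
    if in_reference:
        if N < 2:
            raise InputError("at least two sets required for contrast")
        return (N / (N - 1)) * (S_i / m_i) - ref.R / (N - 1)
    return S_i / m_i - ref.R / N


def _sign_normalise(v: np.ndarray) -> np.ndarray:
    # largest-magnitude component positive; np.argmax takes the lowest index on ties
    idx = int(np.argmax(np.abs(v)))
    return -v if v[idx] < 0 else v


def leading_eigenpair(
    M: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10000,
    method: str = "auto",
) -> tuple[float, np.ndarray]:
    """Return (eigenvalue, unit eigenvector) for the algebraically largest
    eigenvalue of a symmetric matrix.

    ``method`` is ``auto`` (dense for small matrices, Lanczos otherwise),
    ``dense`` or ``iterative``.  The iterative path uses a fixed starting
    vector (normalised all-ones) so results are deterministic.  Raises
    :class:`DegenerateContrastError` when the largest eigenvalue is not
    positive and :class:`ConvergenceError` on non-convergence.
    """
    n = M.shape[0]
    if M.shape != (n, n):
        raise InputError("leading_eigenpair needs a square matrix")
    sym_err = np.abs(M - M.T).max()
    if sym_err > 1e-8 * max(1.0, np.abs(M).max()):
        raise InputError(f"matrix is not symmetric (max asymmetry {sym_err:.3g})")

    if method == "auto":
        method = "dense" if n <= DENSE_THRESHOLD else "iterative"

    if method == "dense" or n < 3:
        w, V = np.linalg.eigh(M)
        lam = float(w[-1])
        v = V[:, -1]
        if n >= 2 and lam > 0 and (lam - w[-2]) < 1e-6 * lam:
            logger.warning(
                "leading eigenvalue nearly degenerate (gap %.3g of %.3g); "
                "the indicator vector may be unstable",
                lam - w[-2],
                lam,
            )
    elif method == "iterative":
        v0 = np.ones(n) / np.sqrt(n)
        try:
            w, V = scipy.sparse.linalg.eigsh(
                M, k=1, which="LA", v0=v0, tol=tol, maxiter=max_iter
            )
        except scipy.sparse.linalg.ArpackNoConvergence as exc:
            raise ConvergenceError(
                f"eigensolver did not converge within {max_iter} iterations"
            ) from exc
        lam = float(w[0])
        v = V[:, 0]
    else:
        raise InputError(f"unknown eigensolver method {method!r}")

    if lam <= 0:
        raise DegenerateContrastError(
            f"no positive eigenvalue — degenerate contrast (largest = {lam:.6g})",
            eigenvalue=lam,
        )
    v = v / np.linalg.norm(v)
    residual = np.linalg.norm(M @ v - lam * v)
    scale = np.linalg.norm(M, ord=2) if n <= DENSE_THRESHOLD else abs(lam)
    if residual > max(tol, 1e-8) * max(scale, 1e-300):
        raise ConvergenceError(
            f"eigenpair residual {residual:.3g} exceeds tolerance"
        )
    return lam, _sign_normalise(v)


def compute_indicators(
    sets: Sequence[EncodedSet],
    ref: ReferenceMatrix,
    allow_extrapolation: bool = True,
    tol: float = 1e-10,
    max_iter: int = 10000,
    workers: int = 1,
) -> list[IndicatorVector]:
    """Compute one indicator vector per encoded set against a reference.

    Sets whose name appears in the reference use the in-reference contrast;
    others are extrapolated (or rejected if ``allow_extrapolation`` is
    False).  Each vector depends only on its own set and the reference, so
    any partitioning of the input gives identical results; ``workers``
    exercises that partitioning within one process.
    """
    in_ref_names = set(ref.contributing_set_names)

    def one(es: EncodedSet) -> IndicatorVector:
        in_ref = es.set_name in in_ref_names
        if not in_ref and not allow_extrapolation:
            raise InputError(
                f"set {es.set_name!r} is absent from the reference and "
                "extrapolation is disabled"
            )
        if es.s != ref.s:
            raise InputError(
                f"set {es.set_name!r} has alignment length {es.s}, "
                f"reference expects {ref.s}"
            )
        S, m = set_gram(es)
        M = contrast_matrix(S, m, ref, in_reference=in_ref)
        try:
            lam, v = leading_eigenpair(M, tol=tol, max_iter=max_iter)
        except (DegenerateContrastError, ConvergenceError, InputError) as exc:
            raise type(exc)(f"set {es.set_name!r}: {exc}") from exc
        return IndicatorVector(
            set_name=es.set_name, vector=v, eigenvalue=lam, in_reference=in_ref, m=m
        )

    if workers <= 1:
        return [one(es) for es in sets]
    # Partitioned path: same per-set computation, interleaved then restitched.
    out: list[IndicatorVector | None] = [None] * len(sets)
    for start in range(workers):
        for idx in range(start, len(sets), workers):
            out[idx] = one(sets[idx])
    return out  # type: ignore[return-value]


_HEADER_PREFIX = "set_name,"


def write_indicators(vectors: Sequence[IndicatorVector], path: str | Path) -> None:
    """Write indicator vectors as CSV: set_name, m, eigenvalue, components.

    Floats use 17 significant digits, so reading the file back restores the
    exact float64 values.  Files from split runs merge by concatenation
    (the reader skips repeated header lines).
    """
    if not vectors:
        raise InputError("no indicator vectors to write")
    dim = len(vectors[0].vector)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["set_name", "m", "eigenvalue"] + [f"c{i}" for i in range(dim)]
        )
        for iv in vectors:
            if len(iv.vector) != dim:
                raise InputError(
                    f"set {iv.set_name!r}: vector length {len(iv.vector)} != {dim}"
                )
            writer.writerow(
                [iv.set_name, iv.m, format(iv.eigenvalue, ".17g")]
                + [format(x, ".17g") for x in iv.vector]
            )


def read_indicators(path: str | Path) -> list[IndicatorVector]:
    """Read an indicator CSV (possibly a concatenation of several files)."""
    vectors: list[IndicatorVector] = []
    dim: int | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if row[0] == "set_name":  # header (possibly repeated after concatenation)
                continue
            if len(row) < 4:
                raise FormatError(f"{path}: line {lineno}: too few columns")
            try:
                m = int(row[1])
                eigenvalue = float(row[2])
                vec = np.array([float(x) for x in row[3:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise FormatError(
                    f"{path}: line {lineno}: vector length {len(vec)} "
                    f"inconsistent with {dim} from the header rows"
                )
            vectors.append(
                IndicatorVector(
                    set_name=row[0], vector=vec, eigenvalue=eigenvalue, m=m
                )
            )
    if not vectors:
        raise FormatError(f"{path}: no indicator vectors found")
    return vectors
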