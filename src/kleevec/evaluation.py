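"""Experiments on the impact of an incomplete reference matrix.

Indicator vectors can be computed against a reference matrix that is
missing some — or most — of the sequence sets, which is how new sequences
are integrated into an existing analysis without recomputation.  This
module quantifies the cost of that shortcut: it compares indicator-vector
sets by absolute Pearson correlation (absolute, because an eigenvector's
sign is arbitrary), compares structure matrices block-by-block between
taxonomic groups, and runs a randomised missingness experiment in which a
growing fraction of the sets is dropped from the reference and every set's
indicator vector is re-derived (extrapolating the dropped ones) and
compared with its full-reference counterpart.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .encoding import EncodedSet, GroupedAlignment, encode_sets, impute_ambiguous
from .exceptions import InputError
from .indicator import IndicatorVector, leading_eigenpair
from .render import AnnotationTable
from .structure import StructureMatrix, correlate

__all__ = [
    "ProjectedSets",
    "compare_indicator_sets",
    "compare_structures",
    "run_missingness_experiment",
]


def _abs_pearson(u: np.ndarray, v: np.ndarray) -> float:
    return abs(correlate(u, v, similarity="pearson"))


class ProjectedSets:
    """Exact low-rank workspace for repeated indicator-vector computation.

    Every per-set Gram matrix S_i/m_i — and hence every reference and
    contrast matrix built from any subset of the sets — lives in the span
    of the encoded sequence rows.  Projecting onto an orthonormal basis Q
    of that span turns each 4s x 4s eigenproblem into an r x r one
    (r <= total sequence count) with the identical positive leading
    eigenpair: the orthogonal complement of the span only contributes zero
    eigenvalues.  Reference-matrix subset experiments that would otherwise
    re-solve hundreds of large eigenproblems become cheap.
    """

    def __init__(self, sets: Sequence[EncodedSet]):
        self.names = [es.set_name for es in sets]
        if len(set(self.names)) != len(self.names):
            raise InputError("duplicate set names")
        X = np.vstack([es.matrix for es in sets])
        self.Q = scipy.linalg.orth(X.T)  # (4s, r)
        self.ms = [es.m for es in sets]
        self._grams = []
        for es in sets:
            B = es.matrix @ self.Q
            self._grams.append(B.T @ B)

    def indicators(self, reference_names: Sequence[str]) -> list[IndicatorVector]:
        """Indicator vectors of all sets against a reference built from a
        subset of them (sets outside the subset are extrapolated)."""
        ref_idx = [i for i, n in enumerate(self.names) if n in set(reference_names)]
        if len(ref_idx) < 2:
            raise InputError("at least two sets required for contrast")
        N = len(ref_idx)
        R_small = np.zeros_like(self._grams[0])
        for i in ref_idx:
            R_small += self._grams[i] / self.ms[i]
        in_ref = set(ref_idx)
        out = []
        for i, name in enumerate(self.names):
            G = self._grams[i] / self.ms[i]
            if i in in_ref:
                M = (N / (N - 1)) * G - R_small / (N - 1)
            else:
                M = G - R_small / N
            lam, v_small = leading_eigenpair(M, method="dense")
            v = self.Q @ v_small
            v /= np.linalg.norm(v)
            idx = int(np.argmax(np.abs(v)))
            if v[idx] < 0:
                v = -v
            out.append(
                IndicatorVector(
                    set_name=name,
                    vector=v,
                    eigenvalue=lam,
                    in_reference=i in in_ref,
                    m=self.ms[i],
                )
            )
        return out


def compare_indicator_sets(
    a: Sequence[IndicatorVector], b: Sequence[IndicatorVector]
) -> pd.DataFrame:
    """Per-set absolute Pearson correlation between two indicator-vector sets.

    The two lists must cover the same set names (order free).  Returns a
    DataFrame with columns ``set_name`` and ``abs_pearson``, in the order
    of ``a``.
    """
    names_a = {iv.set_name for iv in a}
    names_b = {iv.set_name for iv in b}
    if names_a != names_b:
        diff = sorted(names_a ^ names_b)
        raise InputError(f"indicator sets do not cover the same names: {diff}")
    by_name_b = {iv.set_name: iv for iv in b}
    rows = [
        (iv.set_name, _abs_pearson(iv.vector, by_name_b[iv.set_name].vector))
        for iv in a
    ]
    return pd.DataFrame(rows, columns=["set_name", "abs_pearson"])


def compare_structures(
    a: StructureMatrix, b: StructureMatrix, groups: AnnotationTable
) -> pd.DataFrame:
    """Pearson correlation between two structure matrices, per group pair.

    Sets are grouped by their coarsest annotation rank.  For every ordered
    pair of groups (g, h), the entries of ``a`` and ``b`` linking a set of
    g to a set of h — excluding the diagonal self-entries — are collected
    and their Pearson correlation reported.  Returns a DataFrame with
    columns ``group_a``, ``group_b``, ``pearson``.
    """
    if set(a.names) != set(b.names):
        diff = sorted(set(a.names) ^ set(b.names))
        raise InputError(f"structure matrices do not cover the same names: {diff}")
    missing = [n for n in a.names if n not in groups.table.index]
    if missing:
        raise InputError(f"sets missing from the group annotation: {missing}")

    b_perm = [b.names.index(n) for n in a.names]
    B = b.values[np.ix_(b_perm, b_perm)]
    A = a.values
    coarse = np.array([groups.coarse(n) for n in a.names])
    group_names = list(dict.fromkeys(coarse))

    rows = []
    for g in group_names:
        gi = np.flatnonzero(coarse == g)
        for h in group_names:
            hi = np.flatnonzero(coarse == h)
            mask = np.ones((len(gi), len(hi)), dtype=bool)
            if g == h:
                np.fill_diagonal(mask, False)
            xa = A[np.ix_(gi, hi)][mask]
            xb = B[np.ix_(gi, hi)][mask]
            if xa.size < 2 or np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
                r = np.nan
            else:
                r = correlate(xa, xb, similarity="pearson")
            rows.append((g, h, r))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "pearson"])


def run_missingness_experiment(
    aln: GroupedAlignment,
    fractions: Sequence[float],
    replicates: int,
    seed: int,
    impute: bool = True,
    drop_level: str = "set",
) -> pd.DataFrame:
    """Drop a random fraction of sets from the reference and measure the damage.

    For each fraction f and replicate: a uniformly random f-fraction of the
    sequence sets is removed from the reference matrix, every set's
    indicator vector is recomputed against the reduced reference (dropped
    sets are extrapolated), and compared with the full-reference vector by
    absolute Pearson correlation.  ``drop_level='sequence'`` instead drops
    individual sequences, rebuilding each affected set from its survivors
    (sets losing all members leave the reference entirely).

    Returns a tidy DataFrame (fraction, replicate, set_name, abs_pearson);
    fully reproducible for a fixed ``seed``.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise InputError(f"fraction {f} not in (0, 1)")
    if drop_level not in {"set", "sequence"}:
        raise InputError(f"unknown drop_level {drop_level!r}")

    if impute:
        aln = impute_ambiguous(aln)
    sets = encode_sets(aln)
    ws = ProjectedSets(sets)
    full_vectors = ws.indicators(ws.names)
    full_by_name = {iv.set_name: iv for iv in full_vectors}

    rows = []
    for f in fractions:
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, rep, int(round(f * 1000))])
            )
            if drop_level == "set":
                n_drop = int(round(f * len(sets)))
                dropped = set(
                    rng.choice(len(sets), size=n_drop, replace=False).tolist()
                )
                kept_names = [
                    es.set_name for i, es in enumerate(sets) if i not in dropped
                ]
                if len(kept_names) < 2:
                    import warnings

                    warnings.warn(
                        f"fraction {f}: fewer than 2 sets left in the reference; "
                        "skipped"
                    )
                    continue
                vectors = ws.indicators(kept_names)
            else:
                vectors = _sequence_drop_indicators(sets, f, rng)
                if vectors is None:
                    import warnings

                    warnings.warn(
                        f"fraction {f}: fewer than 2 sets left in the reference; "
                        "skipped"
                    )
                    continue
            for iv in vectors:
                rows.append(
                    (
                        f,
                        rep,
                        iv.set_name,
                        _abs_pearson(iv.vector, full_by_name[iv.set_name].vector),
                    )
                )
    return pd.DataFrame(
        rows, columns=["fraction", "replicate", "set_name", "abs_pearson"]
    )


def _sequence_drop_indicators(sets, f, rng):
    """Reference with a random fraction of individual sequences removed.

    Kept sets stay in the reference with their surviving members; sets
    losing every member leave the reference and are extrapolated.
    """
    from .indicator import compute_indicators
    from .reference import compute_reference

    n_seq = sum(es.m for es in sets)
    drop_ids = set(rng.choice(n_seq, size=int(round(f * n_seq)), replace=False).tolist())
    kept = []
    offset = 0
    for es in sets:
        keep_rows = [r for r in range(es.m) if offset + r not in drop_ids]
        offset += es.m
        if keep_rows:
            kept.append(EncodedSet(set_name=es.set_name, matrix=es.matrix[keep_rows]))
    if len(kept) < 2:
        return None
    ref = compute_reference(kept)
    return compute_indicators(sets, ref)
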