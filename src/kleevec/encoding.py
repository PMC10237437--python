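"""Alignment input, species grouping, N imputation and numeric encoding.

An aligned DNA barcode dataset enters the pipeline as a FASTA multiple
sequence alignment whose records are partitioned into *sequence sets*
(typically one set per species).  Each residue is mapped to a block of four
non-negative weights over (A, C, G, T): unambiguous bases become unit basis
vectors, IUPAC ambiguity codes spread unit mass uniformly over the bases
they cover, and gaps become all-zero blocks.  A set of m aligned sequences
of length s thus becomes an m x 4s real matrix, the raw material for the
reference and contrast matrices downstream.

Before encoding, missing-base characters (N) are imputed within each set:
an N is replaced by the modal character of its column among the set's
members, unless that mode is a gap or is not unique among non-gap
characters, in which case the N is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .exceptions import AlignmentError, InputError

__all__ = [
    "GAP_CHARS",
    "IUPAC_BASES",
    "GroupedAlignment",
    "EncodedSet",
    "HeaderFieldRule",
    "read_alignment",
    "read_grouping_table",
    "impute_ambiguous",
    "encode_residue",
    "encode_sets",
]

GAP_CHARS = frozenset({"-", "."})

# Bases covered by each accepted residue character, in (A, C, G, T) order.
# U is an alias for T; '.' an alias for '-'.
IUPAC_BASES: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
    "-": "",
    ".": "",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _build_weight_table() -> dict[str, np.ndarray]:
    table = {}
    for char, bases in IUPAC_BASES.items():
        w = np.zeros(4)
        if bases:
            w[[_BASE_INDEX[b] for b in bases]] = 1.0 / len(bases)
        w.setflags(write=False)
        table[char] = w
    return table


_WEIGHTS = _build_weight_table()


@dataclass(frozen=True)
class HeaderFieldRule:
    """Grouping rule extracting one separator-delimited field from the header.

    The header is first truncated at the first whitespace; the set name is
    field number `index` (0-based) after splitting on `separator`.
    """

    separator: str
    index: int

    def set_name(self, header: str) -> str:
        fields = header.split(self.separator)
        if self.index >= len(fields):
            raise InputError(
                f"header {header!r} has {len(fields)} field(s); "
                f"cannot extract field {self.index}"
            )
        return fields[self.index]


@dataclass
class GroupedAlignment:
    """An aligned, grouped set of DNA sequences.

    records : list of (sequence_id, set_name, residues) in file order.
    s       : alignment length in columns.
    set_names : unique set names in order of first appearance.
    """

    records: list[tuple[str, str, str]]
    s: int
    set_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no records")
        seen_ids: set[str] = set()
        names: list[str] = []
        for seq_id, set_name, residues in self.records:
            if len(residues) != self.s:
                raise AlignmentError(
                    f"record {seq_id!r} has length {len(residues)}, "
                    f"expected alignment length {self.s}"
                )
            if seq_id in seen_ids:
                raise InputError(f"duplicate sequence id {seq_id!r}")
            seen_ids.add(seq_id)
            if set_name not in names:
                names.append(set_name)
        if not self.set_names:
            self.set_names = names
        elif set(self.set_names) != set(names):
            raise InputError("set_names inconsistent with records")

    def members(self, set_name: str) -> list[tuple[str, str, str]]:
        return [r for r in self.records if r[1] == set_name]

    def iter_sets(self):
        """Yield (set_name, member records) in set_names order."""
        by_set: dict[str, list[tuple[str, str, str]]] = {n: [] for n in self.set_names}
        for rec in self.records:
            by_set[rec[1]].append(rec)
        for name in self.set_names:
            yield name, by_set[name]

    @property
    def n_sets(self) -> int:
        return len(self.set_names)


@dataclass
class EncodedSet:
    """Numeric encoding of one sequence set: an m x 4s weight matrix."""

    set_name: str
    matrix: np.ndarray  # shape (m, 4s), float64

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def s(self) -> int:
        return self.matrix.shape[1] // 4


def read_grouping_table(path: str | Path, skip_header: bool = False) -> dict[str, str]:
    """Read a two-column TSV mapping sequence_id -> set_name."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            seq_id, set_name = parts[0], parts[1]
            if seq_id in mapping:
                raise InputError(f"{path}: duplicate sequence id {seq_id!r}")
            mapping[seq_id] = set_name
    if not mapping:
        raise InputError(f"{path}: empty association table")
    return mapping


def read_alignment(
    fasta_path: str | Path,
    grouping: str | Path | HeaderFieldRule | dict[str, str] | None = None,
    skip_header: bool = False,
) -> GroupedAlignment:
    """Read an aligned FASTA and group its records into sequence sets.

    Parameters
    ----------
    fasta_path
        Path to an aligned FASTA file (all records the same length).
    grouping
        How to assign each record to a set:
        ``None`` — the set name is the header up to the first whitespace;
        a :class:`HeaderFieldRule` — a separator-delimited field of that token;
        a path or dict — an association table sequence_id -> set_name
        (records missing from the table are an error).
    skip_header
        Skip the first line of a TSV association table.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"no such file: {fasta_path}")

    table: dict[str, str] | None = None
    if isinstance(grouping, dict):
        table = grouping
    elif isinstance(grouping, (str, Path)):
        table = read_grouping_table(grouping, skip_header=skip_header)

    records: list[tuple[str, str, str]] = []
    s: int | None = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq_id = rec.id  # header token before the first whitespace
        residues = str(rec.seq).upper()
        if s is None:
            s = len(residues)
        if table is not None:
            if seq_id not in table:
                raise InputError(
                    f"sequence {seq_id!r} not present in the association table"
                )
            set_name = table[seq_id]
        elif isinstance(grouping, HeaderFieldRule):
            set_name = grouping.set_name(seq_id)
        else:
            set_name = seq_id
        records.append((seq_id, set_name, residues))

    if not records:
        raise InputError(f"{fasta_path}: no FASTA records found")
    return GroupedAlignment(records=records, s=s)


def _impute_column(chars: list[str]) -> list[str]:
    """Impute N characters in one within-set alignment column.

    The mode is taken over every character in the column (N and gaps
    included).  Replacement candidates are the modal characters minus gaps
    and minus N itself; the N is replaced only when exactly one candidate
    remains.
    """
    if "N" not in chars:
        return chars
    counts = Counter(chars)
    top = max(counts.values())
    candidates = [
        c for c, k in counts.items() if k == top and c not in GAP_CHARS and c != "N"
    ]
    if len(candidates) != 1:
        return chars
    mode = candidates[0]
    return [mode if c == "N" else c for c in chars]


def impute_ambiguous(aln: GroupedAlignment) -> GroupedAlignment:
    """Impute N characters set-wise by the modal column character.

    Within each sequence set and each column, every N is replaced by the
    column's modal character among the set's members unless the mode is a
    gap or tied between several non-gap characters.  Imputation reads the
    pre-imputation column contents only (no cascading) and never touches
    any character other than N.
    """
    replacement: dict[str, str] = {}
    for set_name, members in aln.iter_sets():
        rows = [list(residues) for _, _, residues in members]
        if any("N" in residues for _, _, residues in members):
            cols = list(map(list, zip(*rows)))
            cols = [_impute_column(col) for col in cols]
            rows = list(map(list, zip(*cols)))
        for (seq_id, _, _), row in zip(members, rows):
            replacement[seq_id] = "".join(row)
    new_records = [
        (seq_id, set_name, replacement[seq_id]) for seq_id, set_name, _ in aln.records
    ]
    return GroupedAlignment(records=new_records, s=aln.s, set_names=list(aln.set_names))


def encode_residue(c: str) -> np.ndarray:
    """Encode one residue character as its (A, C, G, T) weight vector.

    Unambiguous bases give unit basis vectors, an ambiguity code covering k
    bases gives weight 1/k on each, and gaps give the zero vector.
    Case-insensitive.  Any other character is an error.
    """
    w = _WEIGHTS.get(c.upper())
    if w is None:
        raise InputError(f"invalid residue character {c!r}")
    return w.copy()


def encode_sets(aln: GroupedAlignment) -> list[EncodedSet]:
    """Encode every sequence set of an (already imputed) alignment.

    Returns one :class:`EncodedSet` per set in ``set_names`` order, rows in
    record order, each row the concatenation of s four-weight blocks.
    """
    encoded = []
    for set_name, members in aln.iter_sets():
        matrix = np.empty((len(members), 4 * aln.s))
        for r, (seq_id, _, residues) in enumerate(members):
            for j, c in enumerate(residues):
                w = _WEIGHTS.get(c)
                if w is None:
                    raise InputError(
                        f"invalid residue character {c!r} at position {j + 1} "
                        f"of sequence {seq_id!r}"
                    )
                matrix[r, 4 * j : 4 * j + 4] = w
        encoded.append(EncodedSet(set_name=set_name, matrix=matrix))
    return encoded
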