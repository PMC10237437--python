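"""Clade-structured synthetic alignment generator.

Real barcode datasets (e.g. curated COI5-P alignments) are hierarchical:
species within a higher taxon resemble each other more than species across
taxa, and individuals within a species more still.  This generator
reproduces exactly that three-level structure with the simplest adequate
substitution process: a uniform random ancestral sequence is mutated
per-site (uniform choice among the three other bases, Jukes-Cantor-like)
into one ancestor per coarse group, then per sequence set, then per
member.  Optional per-site noise injects gaps, missing bases (N) and
2/3-base IUPAC ambiguity codes covering the true base.  No indels, no rate
heterogeneity — the point is to exercise the linear algebra and file
plumbing with a controllable clade signal, not to model real COI
evolution.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import GroupedAlignment
from .exceptions import InputError

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_alignment",
    "make_default_fixtures",
]

_BASES = np.array(list("ACGT"))
# ambiguity codes covering each base, by code size (2- or 3-base codes)
_COVERING = {
    "A": ["R", "W", "M", "D", "H", "V"],
    "C": ["Y", "S", "M", "B", "H", "V"],
    "G": ["R", "S", "K", "B", "D", "V"],
    "T": ["Y", "W", "K", "B", "D", "H"],
}


@dataclass
class SimulationConfig:
    """Parameters of the clade-structured simulator.

    Divergence parameters are per-site substitution probabilities along
    the group / set / member branches; they must be nested
    (d_within_set <= d_between_sets <= d_between_groups) so that a clade
    signal exists.  Noise parameters are per-site injection probabilities
    applied independently to every member sequence.
    """

    n_groups: int = 3
    sets_per_group: int = 3
    members_per_set: int | tuple[int, int] = 2
    s: int = 60
    d_between_groups: float = 0.15
    d_between_sets: float = 0.05
    d_within_set: float = 0.01
    p_gap: float = 0.0
    p_N: float = 0.0
    p_iupac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_between_groups", "d_between_sets", "d_within_set",
                     "p_gap", "p_N", "p_iupac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InputError(f"{name}={v} must be in [0, 1)")
        if not (self.d_within_set <= self.d_between_sets <= self.d_between_groups):
            raise InputError(
                "divergence must be nested: d_within_set <= d_between_sets "
                "<= d_between_groups"
            )
        if self.s < 10:
            raise InputError("alignment length s must be >= 10")
        if self.n_groups < 1 or self.sets_per_group < 1:
            raise InputError("n_groups and sets_per_group must be >= 1")
        lo, hi = self._member_range()
        if lo < 1 or hi < lo:
            raise InputError("members_per_set must be >= 1 (or a valid range)")

    def _member_range(self) -> tuple[int, int]:
        if isinstance(self.members_per_set, tuple):
            return self.members_per_set
        return self.members_per_set, self.members_per_set


@dataclass
class SimulatedDataset:
    """A simulated alignment plus its grouping and taxonomic annotation."""

    alignment: GroupedAlignment
    grouping: pd.DataFrame  # columns: sequence_id, set_name
    annotation: pd.DataFrame  # columns: set_name, group

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write alignment.fasta, groups.tsv and annotation.tsv to a directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "alignment.fasta",
            "groups": out_dir / "groups.tsv",
            "annotation": out_dir / "annotation.tsv",
        }
        with open(paths["fasta"], "w", encoding="utf-8") as fh:
            for seq_id, _, residues in self.alignment.records:
                fh.write(f">{seq_id}\n{residues}\n")
        self.grouping.to_csv(paths["groups"], sep="\t", header=False, index=False)
        self.annotation.to_csv(paths["annotation"], sep="\t", header=False, index=False)
        return paths


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with probability d, uniform among the 3 others."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < d)
    for i in hits:
        others = [b for b in "ACGT" if b != out[i]]
        out[i] = others[rng.integers(3)]
    return out


def simulate_alignment(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate a clade-structured alignment from a config.

    Draws an ancestral sequence, derives group ancestors, set ancestors and
    member sequences by successive per-site mutation, then injects gap / N
    / ambiguity noise independently per member site.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = _BASES[rng.integers(4, size=cfg.s)]
    lo, hi = cfg._member_range()

    records: list[tuple[str, str, str]] = []
    grouping_rows = []
    annotation_rows = []
    for g in range(cfg.n_groups):
        group_name = f"group{g:02d}"
        group_anc = _mutate(ancestor, cfg.d_between_groups, rng)
        for t in range(cfg.sets_per_group):
            set_name = f"{group_name}_set{t:02d}"
            set_anc = _mutate(group_anc, cfg.d_between_sets, rng)
            annotation_rows.append((set_name, group_name))
            n_members = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            for k in range(n_members):
                member = _mutate(set_anc, cfg.d_within_set, rng)
                member = _inject_noise(member, cfg, rng)
                seq_id = f"{set_name}_seq{k:02d}"
                records.append((seq_id, set_name, "".join(member)))
                grouping_rows.append((seq_id, set_name))

    return SimulatedDataset(
        alignment=GroupedAlignment(records=records, s=cfg.s),
        grouping=pd.DataFrame(grouping_rows, columns=["sequence_id", "set_name"]),
        annotation=pd.DataFrame(annotation_rows, columns=["set_name", "group"]),
    )


def _inject_noise(
    seq: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    u = rng.random(len(seq))
    for i in range(len(seq)):
        if u[i] < cfg.p_gap:
            out[i] = "-"
        elif u[i] < cfg.p_gap + cfg.p_N:
            out[i] = "N"
        elif u[i] < cfg.p_gap + cfg.p_N + cfg.p_iupac:
            codes = _COVERING[str(seq[i])]
            out[i] = codes[rng.integers(len(codes))]
    return out


def make_default_fixtures(seed: int = 0) -> dict[str, SimulatedDataset]:
    """The three canonical test datasets.

    ``tiny``       — 3 groups x 3 sets x 2 members, s=60: fast smoke data.
    ``medium``     — 5 groups x 10 sets x 3 members, s=400 (50 sets, 150
                     sequences): a reduced-scale stand-in for a curated
                     mammalian barcode alignment.
    ``degenerate`` — duplicated sets, a singleton set, gap columns and
                     N-rich columns: the awkward cases.
    """
    tiny = simulate_alignment(
        SimulationConfig(n_groups=3, sets_per_group=3, members_per_set=2, s=60,
                         seed=seed)
    )
    medium = simulate_alignment(
        SimulationConfig(
            n_groups=5,
            sets_per_group=10,
            members_per_set=3,
            s=400,
            d_between_groups=0.15,
            d_between_sets=0.05,
            d_within_set=0.01,
            p_gap=0.01,
            p_N=0.01,
            p_iupac=0.002,
            seed=seed + 1,
        )
    )
    degenerate = _make_degenerate(seed + 2)
    return {"tiny": tiny, "medium": medium, "degenerate": degenerate}


def _make_degenerate(seed: int) -> SimulatedDataset:
    """Hand-crafted awkward dataset built on a small simulated base."""
    base = simulate_alignment(
        SimulationConfig(n_groups=2, sets_per_group=2, members_per_set=2, s=30,
                         seed=seed)
    )
    records = list(base.alignment.records)
    s = base.alignment.s

    # a set duplicating another set's sequences exactly
    dup_source = [r for r in records if r[1] == records[0][1]]
    for i, (seq_id, _, residues) in enumerate(dup_source):
        records.append((f"dup_seq{i:02d}", "dup_set", residues))
    # a singleton set with an N-rich sequence
    first = records[0][2]
    noisy = "N" * 5 + first[5:]
    records.append(("singleton_seq00", "singleton_set", noisy))
    # a set with an all-gap column and N-only column
    gappy0 = "-" + first[1:14] + "N" + first[15:]
    gappy1 = "-" + records[1][2][1:14] + "N" + records[1][2][15:]
    records.append(("gappy_seq00", "gappy_set", gappy0))
    records.append(("gappy_seq01", "gappy_set", gappy1))

    grouping = pd.DataFrame(
        [(r[0], r[1]) for r in records], columns=["sequence_id", "set_name"]
    )
    set_names = list(dict.fromkeys(r[1] for r in records))
    annotation = pd.DataFrame(
        [(n, n.split("_")[0]) for n in set_names], columns=["set_name", "group"]
    )
    return SimulatedDataset(
        alignment=GroupedAlignment(records=records, s=s),
        grouping=grouping,
        annotation=annotation,
    )
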