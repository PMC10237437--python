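"""Klee diagram rendering: the structure matrix as an annotated heatmap.

Rows and columns are ordered by a hierarchical taxonomic annotation
(coarse rank first), so that related sets form contiguous blocks and the
block-diagonal pattern of within-clade similarity becomes visible.  The
within-group order is arbitrary but deterministic (stable sort, ties kept
in original order).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # deterministic, headless
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import InputError
from .structure import StructureMatrix

__all__ = [
    "AnnotationTable",
    "read_annotation",
    "order_by_annotation",
    "render_klee",
]


@dataclass
class AnnotationTable:
    """Per-set taxonomic rank labels, coarse to fine."""

    table: pd.DataFrame  # index: set_name, columns: rank levels coarse->fine

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise InputError(f"duplicate set names in annotation: {dupes}")

    @property
    def set_names(self) -> list[str]:
        return list(self.table.index)

    def ranks(self, set_name: str) -> tuple[str, ...]:
        return tuple(str(x) for x in self.table.loc[set_name])

    def coarse(self, set_name: str) -> str:
        return str(self.table.loc[set_name].iloc[0])


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a TSV of set_name plus one column per taxonomic rank."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: annotation needs set_name plus >= 1 rank column")
    df = df.set_index(0)
    df.index.name = "set_name"
    return AnnotationTable(table=df)


def order_by_annotation(sm: StructureMatrix, ann: AnnotationTable) -> np.ndarray:
    """Permutation sorting the structure matrix by taxonomic rank labels.

    Stable lexicographic sort on the (coarse, ..., fine) label tuple; ties
    keep their original order, so the within-group arrangement is
    arbitrary but deterministic.
    """
    missing = [n for n in sm.names if n not in ann.table.index]
    if missing:
        raise InputError(f"sets missing from the annotation: {missing}")
    keys = [ann.ranks(n) for n in sm.names]
    return np.array(
        sorted(range(len(sm.names)), key=lambda i: keys[i]), dtype=int
    )


def render_klee(
    sm: StructureMatrix,
    perm: Sequence[int] | np.ndarray,
    out: str | Path,
    annotation: AnnotationTable | None = None,
    colormap: str = "viridis",
    vmin: float = 0.0,
    vmax: float = 1.0,
) -> None:
    """Render the permuted structure matrix as a heatmap image.

    The colour scale defaults to [0, 1]; values below ``vmin`` are clamped
    and the clamping is flagged in the colourbar label.  When an annotation
    is given, boundary lines are drawn where the coarsest rank label
    changes.  The input matrix is never modified.
    """
    perm = np.asarray(perm, dtype=int)
    if sorted(perm.tolist()) != list(range(len(sm.names))):
        raise InputError("invalid permutation for this structure matrix")
    values = sm.values[np.ix_(perm, perm)]
    names = [sm.names[i] for i in perm]

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(
        values, cmap=colormap, vmin=vmin, vmax=vmax, interpolation="nearest"
    )
    label = "indicator-vector correlation"
    if values.min() < vmin:
        label += f" (values < {vmin:g} clamped)"
    fig.colorbar(im, ax=ax, label=label)

    if annotation is not None:
        coarse = [annotation.coarse(n) for n in names]
        boundaries = [i for i in range(1, len(coarse)) if coarse[i] != coarse[i - 1]]
        for b in boundaries:
            ax.axhline(b - 0.5, color="white", linewidth=0.8)
            ax.axvline(b - 0.5, color="white", linewidth=0.8)
        # one tick per coarse group, centred on its block
        ticks, labels = [], []
        start = 0
        for i in range(1, len(coarse) + 1):
            if i == len(coarse) or coarse[i] != coarse[start]:
                ticks.append((start + i - 1) / 2)
                labels.append(coarse[start])
                start = i
        ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
        ax.set_yticks(ticks, labels, fontsize=7)
    else:
        ax.set_xticks([])
        ax.set_yticks([])

    ax.set_title("Structure matrix (Klee diagram)")
    fig.tight_layout()
    fig.savefig(out, dpi=150, metadata=_stable_metadata(Path(out).suffix))
    plt.close(fig)


def _stable_metadata(suffix: str) -> dict | None:
    # strip timestamps so identical inputs give identical bytes
    if suffix.lower() == ".png":
        return {"Software": None}
    if suffix.lower() in {".svg", ".pdf"}:
        return {"Date": None}
    return None
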