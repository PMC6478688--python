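"""S/L/0 cell classes and the division-type matrix.

Every member of a granddaughter set receives a class: the outlier of a 3:L
set is an L-cell, the outlier of a 3:S set an S-cell, and every other set
member is a 0-cell.  Cells belonging to no complete granddaughter set stay
unclassified (this necessarily includes generations 1–2, which have no
grandmother two generations up).

A *division type* is the transition from a mother's class to the unordered
class pair of its two daughters.  Because both daughters of one mother lie
in the same granddaughter set — which holds at most one outlier — the only
possible daughter pairs are 0/0, S/0 and L/0; S/S, L/L and S/L are
structurally impossible.  Divisions touching any unclassified cell are
excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import LineageForest
from .motifs import DEFAULT_THRESHOLD, Motif, classify_forest


class CellClass(str, Enum):
    S = "S"
    L = "L"
    ZERO = "0"
    UNCLASSIFIED = "unclassified"


#: Row order of the division-type matrix (mother class).
ROW_CLASSES = (CellClass.S, CellClass.L, CellClass.ZERO)
#: Column order (unordered daughter pair).
PAIR_TYPES = ("0/0", "S/0", "L/0")


@dataclass(frozen=True, eq=False)
class DivisionTypeMatrix:
    """3x3 counts: mother class (S, L, 0) x daughter pair (0/0, S/0, L/0)."""

    counts: np.ndarray  # (3, 3) int

    def __eq__(self, other):
        return (isinstance(other, DivisionTypeMatrix)
                and np.array_equal(self.counts, other.counts))

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 array")

    @property
    def n_divisions(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.counts, dtype=int),
            index=pd.Index([c.value for c in ROW_CLASSES], name="from"),
            columns=pd.Index(PAIR_TYPES, name="to"),
        )

    def flat(self) -> np.ndarray:
        """Counts flattened row-major: 9 division types in matrix order."""
        return np.asarray(self.counts, dtype=int).ravel()


def assign_cell_classes(forest: LineageForest,
                        threshold: float = DEFAULT_THRESHOLD) -> dict[str, CellClass]:
    """Map every cell to its S/L/0 class (unclassified if in no set)."""
    classes = {cid: CellClass.UNCLASSIFIED for cid in forest.cells}
    for call in classify_forest(forest, threshold):
        for cid in call.set_ref.members:
            classes[cid] = CellClass.ZERO
        if call.motif is Motif.THREE_L:
            classes[call.outlier_id] = CellClass.L
        elif call.motif is Motif.THREE_S:
            classes[call.outlier_id] = CellClass.S
    return classes


@dataclass(frozen=True)
class DivisionEnumeration:
    divisions: tuple[tuple[CellClass, str], ...]  # (mother class, pair type)
    n_excluded: int  # divisions skipped because a participant was unclassified


def enumerate_divisions(forest: LineageForest,
                        classes: dict[str, CellClass]) -> DivisionEnumeration:
    """List (mother class, daughter pair type) for fully classified divisions.

    A division enters only when the mother and both daughters carry an
    S/L/0 class; others are excluded and counted.
    """
    entries = []
    excluded = 0
    for mother_id in sorted(forest.cells):
        daughters = forest.children_of(mother_id)
        if len(daughters) != 2:
            continue
        trio = [classes.get(mother_id, CellClass.UNCLASSIFIED)] + [
            classes.get(d, CellClass.UNCLASSIFIED) for d in daughters
        ]
        if any(c is CellClass.UNCLASSIFIED for c in trio):
            excluded += 1
            continue
        mc, c1, c2 = trio
        pair = frozenset((c1, c2))
        if CellClass.S in pair and CellClass.L in pair:
            raise AssertionError(
                f"impossible S/L daughter pair under {mother_id!r}"
            )
        if c1 is not CellClass.ZERO and c1 is c2:
            raise AssertionError(
                f"impossible {c1.value}/{c2.value} daughter pair under {mother_id!r}"
            )
        if CellClass.S in pair:
            ptype = "S/0"
        elif CellClass.L in pair:
            ptype = "L/0"
        else:
            ptype = "0/0"
        entries.append((mc, ptype))
    return DivisionEnumeration(tuple(entries), excluded)


def division_type_matrix(divisions: DivisionEnumeration | list) -> DivisionTypeMatrix:
    """Count divisions into the 3x3 matrix."""
    if isinstance(divisions, DivisionEnumeration):
        entries = divisions.divisions
    else:
        entries = divisions
    counts = np.zeros((3, 3), dtype=int)
    row = {c: i for i, c in enumerate(ROW_CLASSES)}
    col = {p: j for j, p in enumerate(PAIR_TYPES)}
    for mc, ptype in entries:
        counts[row[mc], col[ptype]] += 1
    return DivisionTypeMatrix(counts)


def forest_division_matrix(forest: LineageForest,
                           threshold: float = DEFAULT_THRESHOLD) -> DivisionTypeMatrix:
    """Convenience: classes -> divisions -> matrix in one call."""
    classes = assign_cell_classes(forest, threshold)
    return division_type_matrix(enumerate_divisions(forest, classes))
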