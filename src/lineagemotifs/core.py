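"""Lineage forests of tracked cells and their derived views.

A lineage tree records one founder cell and its clonal descendants from a
time-lapse movie.  Nodes are cells; a cell either was not observed to divide
(0 children) or divided into exactly two daughters.  The *cell cycle
duration* of a cell is its imaged lifetime, from the end of the mitosis that
created it to the completion of its own mitosis; it is only meaningful for
cells whose full lifetime lies inside the imaging window (``complete=True``).
Incomplete cells keep their place in the topology — they define tree shape —
but never contribute a duration to any statistic.

Generations are counted from the founder: root = generation 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence


class LineageValidationError(ValueError):
    """Raised when a set of cell records does not form a valid forest.

    ``problems`` lists every violation found, each naming the offending
    cell/lineage ids.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class CellRecord:
    """One tracked cell.

    Parameters
    ----------
    cell_id : str
        Globally unique identifier.
    lineage_id : str
        Identifier of the tree this cell belongs to.
    parent_id : str or None
        ``None`` for founder cells.
    generation : int
        1-based generation index; the founder is generation 1.
    duration : float or None
        Cell cycle duration in hours, if measured.
    complete : bool
        True when the full lifetime was imaged; only complete cells enter
        statistics.
    track : tuple of (time, x, y) or None
        Optional centroid track (hours, µm, µm).
    """

    cell_id: str
    lineage_id: str
    parent_id: Optional[str]
    generation: int
    duration: Optional[float] = None
    complete: bool = False
    track: Optional[tuple] = None


@dataclass(frozen=True)
class GranddaughterSet:
    """The four same-grandmother cells, ordered by increasing duration.

    ``members[0]`` (cell1) has the shortest duration, ``members[3]`` (cell4)
    the longest; duration ties are broken by lexicographic cell id so the
    ordering is deterministic.
    """

    grandmother_id: str
    members: tuple[str, str, str, str]
    durations: tuple[float, float, float, float]

    def __post_init__(self):
        if any(self.durations[i] > self.durations[i + 1] for i in range(3)):
            raise ValueError("granddaughter durations must be non-decreasing")


@dataclass(frozen=True)
class CensorResult:
    """Outcome of short-duration lineage censoring."""

    forest: "LineageForest"
    removed_lineages: tuple[str, ...]
    effective_k: int


class LineageForest:
    """A validated set of rooted binary lineage trees.

    Construct via :func:`build_forest`; direct construction skips validation.
    """

    def __init__(self, cells: Mapping[str, CellRecord], children: Mapping[str, tuple],
                 roots: Sequence[str]):
        self.cells: dict[str, CellRecord] = dict(cells)
        self.children: dict[str, tuple] = {k: tuple(v) for k, v in children.items()}
        self.roots: tuple[str, ...] = tuple(roots)

    # -- basic views ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells.values())

    @property
    def lineage_ids(self) -> tuple[str, ...]:
        return tuple(sorted({c.lineage_id for c in self.cells.values()}))

    def children_of(self, cell_id: str) -> tuple:
        return self.children.get(cell_id, ())

    def complete_cells(self) -> list[CellRecord]:
        """Complete cells with a duration, in sorted cell-id order."""
        return sorted(
            (c for c in self.cells.values() if c.complete and c.duration is not None),
            key=lambda c: c.cell_id,
        )

    @property
    def generation_pools(self) -> dict[int, list[float]]:
        """Generation -> sorted complete durations across all trees."""
        pools: dict[int, list[float]] = {}
        for c in self.complete_cells():
            pools.setdefault(c.generation, []).append(c.duration)
        return {g: sorted(v) for g, v in sorted(pools.items())}

    def with_durations(self, durations: Mapping[str, float]) -> "LineageForest":
        """Copy of the forest with complete cells' durations replaced.

        Topology, completeness and generations are untouched; used by
        within-generation permutation.
        """
        cells = {}
        for cid, c in self.cells.items():
            if cid in durations:
                cells[cid] = replace(c, duration=float(durations[cid]))
            else:
                cells[cid] = c
        return LineageForest(cells, self.children, self.roots)

    def subset_lineages(self, keep: Iterable[str]) -> "LineageForest":
        keep = set(keep)
        cells = {cid: c for cid, c in self.cells.items() if c.lineage_id in keep}
        children = {cid: ch for cid, ch in self.children.items() if cid in cells}
        roots = tuple(r for r in self.roots if r in cells)
        return LineageForest(cells, children, roots)


def build_forest(records: Iterable[CellRecord]) -> LineageForest:
    """Validate cell records and assemble a :class:`LineageForest`.

    Checks: globally unique cell ids; parent references resolvable within the
    same lineage; every cell has 0 or 2 children; generations consistent with
    topology (root = 1); complete cells carry a positive duration.

    Raises
    ------
    LineageValidationError
        With one entry per violation, naming the offending ids.
    """
    records = list(records)
    problems: list[str] = []
    if not records:
        raise LineageValidationError(["no records supplied"])

    cells: dict[str, CellRecord] = {}
    for r in records:
        if r.cell_id in cells:
            problems.append(f"duplicate cell_id {r.cell_id!r}")
        else:
            cells[r.cell_id] = r

    children: dict[str, list] = {}
    roots: list[str] = []
    for r in cells.values():
        if r.parent_id is None:
            roots.append(r.cell_id)
        else:
            parent = cells.get(r.parent_id)
            if parent is None:
                problems.append(
                    f"cell {r.cell_id!r} references missing parent {r.parent_id!r}"
                )
            elif parent.lineage_id != r.lineage_id:
                problems.append(
                    f"cell {r.cell_id!r} (lineage {r.lineage_id!r}) has parent in "
                    f"lineage {parent.lineage_id!r}"
                )
            else:
                children.setdefault(r.parent_id, []).append(r.cell_id)

    for pid, ch in children.items():
        if len(ch) == 1:
            problems.append(f"cell {pid!r} has exactly one child ({ch[0]!r})")
        elif len(ch) > 2:
            problems.append(f"cell {pid!r} has {len(ch)} children")

    # one root per lineage
    by_lineage: dict[str, list[str]] = {}
    for r in roots:
        by_lineage.setdefault(cells[r].lineage_id, []).append(r)
    for lid, rs in by_lineage.items():
        if len(rs) > 1:
            problems.append(f"lineage {lid!r} has {len(rs)} roots: {sorted(rs)}")
    rooted_lineages = set(by_lineage)
    for lid in {c.lineage_id for c in cells.values()}:
        if lid not in rooted_lineages:
            problems.append(f"lineage {lid!r} has no root")

    # recompute generations from topology and check
    if not problems:
        gen: dict[str, int] = {}
        stack = [(r, 1) for r in roots]
        while stack:
            cid, g = stack.pop()
            gen[cid] = g
            for ch in children.get(cid, ()):
                stack.append((ch, g + 1))
        for cid, c in cells.items():
            if cid not in gen:
                problems.append(f"cell {cid!r} unreachable from any root (cycle?)")
            elif gen[cid] != c.generation:
                problems.append(
                    f"cell {cid!r}: supplied generation {c.generation} != "
                    f"topological generation {gen[cid]}"
                )

    for c in cells.values():
        if c.duration is not None and not math.isfinite(c.duration):
            problems.append(f"cell {c.cell_id!r} has non-finite duration")
        elif c.duration is not None and c.duration <= 0:
            problems.append(f"cell {c.cell_id!r} has non-positive duration {c.duration}")
        if c.complete and c.duration is None:
            problems.append(f"cell {c.cell_id!r} marked complete but has no duration")

    if problems:
        raise LineageValidationError(problems)

    children_sorted = {pid: tuple(sorted(ch)) for pid, ch in children.items()}
    return LineageForest(cells, children_sorted, sorted(roots))


def extract_granddaughter_sets(forest: LineageForest) -> list[GranddaughterSet]:
    """All granddaughter sets: one per grandmother with four complete grandchildren.

    A grandmother contributes a set only when all four of its grandchildren
    were imaged over their complete lifetimes; any incomplete or missing
    grandchild discards the set.  Members are ordered by (duration, cell_id).
    The daughters' own completeness is irrelevant: only the grandchildren's
    durations enter the motif analysis.
    """
    sets: list[GranddaughterSet] = []
    for gm_id in sorted(forest.cells):
        daughters = forest.children_of(gm_id)
        if len(daughters) != 2:
            continue
        grandchildren = [g for d in daughters for g in forest.children_of(d)]
        if len(grandchildren) != 4:
            continue
        recs = [forest.cells[g] for g in grandchildren]
        if not all(r.complete and r.duration is not None for r in recs):
            continue
        recs.sort(key=lambda r: (r.duration, r.cell_id))
        sets.append(
            GranddaughterSet(
                grandmother_id=gm_id,
                members=tuple(r.cell_id for r in recs),
                durations=tuple(r.duration for r in recs),
            )
        )
    return sets


def censor_suspect_lineages(forest: LineageForest, k: int) -> CensorResult:
    """Remove every lineage containing one of the ``k`` shortest durations.

    Emulates quality censoring of suspiciously short cell cycle durations
    (probable tracking errors): the ``k`` shortest complete durations over
    the whole forest are located and every lineage containing at least one
    of them is dropped.  Ties at the k-th shortest are all included, and the
    realized count is reported as ``effective_k``.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return CensorResult(forest, (), 0)
    complete = forest.complete_cells()
    if k > len(complete):
        raise ValueError(
            f"k={k} exceeds the number of complete durations ({len(complete)})"
        )
    durations = sorted(c.duration for c in complete)
    cutoff = durations[k - 1]
    flagged = [c for c in complete if c.duration <= cutoff]
    removed = sorted({c.lineage_id for c in flagged})
    kept = [lid for lid in forest.lineage_ids if lid not in removed]
    return CensorResult(forest.subset_lineages(kept), tuple(removed), len(flagged))
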