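"""Lineage-table and track CSV formats, Newick export, result serialization.

The lineage table is the one interchange format: one row per tracked cell
with columns ``lineage_id, cell_id, parent_id, generation, duration_h,
complete``.  ``parent_id`` is empty for founder cells, ``duration_h`` empty
when unmeasured, ``complete`` is boolean.  Generations are 1-based (root =
1).  Track tables carry ``cell_id, time_h, x_um, y_um``.  Simulated and
imported data share these readers, so every downstream analysis runs
unchanged on either.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .colony import ColonyFrame
from .core import CellRecord, LineageForest
from .propagation import PropagationResult

LINEAGE_COLUMNS = ("lineage_id", "cell_id", "parent_id", "generation",
                   "duration_h", "complete")
TRACK_COLUMNS = ("cell_id", "time_h", "x_um", "y_um")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


class LineageTableError(ValueError):
    """All parse/validation problems of a lineage table, with line numbers."""

    def __init__(self, path, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(f"{path}: " + "; ".join(self.problems))


def read_lineage_table(path) -> list[CellRecord]:
    """Parse a lineage-table CSV into cell records.

    Validation problems are aggregated and raised together, each citing the
    1-based file line (header = line 1).  Hard errors return nothing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise LineageTableError(path, [f"missing columns: {', '.join(missing)}"])
    problems: list[str] = []
    records: list[CellRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        cid = row.cell_id.strip()
        if not cid:
            problems.append(f"line {line}: empty cell_id")
            continue
        if cid in seen:
            problems.append(f"line {line}: duplicate cell_id {cid!r}")
            continue
        seen.add(cid)
        parent = row.parent_id.strip() or None
        try:
            generation = int(row.generation)
        except ValueError:
            problems.append(f"line {line}: unparseable generation {row.generation!r}")
            continue
        dur_s = row.duration_h.strip()
        duration = None
        if dur_s:
            try:
                duration = float(dur_s)
            except ValueError:
                problems.append(f"line {line}: unparseable duration {dur_s!r}")
                continue
            if not np.isfinite(duration) or duration <= 0:
                problems.append(f"line {line}: non-positive duration {dur_s!r}")
                continue
        comp_s = row.complete.strip().lower()
        if comp_s in _TRUE:
            complete = True
        elif comp_s in _FALSE:
            complete = False
        else:
            problems.append(f"line {line}: unparseable complete flag {row.complete!r}")
            continue
        records.append(CellRecord(
            cell_id=cid, lineage_id=row.lineage_id.strip(), parent_id=parent,
            generation=generation, duration=duration, complete=complete,
        ))
    if problems:
        raise LineageTableError(path, problems)
    return records


def write_lineage_table(forest: LineageForest | Sequence[CellRecord], path) -> None:
    records = list(forest) if isinstance(forest, LineageForest) else list(forest)
    df = pd.DataFrame({
        "lineage_id": [r.lineage_id for r in records],
        "cell_id": [r.cell_id for r in records],
        "parent_id": [r.parent_id or "" for r in records],
        "generation": [r.generation for r in records],
        "duration_h": ["" if r.duration is None else repr(r.duration)
                       for r in records],
        "complete": [str(r.complete).lower() for r in records],
    })
    df.to_csv(path, index=False)


def write_track_table(frames_by_colony: dict[str, list[ColonyFrame]], path) -> None:
    """Track CSV (times in hours, coordinates in µm, as the header states)."""
    rows = []
    for colony, frames in frames_by_colony.items():
        for f in frames:
            for cid, (x, y) in zip(f.cell_ids, f.points):
                rows.append((colony, cid, f.time, x, y))
    pd.DataFrame(rows, columns=("colony_id",) + TRACK_COLUMNS).to_csv(path, index=False)


def read_track_table(path) -> dict[str, list[ColonyFrame]]:
    df = pd.read_csv(path)
    need = {"colony_id", *TRACK_COLUMNS}
    missing = need - set(df.columns)
    if missing:
        raise LineageTableError(path, [f"missing columns: {', '.join(sorted(missing))}"])
    out: dict[str, list[ColonyFrame]] = {}
    for colony, cdf in df.groupby("colony_id", sort=True):
        frames = []
        for t, fdf in cdf.groupby("time_h", sort=True):
            frames.append(ColonyFrame(
                time=float(t),
                cell_ids=tuple(fdf["cell_id"].astype(str)),
                points=fdf[["x_um", "y_um"]].to_numpy(dtype=float),
            ))
        out[str(colony)] = frames
    return out


def tracks_of(frames: Sequence[ColonyFrame]) -> dict[str, list[tuple]]:
    """Per-cell (time, x, y) tracks from a frame sequence."""
    tracks: dict[str, list[tuple]] = {}
    for f in frames:
        for cid, (x, y) in zip(f.cell_ids, f.points):
            tracks.setdefault(cid, []).append((f.time, float(x), float(y)))
    return tracks


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def export_newick(forest: LineageForest) -> str:
    """One Newick line per tree; branch length = duration (hours).

    Incomplete cells carry an ``[&incomplete]`` comment after their label
    and omit the branch length when no duration was measured.
    """

    def node(cid: str) -> str:
        c = forest.cells[cid]
        children = forest.children_of(cid)
        inner = ""
        if children:
            inner = "(" + ",".join(node(ch) for ch in children) + ")"
        label = cid if c.complete else f"{cid}[&incomplete]"
        length = f":{c.duration:g}" if c.duration is not None else ""
        return f"{inner}{label}{length}"

    return "\n".join(node(r) + ";" for r in forest.roots) + "\n"


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_propagation_json(result: PropagationResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n")


def read_propagation_json(path) -> PropagationResult:
    return PropagationResult.from_dict(json.loads(Path(path).read_text()))


def decision_matrix_tsv(result: PropagationResult) -> str:
    """Colour-coded division-type matrix as TSV (count and decision per cell)."""
    frame = result.empirical.to_frame()
    out = ["from\t" + "\t".join(frame.columns)]
    for i, row_label in enumerate(frame.index):
        cells = []
        for j in range(3):
            decision = result.decisions[i][j]
            cells.append(f"{frame.iat[i, j]}"
                         + (f" ({decision})" if decision else ""))
        out.append(row_label + "\t" + "\t".join(cells))
    return "\n".join(out) + "\n"
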