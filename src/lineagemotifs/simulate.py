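"""Stochastic lineage and track generators for calibration and power studies.

The forest generator emulates the structure of single-cell time-lapse
tracking data: binary division trees followed for up to seven generations,
log-normal cell cycle durations drawn independently within each generation
(the exchangeable null the propagation test permutes against), and
censoring at an imaging horizon — cells still alive when imaging ends are
incomplete and contribute no duration.

An optional ``outlier_propagation`` mechanism injects the alternative the
propagation test is designed to detect: per granddaughter set, with a given
rate, one prospective granddaughter's duration is scaled by a
multiplicative factor, creating a relative outlier.  ``source_class``
controls which branch carries the perturbation — ``"0"`` prefers an
unperturbed mother (de-novo outlier generation), ``"L"``/``"S"`` prefer an
already-perturbed mother, producing outlier chains across generations.
Ground truth records every perturbed cell.

Defaults encode the primary epithelial-colony study conditions: 36 lineages,
16.2 h median duration, 85 h imaging horizon, at most 7 generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .colony import ColonyFrame
from .core import CellRecord, LineageForest, build_forest


@dataclass(frozen=True)
class OutlierPropagation:
    """Mother→daughter asymmetric outlier-injection mechanism."""

    source_class: str = "0"        # "0" | "L" | "S": preferred mother branch
    target_pair_type: str = "L/0"  # "L/0" (scale up) | "S/0" (scale down)
    rate: float = 0.8              # per-granddaughter-set injection probability
    outlier_effect: float = 3.0    # multiplicative duration factor

    def __post_init__(self):
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must lie in [0, 1]")
        if self.outlier_effect <= 0:
            raise ValueError("outlier_effect must be positive")
        if self.target_pair_type not in ("L/0", "S/0"):
            raise ValueError("target_pair_type must be 'L/0' or 'S/0'")
        if self.source_class not in ("0", "L", "S"):
            raise ValueError("source_class must be '0', 'L' or 'S'")


@dataclass(frozen=True)
class ForestSimConfig:
    """Study conditions for the forest generator (hours throughout)."""

    n_lineages: int = 36
    max_generation: int = 7
    median_duration_h: float = 16.2
    sigma_log: float = 0.22         # log-scale SD of the log-normal family
    imaging_horizon_h: float = 85.0
    median_by_generation: Optional[dict[int, float]] = None
    mechanism: Optional[OutlierPropagation] = None

    def __post_init__(self):
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if not 1 <= self.max_generation <= 7:
            raise ValueError("max_generation must lie in 1..7")
        if self.imaging_horizon_h <= 0:
            raise ValueError("imaging horizon must be positive")
        if self.median_duration_h <= 0 or self.sigma_log < 0:
            raise ValueError("invalid duration model")

    def median_for(self, generation: int) -> float:
        if self.median_by_generation and generation in self.median_by_generation:
            return self.median_by_generation[generation]
        return self.median_duration_h


@dataclass(frozen=True)
class SimulatedForest:
    forest: LineageForest
    perturbed: frozenset[str]  # ground-truth ids of mechanism-scaled cells
    birth_times: dict[str, float]


class _SimCell:
    __slots__ = ("cell_id", "lineage_id", "parent", "generation", "birth",
                 "duration", "children", "tagged")

    def __init__(self, cell_id, lineage_id, parent, generation, birth, duration):
        self.cell_id = cell_id
        self.lineage_id = lineage_id
        self.parent = parent
        self.generation = generation
        self.birth = birth
        self.duration = duration
        self.children: list["_SimCell"] = []
        self.tagged = False


def simulate_forest(config: ForestSimConfig,
                    rng: np.random.Generator | int | None = None) -> SimulatedForest:
    """Grow a forest under the configured duration model and mechanism.

    Trees grow until the cumulative birth time exceeds the imaging horizon;
    a cell whose lifetime crosses the horizon is incomplete (no duration in
    statistics) and leaves no tracked children.  The mechanism, when
    present, perturbs at most one prospective granddaughter per grandmother
    (see module docstring), before that granddaughter's own completeness
    and children are resolved — so at rate 1.0 and a large effect nearly
    every complete granddaughter set carries exactly one relative outlier.
    """
    rng = np.random.default_rng(rng)
    horizon = config.imaging_horizon_h
    mech = config.mechanism

    def draw(generation: int) -> float:
        mu = np.log(config.median_for(generation))
        return float(rng.lognormal(mean=mu, sigma=config.sigma_log))

    all_cells: list[_SimCell] = []
    for li in range(config.n_lineages):
        lid = f"L{li + 1:03d}"
        root = _SimCell(f"{lid}.1", lid, None, 1, 0.0, draw(1))
        all_cells.append(root)
        level = [root]
        for g in range(1, config.max_generation):
            nxt: list[_SimCell] = []
            for cell in level:
                if cell.birth + cell.duration > horizon:
                    continue  # incomplete: division not observed
                num = int(cell.cell_id.split(".")[1])
                for k in (2 * num, 2 * num + 1):
                    child = _SimCell(f"{lid}.{k}", lid, cell, g + 1,
                                     cell.birth + cell.duration, draw(g + 1))
                    cell.children.append(child)
                    nxt.append(child)
            # grandchildren of generation g-1 grandmothers are now complete
            if mech is not None and g >= 2:
                grandmothers = {c.parent.parent for c in nxt
                                if c.parent.parent is not None}
                for gm in sorted(grandmothers, key=lambda c: c.cell_id):
                    _apply_mechanism(gm, mech, rng)
            if not nxt:
                break
            level = nxt
            all_cells.extend(nxt)

    records = []
    births = {}
    for c in all_cells:
        complete = c.birth + c.duration <= horizon
        records.append(CellRecord(
            cell_id=c.cell_id, lineage_id=c.lineage_id,
            parent_id=c.parent.cell_id if c.parent else None,
            generation=c.generation,
            duration=c.duration if complete else None,
            complete=complete,
        ))
        births[c.cell_id] = c.birth
    forest = build_forest(records)
    perturbed = frozenset(c.cell_id for c in all_cells if c.tagged)
    return SimulatedForest(forest, perturbed, births)


def _apply_mechanism(grandmother: _SimCell, mech: OutlierPropagation,
                     rng: np.random.Generator) -> None:
    """Perturb at most one of the grandmother's four prospective granddaughters."""
    daughters = grandmother.children
    if len(daughters) != 2 or any(len(d.children) != 2 for d in daughters):
        return
    if rng.random() >= mech.rate:
        return
    if mech.source_class in ("L", "S"):
        preferred = [d for d in daughters if d.tagged]
    else:
        preferred = [d for d in daughters if not d.tagged]
    pool = preferred if preferred else daughters
    mother = pool[int(rng.integers(len(pool)))]
    child = mother.children[int(rng.integers(2))]
    factor = (mech.outlier_effect if mech.target_pair_type == "L/0"
              else 1.0 / mech.outlier_effect)
    child.duration *= factor
    child.tagged = True


def fixture_toy_forest() -> LineageForest:
    """Small deterministic two-lineage forest used across the test suite.

    Durations are invented round numbers chosen so that the forest contains
    one of each interesting granddaughter-set motif at threshold 2:

    * lineage A, grandmother ``A.1``: durations (10, 11, 12, 30) → 3:L
      (outlier ``A.7``); grandmother ``A.2``: (5, 6, 7, 8) → flat.
    * lineage B, grandmother ``B.1``: (2, 20, 21, 22) → 3:S (outlier
      ``B.4``); grandmother ``B.2``: (10, 12, 28, 30) → 2:2.
    """
    layout = {
        # cell_id: (parent, generation, duration)
        "A.1": (None, 1, 10), "A.2": ("A.1", 2, 12), "A.3": ("A.1", 2, 11),
        "A.4": ("A.2", 3, 10), "A.5": ("A.2", 3, 11),
        "A.6": ("A.3", 3, 12), "A.7": ("A.3", 3, 30),
        "A.8": ("A.4", 4, 5), "A.9": ("A.4", 4, 6),
        "A.10": ("A.5", 4, 7), "A.11": ("A.5", 4, 8),
        "B.1": (None, 1, 10), "B.2": ("B.1", 2, 9), "B.3": ("B.1", 2, 13),
        "B.4": ("B.2", 3, 2), "B.5": ("B.2", 3, 20),
        "B.6": ("B.3", 3, 21), "B.7": ("B.3", 3, 22),
        "B.8": ("B.4", 4, 10), "B.9": ("B.4", 4, 12),
        "B.10": ("B.5", 4, 28), "B.11": ("B.5", 4, 30),
    }
    records = [
        CellRecord(cell_id=cid, lineage_id=cid[0], parent_id=parent,
                   generation=gen, duration=float(dur), complete=True)
        for cid, (parent, gen, dur) in layout.items()
    ]
    return build_forest(records)


@dataclass(frozen=True)
class TrackSimConfig:
    """Cohesive random-walk motility model (hours, µm)."""

    dt: float = 0.5            # frame interval
    noise_sd: float = 0.5      # isotropic step noise per frame
    attraction: float = 0.05   # pull toward the colony centroid per frame
    daughter_offset: float = 1.0  # birth displacement from the mother


def simulate_tracks(sim: SimulatedForest,
                    config: TrackSimConfig = TrackSimConfig(),
                    rng: np.random.Generator | int | None = None
                    ) -> dict[str, list[ColonyFrame]]:
    """Centroid tracks per colony (one colony per lineage).

    Cells perform a cohesive random walk: each frame they move toward the
    colony centroid (rate ``attraction``) plus isotropic Gaussian noise;
    daughters start adjacent to the mother's last position.  Returns, per
    lineage id, the list of :class:`ColonyFrame` at times 0, dt, 2·dt, …
    until the last cell disappears.
    """
    rng = np.random.default_rng(rng)
    forest = sim.forest
    frames_by_lineage: dict[str, list[ColonyFrame]] = {}
    for lid in forest.lineage_ids:
        cells = [c for c in forest.cells.values() if c.lineage_id == lid]
        cells.sort(key=lambda c: (sim.birth_times[c.cell_id], c.cell_id))
        death = {}
        for c in cells:
            if c.complete and c.duration is not None:
                death[c.cell_id] = sim.birth_times[c.cell_id] + c.duration
            else:
                death[c.cell_id] = np.inf  # alive until imaging end
        t_end = max(
            (sim.birth_times[c.cell_id] + (c.duration or 0.0) for c in cells),
            default=0.0,
        )
        pos: dict[str, np.ndarray] = {}
        frames: list[ColonyFrame] = []
        t = 0.0
        while t <= t_end + 1e-9:
            alive = [c for c in cells
                     if sim.birth_times[c.cell_id] <= t + 1e-9 and t < death[c.cell_id] + 1e-9]
            for c in alive:
                if c.cell_id not in pos:
                    parent = c.parent_id
                    if parent is not None and parent in pos:
                        angle = rng.uniform(0, 2 * np.pi)
                        offset = config.daughter_offset * np.array(
                            [np.cos(angle), np.sin(angle)])
                        pos[c.cell_id] = pos[parent] + offset
                    else:
                        pos[c.cell_id] = np.zeros(2)
            if alive:
                centroid = np.mean([pos[c.cell_id] for c in alive], axis=0)
                ids = tuple(c.cell_id for c in alive)
                pts = np.array([pos[c.cell_id] for c in alive])
                frames.append(ColonyFrame(time=t, cell_ids=ids, points=pts))
                for c in alive:
                    step = config.attraction * (centroid - pos[c.cell_id])
                    if config.noise_sd > 0:
                        step = step + rng.normal(0, config.noise_sd, size=2)
                    pos[c.cell_id] = pos[c.cell_id] + step
            t += config.dt
        frames_by_lineage[lid] = frames
    return frames_by_lineage
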