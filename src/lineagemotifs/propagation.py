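"""Monte-Carlo permutation test for non-stochastic propagation of outlier
division types.

Null hypothesis: within each generation, cell cycle durations are
exchangeable across all lineages — outlier (S/L) cells then arise purely
from where durations happen to land in the fixed tree topology.  The test:

1. Permute all complete durations without replacement within each
   generation, across all lineages, keeping topology (default 10,000
   permutations); recompute the division-type matrix each time.
2. *Per-type probability* (step i): for each of the nine division types,
   the empirical probability is the CDF value of the observed count against
   the permutation null, P(count <= observed).
3. *Per-type significance* (step ii): scoring every permuted matrix
   against the same ensemble CDF yields the null distribution of the
   probability statistic; a type is significant when its empirical
   probability falls strictly outside the central 95% of that null
   (direction: over / under-represented).
4. *Global significance* (step iii): treating each permuted matrix in turn
   as pseudo-empirical and counting its significant types gives the null
   distribution of "number of significant types"; the global p-value is the
   tail probability P(#significant >= observed #significant).
5. *Decision* (step iv): a division type is colour-coded (over: red,
   under: green in the original display) only when both its per-type
   criterion and the global criterion are below the 5% level.

Interval endpoints on the discrete nulls are inclusive order-statistic
quantiles, and "outside" is strict — ties at an endpoint never fire, which
makes the per-type test conservative (see docs/methods.md).

The :class:`ForestEngine` pre-compiles the forest's permutation-invariant
structure (set membership, candidate divisions) so each permutation costs
one vectorized re-sort and re-count; it is exact — engine output is
verified against the record-level pipeline in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import LineageForest
from .division_types import (PAIR_TYPES, ROW_CLASSES, DivisionTypeMatrix)
from .motifs import DEFAULT_THRESHOLD

#: Flattened row-major labels of the nine division types.
TYPE_LABELS = tuple(f"{r.value}->{p}" for r in ROW_CLASSES for p in PAIR_TYPES)


# ---------------------------------------------------------------------------
# vectorized forest engine
# ---------------------------------------------------------------------------

class ForestEngine:
    """Permutation-invariant compilation of a forest.

    Holds, as flat arrays over the forest's complete cells (sorted by cell
    id): the per-generation index groups, the granddaughter-set membership
    (member columns in cell-id order, so a stable sort on durations
    reproduces the documented (duration, cell_id) tie-break), and the
    candidate divisions whose mother and daughters all belong to sets.
    """

    def __init__(self, forest: LineageForest):
        self.forest = forest
        complete = forest.complete_cells()  # sorted by cell_id
        self.cell_ids = [c.cell_id for c in complete]
        self.index = {cid: i for i, cid in enumerate(self.cell_ids)}
        self.durations = np.array([c.duration for c in complete], dtype=float)
        self.generations = np.array([c.generation for c in complete], dtype=int)

        self.gen_groups: list[np.ndarray] = []
        for g in sorted(set(self.generations.tolist())):
            self.gen_groups.append(np.flatnonzero(self.generations == g))

        # granddaughter sets: member indices in cell-id order
        members = []
        for gm_id in sorted(forest.cells):
            daughters = forest.children_of(gm_id)
            if len(daughters) != 2:
                continue
            gch = [g for d in daughters for g in forest.children_of(d)]
            if len(gch) != 4:
                continue
            if not all(cid in self.index for cid in gch):
                continue
            members.append(sorted(self.index[cid] for cid in gch))
        self.set_members = (np.array(members, dtype=np.intp)
                            if members else np.empty((0, 4), dtype=np.intp))

        in_set = np.zeros(len(self.cell_ids), dtype=bool)
        in_set[self.set_members.ravel()] = True
        divisions = []
        for mother_id in sorted(forest.cells):
            ch = forest.children_of(mother_id)
            if len(ch) != 2:
                continue
            ids = (mother_id,) + ch
            if not all(cid in self.index for cid in ids):
                continue
            idx = [self.index[cid] for cid in ids]
            if all(in_set[i] for i in idx):
                divisions.append(idx)
        self.divisions = (np.array(divisions, dtype=np.intp)
                          if divisions else np.empty((0, 3), dtype=np.intp))

    @property
    def n_sets(self) -> int:
        return len(self.set_members)

    # -- permutations -----------------------------------------------------

    def permuted_durations(self, rng: np.random.Generator, n_perm: int) -> np.ndarray:
        """(n_perm, n_cells) durations permuted within each generation.

        Draw order (generations ascending, one permutation each, repeated
        per replicate) is shared with :func:`permute_within_generations`.
        """
        out = np.tile(self.durations, (n_perm, 1))
        for b in range(n_perm):
            for idx in self.gen_groups:
                out[b, idx] = out[b, idx][rng.permutation(len(idx))]
        return out

    # -- vectorized classification ---------------------------------------

    def _set_orders(self, durations: np.ndarray):
        """Stable sort of each set's member durations; (B, S, 4) orders/values."""
        vals = durations[:, self.set_members]  # (B, S, 4)
        order = np.argsort(vals, axis=-1, kind="stable")
        return order, np.take_along_axis(vals, order, axis=-1)

    def motif_codes(self, durations: np.ndarray,
                    threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        """(B, S) codes: 0=3:L, 1=3:S, 2=2:2, 3=flat.

        Works on the unscaled adjacent gaps — the variance scale factor
        cancels in the dissimilarity-index ratio.
        """
        order, sv = self._set_orders(durations)
        gaps = np.diff(sv, axis=-1)  # (B, S, 3)
        top = gaps.max(axis=-1)
        second = gaps.sum(axis=-1) - top - gaps.min(axis=-1)
        cut = gaps.argmax(axis=-1)
        nonflat = (second > 0) & (top > threshold * second)
        codes = np.full(top.shape, 3, dtype=np.int8)
        codes[nonflat & (cut == 2)] = 0
        codes[nonflat & (cut == 0)] = 1
        codes[nonflat & (cut == 1)] = 2
        return codes

    def motif_frequencies(self, durations: np.ndarray,
                          threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        """(B, 4) motif frequencies in (3:L, 3:S, 2:2, flat) order."""
        codes = self.motif_codes(durations, threshold)
        return np.stack([(codes == k).mean(axis=1) for k in range(4)], axis=1)

    def cell_classes(self, durations: np.ndarray,
                     threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        """(B, n_cells) classes: -1 unclassified, 0 = 0-cell, 1 = S, 2 = L."""
        B, n = durations.shape[0], len(self.cell_ids)
        classes = np.full((B, n), -1, dtype=np.int8)
        if self.n_sets == 0:
            return classes
        order, _ = self._set_orders(durations)
        codes = self.motif_codes(durations, threshold)
        classes[:, self.set_members.ravel()] = 0
        mem = np.broadcast_to(self.set_members, (B,) + self.set_members.shape)
        longest = np.take_along_axis(mem, order[..., 3:], axis=-1)[..., 0]
        shortest = np.take_along_axis(mem, order[..., :1], axis=-1)[..., 0]
        rows = np.arange(B)[:, None]
        flat = classes.reshape(-1)
        mask_l = codes == 0
        flat[(rows * n + longest)[mask_l]] = 2
        mask_s = codes == 1
        flat[(rows * n + shortest)[mask_s]] = 1
        return classes

    def matrices(self, durations: np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        """(B, 3, 3) division-type count matrices."""
        B = durations.shape[0]
        if len(self.divisions) == 0:
            return np.zeros((B, 3, 3), dtype=np.int64)
        classes = self.cell_classes(durations, threshold)
        mc = classes[:, self.divisions[:, 0]]
        d1 = classes[:, self.divisions[:, 1]]
        d2 = classes[:, self.divisions[:, 2]]
        col = np.maximum(d1, d2)  # 0 -> 0/0, 1 -> S/0, 2 -> L/0
        row = np.where(mc == 1, 0, np.where(mc == 2, 1, 2))
        cell = row * 3 + col
        offset = np.arange(B)[:, None] * 9
        counts = np.bincount((offset + cell).ravel(), minlength=B * 9)
        return counts.reshape(B, 3, 3)

    def empirical_matrix(self, threshold: float = DEFAULT_THRESHOLD) -> DivisionTypeMatrix:
        return DivisionTypeMatrix(self.matrices(self.durations[None, :], threshold)[0])


def permute_within_generations(forest: LineageForest,
                               rng: np.random.Generator | int | None = None
                               ) -> LineageForest:
    """One within-generation permutation of the forest's complete durations.

    For each generation (ascending), the complete durations are reassigned
    by a uniform random permutation among that generation's complete cells
    across all lineages; incomplete cells and topology are untouched, so
    per-generation duration multisets are conserved.
    """
    rng = np.random.default_rng(rng)
    complete = forest.complete_cells()
    new: dict[str, float] = {}
    by_gen: dict[int, list] = {}
    for c in complete:  # already sorted by cell_id
        by_gen.setdefault(c.generation, []).append(c)
    for g in sorted(by_gen):
        cells = by_gen[g]
        perm = rng.permutation(len(cells))
        for dst, src in enumerate(perm):
            new[cells[dst].cell_id] = cells[src].duration
    return forest.with_durations(new)


# ---------------------------------------------------------------------------
# ensemble and the four-step decision
# ---------------------------------------------------------------------------

@dataclass
class PermutationEnsemble:
    """Division-type matrices from within-generation permutations."""

    n_perm: int
    threshold: float
    matrices: np.ndarray  # (n_perm, 3, 3)
    seed: Optional[int] = None

    @property
    def counts(self) -> np.ndarray:
        """(n_perm, 9) flattened row-major counts."""
        return self.matrices.reshape(self.n_perm, 9)


def build_ensemble(forest: LineageForest | ForestEngine,
                   threshold: float = DEFAULT_THRESHOLD,
                   n_perm: int = 10_000,
                   rng: np.random.Generator | int | None = None
                   ) -> PermutationEnsemble:
    """Permute, re-classify and re-count ``n_perm`` times."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    engine = forest if isinstance(forest, ForestEngine) else ForestEngine(forest)
    durations = engine.permuted_durations(rng, n_perm)
    mats = engine.matrices(durations, threshold)
    return PermutationEnsemble(n_perm=n_perm, threshold=threshold,
                               matrices=mats, seed=seed)


def cdf_probability(observed: float, null_counts: Sequence[float]) -> float:
    """Fraction of null values <= observed (empirical CDF value)."""
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    return float(np.count_nonzero(null_counts <= observed) / null_counts.size)


def _order_stat_interval(values: np.ndarray, lo_q: float = 0.025,
                         hi_q: float = 0.975) -> tuple[float, float]:
    """Inclusive order-statistic (type-1) central interval endpoints."""
    v = np.sort(values)
    n = len(v)
    i_lo = max(math.ceil(lo_q * n), 1) - 1
    i_hi = math.ceil(hi_q * n) - 1
    return float(v[i_lo]), float(v[i_hi])


@dataclass(frozen=True)
class TypeRecord:
    label: str
    count: int
    probability: float
    interval: tuple[float, float]
    significant: bool
    direction: str  # over | under | none


@dataclass(frozen=True)
class GlobalRecord:
    histogram: dict[int, float]  # #significant types -> null frequency
    cumulative: dict[int, float]  # x -> P(#significant >= x)
    empirical_count: int
    p: float


@dataclass(frozen=True)
class PropagationResult:
    empirical: DivisionTypeMatrix
    per_type: tuple[TypeRecord, ...]
    global_: GlobalRecord
    decisions: tuple[tuple[Optional[str], ...], ...]  # 3x3 of over/under/None
    threshold: float
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_perm": self.n_perm,
            "empirical_matrix": self.empirical.to_frame().values.tolist(),
            "per_type": [
                {
                    "label": t.label,
                    "count": t.count,
                    "probability": t.probability,
                    "interval": list(t.interval),
                    "significant": t.significant,
                    "direction": t.direction,
                }
                for t in self.per_type
            ],
            "global": {
                "histogram": {str(k): v for k, v in self.global_.histogram.items()},
                "cumulative": {str(k): v for k, v in self.global_.cumulative.items()},
                "empirical_count": self.global_.empirical_count,
                "p": self.global_.p,
            },
            "decisions": [list(row) for row in self.decisions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PropagationResult":
        return cls(
            empirical=DivisionTypeMatrix(np.array(d["empirical_matrix"], dtype=int)),
            per_type=tuple(
                TypeRecord(t["label"], t["count"], t["probability"],
                           tuple(t["interval"]), t["significant"], t["direction"])
                for t in d["per_type"]
            ),
            global_=GlobalRecord(
                histogram={int(k): v for k, v in d["global"]["histogram"].items()},
                cumulative={int(k): v for k, v in d["global"]["cumulative"].items()},
                empirical_count=d["global"]["empirical_count"],
                p=d["global"]["p"],
            ),
            decisions=tuple(tuple(row) for row in d["decisions"]),
            threshold=d["threshold"],
            n_perm=d["n_perm"],
        )


def _probability_table(counts: np.ndarray) -> np.ndarray:
    """CDF-score every row of (B, 9) counts against the column-wise ensemble CDF."""
    B = counts.shape[0]
    probs = np.empty_like(counts, dtype=float)
    for t in range(counts.shape[1]):
        s = np.sort(counts[:, t])
        probs[:, t] = np.searchsorted(s, counts[:, t], side="right") / B
    return probs


def per_type_significance(empirical_matrix: DivisionTypeMatrix,
                          ensemble: PermutationEnsemble) -> tuple[TypeRecord, ...]:
    """Steps i + ii: per-type empirical probabilities and significance flags."""
    counts = ensemble.counts
    observed = empirical_matrix.flat()
    probs = _probability_table(counts)
    records = []
    for t, label in enumerate(TYPE_LABELS):
        s = np.sort(counts[:, t])
        p_emp = np.searchsorted(s, observed[t], side="right") / ensemble.n_perm
        lo, hi = _order_stat_interval(probs[:, t])
        if p_emp < lo:
            sig, direction = True, "under"
        elif p_emp > hi:
            sig, direction = True, "over"
        else:
            sig, direction = False, "none"
        records.append(TypeRecord(label, int(observed[t]), float(p_emp),
                                  (lo, hi), sig, direction))
    return tuple(records)


def _null_significance_counts(ensemble: PermutationEnsemble) -> np.ndarray:
    """Step iii inner loop: #significant types when each permuted matrix is
    treated as pseudo-empirical against the same ensemble."""
    probs = _probability_table(ensemble.counts)
    lo = np.empty(probs.shape[1])
    hi = np.empty(probs.shape[1])
    for t in range(probs.shape[1]):
        lo[t], hi[t] = _order_stat_interval(probs[:, t])
    outside = (probs < lo[None, :]) | (probs > hi[None, :])
    return outside.sum(axis=1)


def global_significance(ensemble: PermutationEnsemble,
                        empirical_count: int) -> GlobalRecord:
    """Step iii: null distribution of #significant types and the tail p."""
    sig_counts = _null_significance_counts(ensemble)
    n = len(sig_counts)
    values, freq = np.unique(sig_counts, return_counts=True)
    histogram = {int(v): float(c / n) for v, c in zip(values, freq)}
    max_x = max(int(values.max(initial=0)), empirical_count)
    cumulative = {
        x: float(np.count_nonzero(sig_counts >= x) / n) for x in range(0, max_x + 1)
    }
    p = cumulative.get(empirical_count, 0.0)
    if empirical_count == 0:
        p = 1.0
    return GlobalRecord(histogram, cumulative, empirical_count, p)


def propagation_result(empirical_matrix: DivisionTypeMatrix,
                       ensemble: PermutationEnsemble) -> PropagationResult:
    """Step iv: combine per-type and global criteria into the colour-coded
    decision matrix."""
    per_type = per_type_significance(empirical_matrix, ensemble)
    emp_count = sum(t.significant for t in per_type)
    global_ = global_significance(ensemble, emp_count)
    joint = global_.p <= 0.05
    decisions = []
    for i in range(3):
        row = []
        for j in range(3):
            t = per_type[i * 3 + j]
            row.append(t.direction if (t.significant and joint) else None)
        decisions.append(tuple(row))
    return PropagationResult(
        empirical=empirical_matrix,
        per_type=per_type,
        global_=global_,
        decisions=tuple(decisions),
        threshold=ensemble.threshold,
        n_perm=ensemble.n_perm,
    )


def run_propagation_test(forest: LineageForest,
                         threshold: float = DEFAULT_THRESHOLD,
                         n_perm: int = 10_000,
                         rng: np.random.Generator | int | None = None
                         ) -> PropagationResult:
    """Full four-step test on one forest."""
    engine = ForestEngine(forest)
    ensemble = build_ensemble(engine, threshold, n_perm, rng)
    return propagation_result(engine.empirical_matrix(threshold), ensemble)
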