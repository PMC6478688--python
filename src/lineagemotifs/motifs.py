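"""Outlier detection method (ODM): diversity motifs of granddaughter sets.

Each granddaughter set holds four cell cycle durations ordered ascending
(cell1..cell4).  Pairwise distances are variance-scaled (|Δ|/s with s the
sample SD of the four values — the univariate Mahalanobis distance), the
four cells are clustered by agglomerative single linkage, and the
*dissimilarity index* is the ratio of the highest to the second-highest
merge height.  When the index strictly exceeds the chosen threshold
(default 2), the top-level bipartition decides the motif:

* cell4 isolated           -> ``3:L`` (one relatively long outlier, the L-cell)
* cell1 isolated           -> ``3:S`` (one relatively short outlier, the S-cell)
* {cell1,cell2}|{cell3,cell4} -> ``2:2`` (two pairs)

otherwise the set is ``flat``.  Threshold 2 is the natural choice: above 2,
the gap between the two top-level sub-clusters exceeds the sum of the
smallest pairwise distances within the rest of the set.

For four sorted scalars, single linkage reduces exactly to the three
adjacent gaps: the merge heights are the sorted gaps and the top split cuts
the largest gap.  The production path uses this reduction (it is what makes
the permutation ensembles cheap); the test-suite checks it against
scipy's general single-linkage routine and against exhaustive enumeration
of all bipartitions.  Because every pairwise distance shares the same
scale factor s, the dissimilarity index — a ratio — does not depend on s,
and motif calls are invariant under affine rescaling of the durations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GranddaughterSet, LineageForest, extract_granddaughter_sets

#: Default dissimilarity-index threshold.
DEFAULT_THRESHOLD = 2.0

#: Default threshold sweep grid.
SWEEP_THRESHOLDS = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 7.0)


class Motif(str, Enum):
    THREE_L = "3:L"
    THREE_S = "3:S"
    TWO_TWO = "2:2"
    FLAT = "flat"


MOTIF_ORDER = (Motif.THREE_L, Motif.THREE_S, Motif.TWO_TWO, Motif.FLAT)


@dataclass(frozen=True)
class MergeHierarchy:
    """Single-linkage dendrogram of one granddaughter set.

    ``heights`` are the three merge heights in ascending order (scaled
    distance units); ``top_split`` is the bipartition obtained by cutting
    the final merge, expressed in 1-based rank positions (cell1..cell4).
    """

    heights: tuple[float, float, float]
    top_split: tuple[tuple[int, ...], tuple[int, ...]]


@dataclass(frozen=True)
class MotifCall:
    set_ref: GranddaughterSet
    motif: Motif
    dissimilarity_index: Optional[float]
    outlier_id: Optional[str]
    split: tuple[tuple[int, ...], tuple[int, ...]]


def pairwise_scaled_distances(durations: Sequence[float]) -> np.ndarray:
    """Six variance-scaled pairwise distances, condensed order.

    distance(i, j) = |d_i - d_j| / s with s the ddof=1 standard deviation of
    the four durations (the univariate Mahalanobis distance).  All-equal
    input gives six zeros.  Order: (1,2),(1,3),(1,4),(2,3),(2,4),(3,4).
    """
    d = np.asarray(durations, dtype=float)
    if d.shape != (4,):
        raise ValueError("exactly four durations required")
    if not np.all(np.isfinite(d)):
        raise ValueError("durations must be finite")
    s = d.std(ddof=1)
    out = np.abs(d[:, None] - d[None, :])[np.triu_indices(4, k=1)]
    if s == 0:
        return np.zeros(6)
    return out / s


def single_linkage_hierarchy(durations: Sequence[float]) -> MergeHierarchy:
    """Single-linkage dendrogram of four durations (ascending input assumed
    for rank labels; the input is sorted internally).

    For sorted scalars the single-linkage merge heights equal the three
    adjacent gaps in ascending order, and cutting the final merge splits the
    sequence at the largest gap, so both sides of the top split are
    contiguous runs of cell1..cell4.  Ties among maximal gaps (which always
    force a dissimilarity index of 1, hence a flat motif) are broken in
    favour of the balanced middle cut, then leftmost.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if d.shape != (4,):
        raise ValueError("exactly four durations required")
    if not np.all(np.isfinite(d)):
        raise ValueError("durations must be finite")
    s = d.std(ddof=1)
    gaps = np.diff(d) / s if s > 0 else np.zeros(3)
    heights = tuple(np.sort(gaps))
    cut = _top_cut(gaps)
    split = (tuple(range(1, cut + 2)), tuple(range(cut + 2, 5)))
    return MergeHierarchy(heights=heights, top_split=split)


def _top_cut(gaps: np.ndarray) -> int:
    """Index (0..2) of the gap cut by the final merge; balanced-middle tie rule."""
    m = gaps.max()
    candidates = np.flatnonzero(gaps == m)
    if 1 in candidates:
        return 1
    return int(candidates[0])


def dissimilarity_index(h: MergeHierarchy) -> Optional[float]:
    """Highest merge height over second-highest; None when undefined.

    Undefined (second-highest = 0) occurs for sets where three or more
    durations coincide; such sets are classified flat.
    """
    top, second = h.heights[2], h.heights[1]
    if second == 0:
        return None
    return top / second


def classify_set(gset: GranddaughterSet, threshold: float = DEFAULT_THRESHOLD) -> MotifCall:
    """Assign the diversity motif of one granddaughter set.

    The index must strictly exceed the threshold for a non-flat call; ties
    at the threshold, undefined indices and zero-variance sets are flat.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    h = single_linkage_hierarchy(gset.durations)
    idx = dissimilarity_index(h)
    motif = Motif.FLAT
    outlier: Optional[str] = None
    if idx is not None and idx > threshold:
        left, right = h.top_split
        if right == (4,):
            motif = Motif.THREE_L
            outlier = gset.members[3]
        elif left == (1,):
            motif = Motif.THREE_S
            outlier = gset.members[0]
        else:  # {1,2}|{3,4}; {1,3}|{2,4} is unreachable for scalar single linkage
            motif = Motif.TWO_TWO
    return MotifCall(
        set_ref=gset, motif=motif, dissimilarity_index=idx,
        outlier_id=outlier, split=h.top_split,
    )


def classify_forest(forest: LineageForest,
                    threshold: float = DEFAULT_THRESHOLD) -> list[MotifCall]:
    """One MotifCall per granddaughter set of the forest (deterministic)."""
    return [classify_set(s, threshold) for s in extract_granddaughter_sets(forest)]


def motif_frequencies(calls: Sequence[MotifCall]) -> dict[Motif, float]:
    """Relative motif frequencies of a collection of calls (sum to 1)."""
    if not calls:
        return {m: float("nan") for m in MOTIF_ORDER}
    n = len(calls)
    return {m: sum(c.motif is m for c in calls) / n for m in MOTIF_ORDER}


def motif_frequency_sweep(forest: LineageForest,
                          thresholds: Sequence[float] = SWEEP_THRESHOLDS) -> pd.DataFrame:
    """Motif frequencies as a function of the dissimilarity-index threshold.

    Returns a DataFrame indexed by threshold with one column per motif;
    rows sum to 1.  Empty forests give an empty table.
    """
    sets = extract_granddaughter_sets(forest)
    if not sets:
        return pd.DataFrame(columns=[m.value for m in MOTIF_ORDER], dtype=float)
    rows = {}
    for t in thresholds:
        calls = [classify_set(s, t) for s in sets]
        rows[t] = {m.value: f for m, f in motif_frequencies(calls).items()}
    return pd.DataFrame.from_dict(rows, orient="index")[[m.value for m in MOTIF_ORDER]]


def motif_confidence_band(forest: LineageForest,
                          thresholds: Sequence[float] = SWEEP_THRESHOLDS,
                          n_perm: int = 1000,
                          rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Permutation confidence band for the motif frequencies.

    Cell cycle durations are permuted without replacement within each
    generation across all lineages (topology maintained); motif frequencies
    are recomputed per permutation and the 2.5%/97.5% empirical quantiles
    per motif and threshold returned, as a DataFrame with a (threshold,
    motif) row MultiIndex and columns ``lo``/``hi``.
    """
    from .propagation import ForestEngine  # local import to avoid a cycle

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    engine = ForestEngine(forest)
    durations = engine.permuted_durations(rng, n_perm)
    rows = []
    for t in thresholds:
        freqs = engine.motif_frequencies(durations, t)  # (n_perm, 4)
        lo = np.quantile(freqs, 0.025, axis=0, method="inverted_cdf")
        hi = np.quantile(freqs, 0.975, axis=0, method="inverted_cdf")
        for j, m in enumerate(MOTIF_ORDER):
            rows.append({"threshold": t, "motif": m.value, "lo": lo[j], "hi": hi[j]})
    return pd.DataFrame(rows).set_index(["threshold", "motif"])


def calls_to_frame(calls: Sequence[MotifCall]) -> pd.DataFrame:
    """Tabulate motif calls (exportable as TSV)."""
    return pd.DataFrame(
        {
            "grandmother": [c.set_ref.grandmother_id for c in calls],
            "motif": [c.motif.value for c in calls],
            "dissimilarity_index": [c.dissimilarity_index for c in calls],
            "outlier_id": [c.outlier_id for c in calls],
            "split": ["|".join(",".join(map(str, side)) for side in c.split)
                      for c in calls],
            "members": [";".join(c.set_ref.members) for c in calls],
            "durations": [";".join(f"{d:g}" for d in c.set_ref.durations)
                          for c in calls],
        }
    )
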