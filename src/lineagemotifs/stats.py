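"""Effect sizes, dispersion and kinship-pair correlation summaries.

Robust effect sizes use the rz-score family: absolute median differences
scaled by (average) raw median absolute deviation — no 1.4826 normal
consistency factor is applied.  Dispersion of duration distributions is
quantified as the interdecile range over the median (IDR/median).
Kinship correlations compare mother–daughter, sibling and granddaughter
(cousin) duration pairs via repeatedly subsampled Spearman coefficients,
which makes conditions with different pair counts comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .core import LineageForest, extract_granddaughter_sets

RELATIONS = ("mother_daughter", "daughter_daughter", "granddaughter_granddaughter")


@dataclass(frozen=True)
class RelationPair:
    relation: str
    cell_ids: tuple[str, str]
    durations: tuple[float, float]


def relation_pairs(forest: LineageForest, relation: str,
                   cousins_only: bool = True) -> list[RelationPair]:
    """All duration pairs of the requested kinship relation.

    ``mother_daughter``: every (parent, child) pair, both complete.
    ``daughter_daughter``: every sibling pair.
    ``granddaughter_granddaughter``: pairs within a granddaughter set whose
    members have different mothers (cousins); set ``cousins_only=False`` to
    include sibling pairs within the set as well.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; expected one of {RELATIONS}")
    pairs: list[RelationPair] = []

    def _complete(cid: str) -> bool:
        c = forest.cells[cid]
        return c.complete and c.duration is not None

    if relation == "mother_daughter":
        for pid in sorted(forest.cells):
            if not _complete(pid):
                continue
            for ch in forest.children_of(pid):
                if _complete(ch):
                    pairs.append(_pair(forest, relation, pid, ch))
    elif relation == "daughter_daughter":
        for pid in sorted(forest.cells):
            ch = forest.children_of(pid)
            if len(ch) == 2 and all(_complete(c) for c in ch):
                pairs.append(_pair(forest, relation, *ch))
    else:
        for gset in extract_granddaughter_sets(forest):
            members = sorted(gset.members)
            for i in range(4):
                for j in range(i + 1, 4):
                    a, b = members[i], members[j]
                    same_mother = forest.cells[a].parent_id == forest.cells[b].parent_id
                    if cousins_only and same_mother:
                        continue
                    pairs.append(_pair(forest, relation, a, b))
    return pairs


def _pair(forest: LineageForest, relation: str, a: str, b: str) -> RelationPair:
    return RelationPair(
        relation=relation,
        cell_ids=(a, b),
        durations=(forest.cells[a].duration, forest.cells[b].duration),
    )


def subsampled_spearman(pairs: Sequence[RelationPair] | np.ndarray,
                        n_pairs: int = 60, reps: int = 100,
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Spearman coefficients of ``reps`` random ``n_pairs``-subsamples.

    Each repetition draws ``n_pairs`` pairs uniformly without replacement
    and computes the Spearman rank correlation of the two duration columns.
    """
    rng = np.random.default_rng(rng)
    if len(pairs) and isinstance(pairs[0], RelationPair):
        data = np.array([p.durations for p in pairs], dtype=float)
    else:
        data = np.asarray(pairs, dtype=float)
    if len(data) < n_pairs:
        raise ValueError(f"need at least {n_pairs} pairs, got {len(data)}")
    out = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(len(data), size=n_pairs, replace=False)
        out[r] = sps.spearmanr(data[idx, 0], data[idx, 1]).statistic
    return out


def idr_over_median(durations: Iterable[float]) -> float:
    """Interdecile range over the median (dispersion quantifier).

    (90th − 10th percentile) / median, with linearly interpolated empirical
    quantiles; scale-invariant under d -> a·d.
    """
    d = np.asarray(list(durations), dtype=float)
    if len(d) < 10:
        raise ValueError("need at least 10 values for decile estimation")
    med = np.median(d)
    if med == 0:
        raise ValueError("median is zero; IDR/median undefined")
    q10, q90 = np.percentile(d, [10, 90])
    return float((q90 - q10) / med)


def mad(values: Iterable[float]) -> float:
    """Raw median absolute deviation (no consistency factor)."""
    v = np.asarray(list(values), dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def rz_score_conditions(durations_a: Iterable[float],
                        durations_b: Iterable[float]) -> float:
    """Robust effect size between two duration distributions.

    |median(A) − median(B)| / mean(MAD(A), MAD(B)).  A value near 1 means
    the medians differ by about one MAD — as large as the typical distance
    of a data point from its own median, i.e. a clear effect.
    """
    a = np.asarray(list(durations_a), dtype=float)
    b = np.asarray(list(durations_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    denom = (mad(a) + mad(b)) / 2
    if denom == 0:
        raise ValueError("average MAD is zero; rz-score undefined")
    return float(abs(np.median(a) - np.median(b)) / denom)


def estimated_rz_score(observed: float, null_counts: Sequence[float]) -> float:
    """Robust effect size of one division type against its permutation null.

    |observed − median(null)| / MAD(null), with the null counts taken from
    the permutation ensemble of the propagation test.
    """
    null_counts = np.asarray(null_counts, dtype=float)
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    m = mad(null_counts)
    if m == 0:
        raise ValueError("null MAD is zero; estimated rz-score undefined")
    return float(abs(observed - np.median(null_counts)) / m)


# Thin conveniences over stock tests quoted alongside the summaries; these
# delegate entirely to scipy.

def kruskal_wallis(*samples) -> tuple[float, float]:
    res = sps.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def levene(*samples) -> tuple[float, float]:
    res = sps.levene(*samples)
    return float(res.statistic), float(res.pvalue)


def condition_summary(durations_by_condition: dict[str, Sequence[float]],
                      reference: str | None = None):
    """Per-condition n / median / IDR-median / rz vs reference, as a DataFrame."""
    import pandas as pd

    if reference is None:
        reference = next(iter(durations_by_condition))
    ref = durations_by_condition[reference]
    rows = {}
    for name, d in durations_by_condition.items():
        d = np.asarray(list(d), dtype=float)
        rows[name] = {
            "n": len(d),
            "median_h": float(np.median(d)),
            "idr_over_median": idr_over_median(d) if len(d) >= 10 else np.nan,
            "rz_vs_" + reference: (
                0.0 if name == reference else rz_score_conditions(d, ref)
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
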