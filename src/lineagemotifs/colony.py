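"""Colony-shape and motility diagnostics on nuclear centroid tracks.

These metrics probe whether outlier cells could be explained by the local
environment rather than inheritance: the colony boundary (a concave hull of
all nuclear centroids per frame), each cell's periphery index (fraction of
its observed frames spent on that boundary), the colony circularity trend
over time, and per-cell median velocities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
import statsmodels.api as sm


@dataclass(frozen=True)
class ColonyFrame:
    """Nuclear centroid positions of one time point (hours, µm)."""

    time: float
    cell_ids: tuple[str, ...]
    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
            raise ValueError("points must be a non-empty (n, 2) array")
        if not np.all(np.isfinite(p)):
            raise ValueError("points must be finite")
        if len(self.cell_ids) != p.shape[0]:
            raise ValueError("cell_ids and points must align")


@dataclass(frozen=True)
class BoundaryResult:
    polygon: Optional[Polygon]  # None when the frame is degenerate
    boundary_ids: frozenset[str]


def colony_boundary(frame: ColonyFrame, shrink: float = 0.5) -> BoundaryResult:
    """Concave hull of a colony frame with a Matlab-style shrink factor.

    ``shrink=0`` gives the convex hull; ``shrink=1`` the tightest concave
    hull that still encloses all points in a single region (realized via
    shapely's concave hull with ratio ``1 − shrink``).  A cell is on the
    boundary when its centroid is a vertex of the hull polygon.  Fewer than
    three points, or collinear points, make every cell a boundary cell.
    """
    if not 0 <= shrink <= 1:
        raise ValueError("shrink must lie in [0, 1]")
    pts = np.asarray(frame.points, dtype=float)
    uniq = np.unique(pts, axis=0)
    degenerate = len(uniq) < 3 or _collinear(uniq)
    if degenerate:
        return BoundaryResult(None, frozenset(frame.cell_ids))
    hull = shapely.concave_hull(MultiPoint(pts), ratio=1.0 - shrink)
    if not isinstance(hull, Polygon):  # geometry collapsed; treat as degenerate
        return BoundaryResult(None, frozenset(frame.cell_ids))
    vertices = np.asarray(hull.exterior.coords)
    on_boundary = frozenset(
        cid for cid, p in zip(frame.cell_ids, pts)
        if np.any(np.all(np.isclose(vertices, p, atol=1e-9), axis=1))
    )
    return BoundaryResult(hull, on_boundary)


def _collinear(points: np.ndarray, tol: float = 1e-12) -> bool:
    p0 = points[0]
    d = points[1:] - p0
    cross = d[:, 0, None] * d[None, :, 1] - d[:, 1, None] * d[None, :, 0]
    return bool(np.all(np.abs(cross) < tol))


def boundary_sets(frames: Sequence[ColonyFrame],
                  shrink: float = 0.5) -> list[frozenset[str]]:
    """Per-frame boundary cell-id sets."""
    return [colony_boundary(f, shrink).boundary_ids for f in frames]


def periphery_index(cell_id: str, frames: Sequence[ColonyFrame],
                    boundaries: Sequence[frozenset[str]] | None = None,
                    shrink: float = 0.5) -> float:
    """Fraction of a cell's observed frames in which it sits on the boundary."""
    if boundaries is None:
        boundaries = boundary_sets(frames, shrink)
    observed = 0
    on = 0
    for frame, b in zip(frames, boundaries):
        if cell_id in frame.cell_ids:
            observed += 1
            on += cell_id in b
    if observed == 0:
        raise ValueError(f"cell {cell_id!r} observed in no frame")
    return on / observed


def circularity(polygon: Polygon) -> float:
    """4πA / P² — 1 for a disc, π/4 for a square, → 0 for elongated shapes."""
    if polygon.length == 0:
        raise ValueError("zero-perimeter polygon")
    return float(4 * np.pi * polygon.area / polygon.length ** 2)


def circularity_series(frames: Sequence[ColonyFrame],
                       shrink: float = 0.5) -> list[tuple[float, float]]:
    """(time, circularity) per frame; degenerate frames are skipped."""
    out = []
    for f in frames:
        b = colony_boundary(f, shrink)
        if b.polygon is not None and b.polygon.length > 0:
            out.append((f.time, circularity(b.polygon)))
    return out


@dataclass(frozen=True)
class RobustSlope:
    slope: float
    intercept: float
    converged: bool
    n_iter: int


def robust_slope(series: Sequence[tuple[float, float]],
                 max_iter: int = 50, tol: float = 1e-8) -> RobustSlope:
    """Robust linear trend via IRLS with Tukey bisquare weights (c = 4.685).

    Scale is re-estimated from the median absolute residual each iteration;
    gross outliers receive zero weight, so an exact line contaminated by a
    single aberrant point still recovers the true slope.
    """
    data = np.asarray(series, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("need at least 3 (t, y) points")
    t, y = data[:, 0], data[:, 1]
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    X = sm.add_constant(t)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit(maxiter=max_iter, tol=tol, scale_est="mad")
    n_iter = int(fit.fit_history.get("iteration", max_iter)) if hasattr(
        fit, "fit_history") else max_iter
    converged = n_iter < max_iter
    return RobustSlope(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                       converged=converged, n_iter=n_iter)


def median_velocity(track: Sequence[tuple[float, float, float]]) -> float:
    """Median per-interval speed (µm/h) of a (time, x, y) centroid track."""
    tr = np.asarray(track, dtype=float)
    if tr.ndim != 2 or tr.shape[0] < 2:
        raise ValueError("track needs at least 2 samples")
    dt = np.diff(tr[:, 0])
    if np.any(dt <= 0):
        raise ValueError("track times must be strictly increasing")
    step = np.linalg.norm(np.diff(tr[:, 1:], axis=0), axis=1)
    return float(np.median(step / dt))
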