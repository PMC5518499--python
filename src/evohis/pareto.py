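"""Nondominated filtering and front-quality metrics (GD and spacing).

Conventions: all objectives are maximized; generational distance uses
Euclidean nearest-neighbor distances from the obtained front Q to the
reference front P*; spacing uses Manhattan nearest-neighbor distances
within Q and divides the variance by |Q| (not |Q| - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyFrontError, FrontSizeError

__all__ = [
    "Front",
    "nondominated",
    "normalize_front",
    "generational_distance",
    "spacing",
    "build_reference_front",
]


@dataclass(frozen=True)
class Front:
    """A set of objective vectors (rows), all objectives to be maximized."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)

    def __len__(self):
        return self.points.shape[0]

    def deduplicated(self) -> "Front":
        return Front(np.unique(self.points, axis=0))


def _as_points(front_or_points) -> np.ndarray:
    if isinstance(front_or_points, Front):
        return front_or_points.points
    return np.atleast_2d(np.asarray(front_or_points, dtype=float))


def nondominated(points) -> Front:
    """Exact nondominated subset under maximization.

    A point is kept unless some other point is >= in every objective and
    > in at least one.  Duplicate points do not dominate each other.
    """
    pts = _as_points(points)
    if pts.shape[0] == 0:
        raise EmptyFrontError("nondominated requires at least one point")
    n = pts.shape[0]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        if np.any(ge & gt):
            keep[i] = False
    return Front(np.unique(pts[keep], axis=0))


def normalize_front(q, reference) -> tuple:
    """Min-max scale both fronts per objective using the union's ranges.

    Objectives constant over the union map to 0.
    """
    qp, rp = _as_points(q), _as_points(reference)
    union = np.vstack([qp, rp])
    if union.shape[0] == 0:
        raise EmptyFrontError("normalize_front requires at least one point")
    lo = union.min(axis=0)
    hi = union.max(axis=0)
    span = hi - lo
    constant = span == 0
    span = np.where(constant, 1.0, span)

    def _scale(p):
        out = (p - lo) / span
        out[:, constant] = 0.0
        return out

    return Front(_scale(qp)), Front(_scale(rp))


def generational_distance(q, pstar, p: float = 2.0) -> float:
    """GD = (sum_i d_i^p)^(1/p) / |Q| with d_i the Euclidean distance from
    the i-th member of Q to its nearest member of P*."""
    qp, rp = _as_points(q), _as_points(pstar)
    if qp.shape[0] == 0 or rp.shape[0] == 0:
        raise EmptyFrontError("generational_distance requires nonempty fronts")
    diffs = qp[:, None, :] - rp[None, :, :]
    d = np.sqrt((diffs**2).sum(axis=2)).min(axis=1)
    return float((d**p).sum() ** (1.0 / p) / qp.shape[0])


def spacing(q) -> float:
    """S = sqrt(mean((d_i - dbar)^2)) over Manhattan nearest-neighbor d_i."""
    qp = _as_points(q)
    m = qp.shape[0]
    if m < 2:
        raise FrontSizeError("spacing requires at least two front members")
    diffs = np.abs(qp[:, None, :] - qp[None, :, :]).sum(axis=2)
    np.fill_diagonal(diffs, np.inf)
    d = diffs.min(axis=1)
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


def build_reference_front(archives, mode: str = "nondominated") -> Front:
    """Reference front from one or more evaluation archives.

    ``archives`` is an iterable of point collections (arrays or Fronts).
    Default mode takes the nondominated set of the union; mode
    ``"per_objective_max"`` keeps, per objective, the union points
    attaining that objective's maximum.
    """
    stacks = [_as_points(a) for a in archives if _as_points(a).shape[0] > 0]
    if not stacks:
        raise EmptyFrontError("build_reference_front requires a nonempty union")
    union = np.vstack(stacks)
    if mode == "nondominated":
        return nondominated(union)
    if mode == "per_objective_max":
        keep = np.zeros(union.shape[0], dtype=bool)
        for m in range(union.shape[1]):
            keep |= union[:, m] == union[:, m].max()
        return Front(np.unique(union[keep], axis=0))
    raise ValueError(f"unknown reference-front mode {mode!r}")
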