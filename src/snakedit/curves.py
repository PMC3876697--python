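"""Hermite cubic curves and closed-contour geometry.

A contour is an ordered, closed polyline of continuous 2D points in pixel
coordinates (x = column, y = row, origin at the center of the top-left
pixel).  Hermite cubic segments — two endpoints plus two endpoint tangents
blended by four cubic basis polynomials — are the primitive used both to
turn a sparse set of user control points into a smooth closed boundary and
to re-fit a boundary after individual control points are moved.  Because
each segment depends only on its own endpoints and tangents (and the
tangents, in turn, only on immediate neighbours), moving one control point
reshapes only the nearby portion of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contour",
    "HermiteSegment",
    "SamplingParams",
    "hermite_basis",
    "evaluate_segment",
    "sample_segment",
    "estimate_tangents",
    "fit_closed_curve",
    "resample_uniform",
]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite point: {p!r}")
    return a


@dataclass(frozen=True)
class SamplingParams:
    """Parameter-step sampling of a Hermite segment.

    ``delta_s`` is the step of the curve parameter s in [0, 1]; sampling is
    endpoint-exclusive (s = 0, Δs, …, 1−Δs) so that chained segments share
    no duplicate joint points, giving exactly ``round(1/Δs)`` samples per
    segment — 10 at the default spacing.
    """

    delta_s: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.delta_s <= 0.5):
            raise ValueError(f"delta_s must be in (0, 0.5], got {self.delta_s}")

    @property
    def n_samples(self) -> int:
        return int(round(1.0 / self.delta_s))


@dataclass(frozen=True)
class HermiteSegment:
    """One cubic span: endpoints ``p0``, ``p1`` and endpoint tangents ``u0``, ``u1``."""

    p0: np.ndarray
    p1: np.ndarray
    u0: np.ndarray
    u1: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "u0", "u1"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))


def hermite_basis(s):
    """Evaluate the four Hermite basis polynomials at parameter ``s`` in [0, 1].

    Returns ``(h1, h2, h3, h4)`` with

        h1 = 2s³ − 3s² + 1     h2 = −2s³ + 3s²
        h3 = s³ − 2s² + s      h4 = s³ − s²

    ``h1`` and ``h2`` blend the endpoints (partition of unity, h1 + h2 = 1),
    ``h3`` and ``h4`` blend the endpoint tangents.  Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError("curve parameter s must lie in [0, 1]")
    s2 = s * s
    s3 = s2 * s
    h1 = 2.0 * s3 - 3.0 * s2 + 1.0
    h2 = -2.0 * s3 + 3.0 * s2
    h3 = s3 - 2.0 * s2 + s
    h4 = s3 - s2
    return h1, h2, h3, h4


def evaluate_segment(seg: HermiteSegment, s):
    """Point on the segment: P(s) = h1·P0 + h2·P1 + h3·u0 + h4·u1.

    Interpolates the endpoints exactly (P(0) = P0, P(1) = P1) and leaves /
    arrives along the endpoint tangents.  ``s`` may be a scalar (returns a
    2-vector) or an array of shape (n,) (returns (n, 2)).
    """
    h1, h2, h3, h4 = hermite_basis(s)
    h = np.stack([np.atleast_1d(h1), np.atleast_1d(h2),
                  np.atleast_1d(h3), np.atleast_1d(h4)], axis=1)
    ctrl = np.stack([seg.p0, seg.p1, seg.u0, seg.u1])
    out = h @ ctrl
    return out[0] if np.isscalar(s) or np.ndim(s) == 0 else out


def sample_segment(seg: HermiteSegment, sp: SamplingParams = SamplingParams()) -> np.ndarray:
    """Sample the segment at s = 0, Δs, …, 1−Δs (endpoint excluded).

    The end point is left to the next segment of a chained curve, so the
    concatenation of sampled segments never duplicates joints; the count is
    ``round(1/Δs)`` (10 points at the default Δs = 0.1).
    """
    n = sp.n_samples
    s = np.arange(n, dtype=float) / n
    return evaluate_segment(seg, s)


def estimate_tangents(control_points, closed: bool = True, tension: float = 0.5) -> np.ndarray:
    """Central-difference (Catmull–Rom) tangents for a chain of control points.

    The tangent at point k is ``tension · (P[k+1] − P[k−1])`` with periodic
    indexing when the chain is closed; open chains use one-sided differences
    (scaled to match the central rule on equally spaced points) at their
    ends.  Tension 0.5 is the classic Catmull–Rom choice.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("control points must have shape (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least 3 control points")
    if closed:
        return tension * (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0))
    tang = np.empty_like(pts)
    tang[1:-1] = tension * (pts[2:] - pts[:-2])
    tang[0] = tension * 2.0 * (pts[1] - pts[0])
    tang[-1] = tension * 2.0 * (pts[-1] - pts[-2])
    return tang


class Contour:
    """An ordered closed polyline of 2D points.

    Canonicalized to counterclockwise orientation (positive signed area in
    the (x, y) plane) on construction, keeping the first point first.
    Consecutive duplicate points are rejected.
    """

    __slots__ = ("points",)

    def __init__(self, points, closed: bool = True):
        if not closed:
            raise ValueError("only closed contours are supported")
        pts = np.array(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must have shape (n, 2)")
        if len(pts) < 3:
            raise ValueError("a closed contour needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour contains non-finite coordinates")
        seg = pts - np.roll(pts, 1, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError("contour has consecutive identical points")
        if self._signed_area(pts) < 0.0:
            pts = np.concatenate([pts[:1], pts[1:][::-1]])
        self.points = pts
        self.points.setflags(write=False)

    @staticmethod
    def _signed_area(pts: np.ndarray) -> float:
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def closed(self) -> bool:
        return True

    def __len__(self) -> int:
        return len(self.points)

    def __eq__(self, other) -> bool:
        return isinstance(other, Contour) and np.array_equal(self.points, other.points)

    @property
    def signed_area(self) -> float:
        return self._signed_area(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        """Length of each edge, edge i running from point i to point i+1 (wrapping)."""
        d = np.roll(self.points, -1, axis=0) - self.points
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths.sum())

    def arclength_point(self, fractions) -> np.ndarray:
        """Points at the given arc-length fractions (0 at the first point)."""
        fr = np.atleast_1d(np.asarray(fractions, dtype=float)) % 1.0
        cum = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        target = fr * cum[-1]
        xy = np.vstack([self.points, self.points[:1]])
        x = np.interp(target, cum, xy[:, 0])
        y = np.interp(target, cum, xy[:, 1])
        return np.column_stack([x, y])

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def fit_closed_curve(control_points, sp: SamplingParams = SamplingParams(),
                     tension: float = 0.5) -> Contour:
    """Fit a closed Hermite cubic curve through control points.

    Builds one segment per consecutive control-point pair (wrapping around),
    with Catmull–Rom tangents, samples each segment endpoint-exclusively and
    concatenates the samples into the replacement digital curve.  The result
    passes through every control point exactly and has
    ``len(control_points) × round(1/Δs)`` points.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 control points of shape (n, 2)")
    d = np.roll(pts, -1, axis=0) - pts
    if np.any(np.hypot(d[:, 0], d[:, 1]) == 0.0):
        raise ValueError("degenerate chain: consecutive control points coincide")
    tang = estimate_tangents(pts, closed=True, tension=tension)
    pieces = []
    for k in range(len(pts)):
        k1 = (k + 1) % len(pts)
        seg = HermiteSegment(pts[k], pts[k1], tang[k], tang[k1])
        pieces.append(sample_segment(seg, sp))
    return Contour(np.concatenate(pieces))


def resample_uniform(contour: Contour, n: int) -> Contour:
    """Resample a contour to ``n`` points at equal arc-length spacing.

    Points are placed along the polyline starting at the contour's first
    point; positions are linearly interpolated on the existing edges.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    fr = np.arange(n, dtype=float) / n
    return Contour(contour.arclength_point(fr))
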