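"""Hierarchical multiscale control-point meshes and scripted edits.

A control-point mesh is a set of uniformly arc-length-spaced points on a
contour.  Meshes form a hierarchy: level 1 has ``base_count`` points and
every subsequent level inserts the arc-length midpoints of the previous
one, doubling the count and halving the spacing.  Coarse levels let a user
correct large boundary errors by moving a few points; finer levels resolve
sharp detail.  Edits are applied declaratively through an
:class:`EditScript` (the scripted equivalent of dragging control points
with the mouse), after which the full closed Hermite curve is re-fitted
through the edited control points.  Because tangents are central
differences, an edit has local support: only curve segments incident to
the edited point or its immediate neighbours change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .curves import Contour, SamplingParams, fit_closed_curve

__all__ = [
    "ControlPointMesh",
    "Edit",
    "EditScript",
    "generate_mesh",
    "refine_mesh",
    "apply_edits",
    "hausdorff_distance",
    "mean_radial_error",
    "mean_contour_distance",
]


@dataclass(frozen=True)
class ControlPointMesh:
    """Uniformly spaced control points on a source contour at one hierarchy level."""

    level: int
    fractions: np.ndarray  # arc-length fractions in [0, 1) of each control point
    points: np.ndarray     # (m, 2) positions on the source contour
    spacing: float         # arc length between consecutive control points
    source: Contour

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Edit:
    """Move one control point, by absolute target or by displacement."""

    level: int
    index: int
    new_position: tuple[float, float] | None = None
    displacement: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.new_position is None) == (self.displacement is None):
            raise ValueError("exactly one of new_position / displacement is required")


@dataclass(frozen=True)
class EditScript:
    edits: tuple[Edit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edits", tuple(self.edits))
        keys = [(e.level, e.index) for e in self.edits]
        if len(set(keys)) != len(keys):
            raise ValueError("at most one edit per (level, index)")

    def __len__(self) -> int:
        return len(self.edits)


def generate_mesh(contour: Contour, level: int, base_count: int = 13) -> ControlPointMesh:
    """Place ``base_count · 2^(level−1)`` control points at uniform arc length.

    The mesh starts at the contour's first point; it cannot be finer than
    the contour itself.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if base_count < 4:
        raise ValueError("base_count must be >= 4")
    count = base_count * 2 ** (level - 1)
    if count > len(contour):
        raise ValueError(
            f"mesh of {count} control points exceeds contour resolution ({len(contour)} points)")
    fractions = np.arange(count, dtype=float) / count
    points = contour.arclength_point(fractions)
    spacing = contour.perimeter / count
    return ControlPointMesh(level=level, fractions=fractions, points=points,
                            spacing=spacing, source=contour)


def refine_mesh(mesh: ControlPointMesh) -> ControlPointMesh:
    """Insert the arc-length midpoint of every consecutive control-point pair.

    Original points are retained verbatim; the count doubles and the
    spacing halves, advancing the hierarchy one level.
    """
    count = 2 * len(mesh)
    if count > len(mesh.source):
        raise ValueError(
            f"refined mesh of {count} control points exceeds contour resolution "
            f"({len(mesh.source)} points)")
    nxt = np.roll(mesh.fractions, -1)
    nxt[-1] += 1.0
    mids = (mesh.fractions + nxt) / 2.0 % 1.0
    fractions = np.empty(count)
    fractions[0::2] = mesh.fractions
    fractions[1::2] = mids
    points = np.empty((count, 2))
    points[0::2] = mesh.points
    points[1::2] = mesh.source.arclength_point(mids)
    return ControlPointMesh(level=mesh.level + 1, fractions=fractions, points=points,
                            spacing=mesh.spacing / 2.0, source=mesh.source)


def apply_edits(mesh: ControlPointMesh, edits: EditScript,
                sp: SamplingParams = SamplingParams(), tension: float = 0.5) -> Contour:
    """Move the scripted control points and re-fit the closed Hermite curve.

    Every edit must reference this mesh's level and a valid index.  The
    returned contour interpolates all (edited) control points and replaces
    the former boundary; it is the source for any further mesh generation.
    """
    pts = mesh.points.copy()
    for e in edits.edits:
        if e.level != mesh.level:
            raise ValueError(f"edit {e} targets level {e.level}, mesh is level {mesh.level}")
        if not (0 <= e.index < len(pts)):
            raise ValueError(f"edit {e} has invalid control-point index for a "
                             f"{len(pts)}-point mesh")
        if e.new_position is not None:
            pts[e.index] = e.new_position
        else:
            pts[e.index] = pts[e.index] + np.asarray(e.displacement, dtype=float)
    return fit_closed_curve(pts, sp, tension)


def hausdorff_distance(a: Contour, b: Contour) -> float:
    """Symmetric Hausdorff distance (pixels) between two contours' point sets."""
    pa, pb = a.points, b.points
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def mean_radial_error(contour: Contour, center, radius: float) -> float:
    """Mean absolute deviation of point radii from a reference circle (pixels)."""
    c = np.asarray(center, dtype=float)
    r = np.hypot(*(contour.points - c).T)
    return float(np.abs(r - radius).mean())


def mean_contour_distance(a: Contour, b: Contour) -> float:
    """Mean distance from each point of ``a`` to the nearest point of ``b``."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(b.points).query(a.points)
    return float(d.mean())
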