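"""Synthetic test images with analytically known boundaries.

Phantoms stand in for clinical CT/MR/US slices: a bright object on a darker
background, with a Gaussian-blurred edge (low contrast / partial-volume
effect) and additive Gaussian pixel noise.  The disk exercises the snake's
ordinary operating regime, the star its known failure mode on sharp
high-curvature boundaries, and the cone volume slice-to-slice tracking of
a slowly changing cross-section.  Every phantom carries its ground-truth
boundary as a dense contour and a ``meta`` record from which it can be
regenerated bit for bit.

Shapes are rasterized with half-pixel anti-aliasing: pixel intensity ramps
linearly across one pixel of signed distance to the true boundary.  This
keeps the noiseless image rotation-equivariant to high accuracy, so
symmetry and ground-truth checks are not polluted by raster jaggies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage

from .curves import Contour

__all__ = ["Phantom", "make_disk", "make_star", "make_cone_volume"]

TRUTH_POINTS = 720


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    truth: Contour
    meta: dict


def _check_geometry(size: int, extent: float, blur: float) -> None:
    if size < 16:
        raise ValueError("image size must be at least 16")
    if extent + 3.0 * blur >= size / 2.0:
        raise ValueError(
            f"shape of extent {extent} with blur {blur} does not fit in a {size}×{size} image")


def _finish(coverage: np.ndarray, fg: float, bg: float, blur: float,
            noise: float, seed: int) -> np.ndarray:
    img = bg + (fg - bg) * coverage
    if blur > 0:
        img = ndimage.gaussian_filter(img, blur, mode="nearest")
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, img.shape)
    return np.clip(img, 0.0, 1.0)


def make_disk(size: int = 256, center=None, radius: float = 60.0,
              fg: float = 0.8, bg: float = 0.2, blur: float = 2.0,
              noise: float = 0.0, seed: int = 0) -> Phantom:
    """Blurred, noisy disk with a 720-point circle as ground truth."""
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    cx, cy = float(center[0]), float(center[1])
    _check_geometry(size, radius, blur)
    yy, xx = np.mgrid[0:size, 0:size]
    d = radius - np.hypot(xx - cx, yy - cy)  # signed distance, positive inside
    coverage = np.clip(d + 0.5, 0.0, 1.0)
    image = _finish(coverage, fg, bg, blur, noise, seed)
    theta = 2.0 * np.pi * np.arange(TRUTH_POINTS) / TRUTH_POINTS
    truth = Contour(np.column_stack([cx + radius * np.cos(theta),
                                     cy + radius * np.sin(theta)]))
    meta = {"shape": "disk", "size": size, "center": [cx, cy], "radius": radius,
            "fg": fg, "bg": bg, "blur": blur, "noise": noise, "seed": seed}
    return Phantom(image=image, truth=truth, meta=meta)


def star_vertices(center, r_outer: float, r_inner: float, n_tips: int) -> np.ndarray:
    """Vertices of an ``n_tips``-pointed star, tips first; first tip points up (−y)."""
    cx, cy = float(center[0]), float(center[1])
    k = np.arange(2 * n_tips)
    ang = -np.pi / 2.0 + np.pi * k / n_tips
    r = np.where(k % 2 == 0, r_outer, r_inner)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _polygon_coverage(size: int, vertices: np.ndarray) -> np.ndarray:
    poly = shapely.Polygon(vertices)
    yy, xx = np.mgrid[0:size, 0:size]
    pts = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
    dist = shapely.distance(pts, poly.exterior).reshape(size, size)
    inside = shapely.contains_xy(poly, xx.ravel().astype(float),
                                 yy.ravel().astype(float)).reshape(size, size)
    signed = np.where(inside, dist, -dist)
    return np.clip(signed + 0.5, 0.0, 1.0)


def _sample_polygon(vertices: np.ndarray, n_points: int) -> np.ndarray:
    """Dense, even per-edge sampling of a closed polygon; vertices retained."""
    m = len(vertices)
    per_edge = max(1, n_points // m)
    pts = []
    for i in range(m):
        a, b = vertices[i], vertices[(i + 1) % m]
        t = np.arange(per_edge, dtype=float)[:, None] / per_edge
        pts.append(a + t * (b - a))
    return np.concatenate(pts)


def make_star(size: int = 256, center=None, r_outer: float = 80.0,
              r_inner: float = 45.0, n_tips: int = 5, fg: float = 0.8,
              bg: float = 0.2, blur: float = 2.0, noise: float = 0.0,
              seed: int = 0) -> Phantom:
    """Blurred, noisy star polygon — a sharp high-curvature boundary.

    With ``r_inner == r_outer`` the star degenerates to a regular
    ``2·n_tips``-gon.
    """
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    if not (0 < r_inner <= r_outer):
        raise ValueError("need 0 < r_inner <= r_outer")
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    _check_geometry(size, r_outer, blur)
    verts = star_vertices(center, r_outer, r_inner, n_tips)
    image = _finish(_polygon_coverage(size, verts), fg, bg, blur, noise, seed)
    truth = Contour(_sample_polygon(verts, TRUTH_POINTS))
    meta = {"shape": "star", "size": size, "center": [float(center[0]), float(center[1])],
            "r_outer": r_outer, "r_inner": r_inner, "n_tips": n_tips,
            "fg": fg, "bg": bg, "blur": blur, "noise": noise, "seed": seed}
    return Phantom(image=image, truth=truth, meta=meta)


def make_cone_volume(size: int = 256, n_slices: int = 5, r_start: float = 60.0,
                     r_end: float = 52.0, center=None, fg: float = 0.8,
                     bg: float = 0.2, blur: float = 2.0, noise: float = 0.0,
                     seed: int = 0):
    """Stack of disk slices with linearly interpolated radius.

    Slice i uses seed ``seed + i`` so noise is fresh per slice but the whole
    volume is reproducible.  Returns ``(volume, truths)`` where ``volume``
    is a :class:`~snakedit.propagation.Volume` and ``truths`` the per-slice
    ground-truth contours.
    """
    from .propagation import Volume

    if n_slices < 1:
        raise ValueError("need at least one slice")
    radii = (np.full(1, float(r_start)) if n_slices == 1
             else np.linspace(r_start, r_end, n_slices))
    slices, truths = [], []
    for i, r in enumerate(radii):
        ph = make_disk(size=size, center=center, radius=float(r), fg=fg, bg=bg,
                       blur=blur, noise=noise, seed=seed + i)
        slices.append(ph.image)
        truths.append(ph.truth)
    vol = Volume(slices=slices, ids=[f"slice{i:03d}" for i in range(n_slices)])
    return vol, truths
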