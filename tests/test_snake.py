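"""External/internal energies and semi-implicit snake evolution."""

import numpy as np
import pytest
from scipy import ndimage

import snakedit as sk
from snakedit.snake import internal_operator_column, semi_implicit_step
from .conftest import CENTER, circle_contour


# ---------------------------------------------------------------------------
# independent oracles

def oracle_external_energy(image, sigma):
    """Separable Gaussian then central differences, replicated borders."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-x * x / (2.0 * sigma * sigma))
    k /= k.sum()

    def smooth_axis(a, axis):
        return ndimage.correlate1d(a, k, axis=axis, mode="nearest")

    def ddx(a):
        # correlation kernel: out[i] = −0.5·a[i−1] + 0.5·a[i+1]
        return ndimage.correlate1d(a, [-0.5, 0.0, 0.5], axis=1, mode="nearest")

    def ddy(a):
        return ndimage.correlate1d(a, [-0.5, 0.0, 0.5], axis=0, mode="nearest")

    sm = smooth_axis(smooth_axis(image, 0), 1)
    e = -(ddx(sm) ** 2 + ddy(sm) ** 2)
    return e, -ddx(e), -ddy(e)


def oracle_internal_energy(points, alpha, beta):
    n = len(points)
    total = 0.0
    for i in range(n):
        d1 = points[(i + 1) % n] - points[i]
        d2 = points[(i + 1) % n] - 2 * points[i] + points[(i - 1) % n]
        total += 0.5 * (alpha * (d1 @ d1) + beta * (d2 @ d2))
    return total / n


def oracle_dense_step(points, field, params):
    """One semi-implicit step via an explicitly assembled cyclic pentadiagonal solve."""
    n = len(points)
    A = np.zeros((n, n))
    a, b = params.alpha, params.beta
    for i in range(n):
        A[i, i] = 2 * a + 6 * b
        A[i, (i - 1) % n] += -(a + 4 * b)
        A[i, (i + 1) % n] += -(a + 4 * b)
        A[i, (i - 2) % n] += b
        A[i, (i + 2) % n] += b
    M = np.eye(n) + params.tau * A
    x = np.clip(points[:, 0], 0, field.shape[1] - 1)
    y = np.clip(points[:, 1], 0, field.shape[0] - 1)
    fx = ndimage.map_coordinates(field.fx, [y, x], order=1, mode="nearest")
    fy = ndimage.map_coordinates(field.fy, [y, x], order=1, mode="nearest")
    rhs = points + params.tau * params.force_scale * np.column_stack([fx, fy])
    return np.linalg.solve(M, rhs)


# ---------------------------------------------------------------------------
# external energy

def test_constant_image_zero_field():
    field = sk.external_energy(np.full((32, 32), 0.7), 2.0)
    assert np.all(field.e_ext == 0)
    assert np.all(field.fx == 0) and np.all(field.fy == 0)


def test_external_energy_nonpositive_and_shapes(disk_field, disk_phantom):
    assert np.all(disk_field.e_ext <= 0)
    assert disk_field.e_ext.shape == disk_phantom.image.shape
    assert disk_field.fx.shape == disk_field.fy.shape == disk_field.e_ext.shape


def test_step_edge_energy_minimum_at_edge():
    img = np.zeros((32, 48))
    img[:, 24:] = 1.0
    field = sk.external_energy(img, 1.5)
    for row in (10, 16, 21):
        col = int(np.argmin(field.e_ext[row]))
        assert abs(col - 24) <= 1  # edge between columns 23 and 24


def test_external_energy_matches_oracle():
    rng = np.random.default_rng(5)
    for sigma in (1.0, 2.0):
        img = rng.random((32, 32))
        field = sk.external_energy(img, sigma)
        e, fx, fy = oracle_external_energy(img, sigma)
        assert np.abs(field.e_ext - e).max() < 1e-10
        assert np.abs(field.fx - fx).max() < 1e-10
        assert np.abs(field.fy - fy).max() < 1e-10


def test_external_energy_rejects_bad_input():
    with pytest.raises(ValueError):
        sk.external_energy(np.full((8, 8), 0.5), 2.0)
    bad = np.full((32, 32), 0.5)
    bad[3, 3] = np.nan
    with pytest.raises(ValueError):
        sk.external_energy(bad, 2.0)


# ---------------------------------------------------------------------------
# internal and total energy

def test_internal_energy_straight_spans_have_zero_rigidity():
    xs = np.arange(30.0)
    top = np.column_stack([xs, np.zeros(30)])
    bottom = np.column_stack([xs[::-1], np.full(30, 1.0)])
    rect = sk.Contour(np.vstack([top, bottom]))
    p = rect.points
    d2 = np.roll(p, -1, axis=0) - 2 * p + np.roll(p, 1, axis=0)
    interior = np.hypot(*d2.T)
    assert np.count_nonzero(interior > 1e-12) <= 6  # only the corner neighbourhoods bend


def test_internal_energy_regular_polygon_and_scaling():
    c = circle_contour(10.0, n=16, center=(0, 0))
    chord = np.hypot(*(c.points[1] - c.points[0]))
    val = sk.internal_energy(c, alpha=1.0, beta=0.0)
    assert val == pytest.approx(0.5 * chord**2, rel=1e-12)
    scaled = sk.Contour(c.points * np.sqrt(2.0))
    assert sk.internal_energy(scaled, 1.0, 0.0) == pytest.approx(2 * val, rel=1e-12)


def test_internal_energy_matches_loop_oracle():
    rng = np.random.default_rng(9)
    for _ in range(5):
        pts = circle_contour(40, 32).points + rng.normal(0, 3, (32, 2))
        c = sk.Contour(pts)
        assert sk.internal_energy(c, 0.3, 1.7) == pytest.approx(
            oracle_internal_energy(c.points, 0.3, 1.7), abs=1e-12)


def test_snake_energy_decomposition(disk_field):
    c = circle_contour(40.0, 48)
    params = sk.SnakeParams()
    flat = sk.external_energy(np.full((256, 256), 0.5), 2.0)
    assert sk.snake_energy(c, flat, params) == pytest.approx(
        sk.internal_energy(c, params.alpha, params.beta))
    p0 = sk.SnakeParams(alpha=0.0, beta=0.0)
    ext = ndimage.map_coordinates(disk_field.e_ext,
                                  [c.points[:, 1], c.points[:, 0]], order=1)
    assert sk.snake_energy(c, disk_field, p0) == pytest.approx(ext.mean())


def test_bilinear_sampling_exact_on_grid(disk_field):
    pts = np.array([[10.0, 20.0], [100.0, 200.0], [255.0, 0.0]])
    got = ndimage.map_coordinates(disk_field.e_ext, [pts[:, 1], pts[:, 0]],
                                  order=1, mode="nearest")
    expect = disk_field.e_ext[pts[:, 1].astype(int), pts[:, 0].astype(int)]
    assert got == pytest.approx(expect, abs=0)


# ---------------------------------------------------------------------------
# evolution

def test_semi_implicit_step_matches_dense_oracle(disk_field):
    params = sk.SnakeParams()
    for n in (16, 48, 64):
        pts = circle_contour(66.0, n).points
        got = semi_implicit_step(pts, disk_field, params)
        want = oracle_dense_step(pts, disk_field, params)
        assert np.abs(got - want).max() < 1e-9


def test_operator_annihilates_constants():
    c = internal_operator_column(32, 0.37, 1.21)
    assert c.sum() == pytest.approx(0.0, abs=1e-12)


def test_step_preserves_centroid_without_force():
    flat = sk.external_energy(np.full((256, 256), 0.5), 2.0)
    params = sk.SnakeParams(alpha=0.3, beta=0.0)
    pts = circle_contour(60.0, 40).points
    new = semi_implicit_step(pts, flat, params)
    assert np.abs(new.mean(axis=0) - pts.mean(axis=0)).max() < 1e-9


def test_elasticity_shrinks_perimeter():
    flat = sk.external_energy(np.full((256, 256), 0.5), 2.0)
    params = sk.SnakeParams(alpha=0.5, beta=0.0)
    pts = circle_contour(60.0, 40).points
    perim = sk.Contour(pts).perimeter
    for _ in range(10):
        pts = semi_implicit_step(pts, flat, params)
        new_perim = sk.Contour(pts).perimeter
        assert new_perim < perim
        perim = new_perim


def test_disk_recovery_near_init(disk_field):
    res = sk.evolve(circle_contour(66.0), disk_field, sk.SnakeParams())
    assert res.converged
    assert res.n_iter <= 50
    assert sk.mean_radial_error(res.contour, CENTER, 60.0) < 1.5
    assert len(res.energy_trace) == res.n_iter + 1
    assert res.energy_trace[-1] < res.energy_trace[0]


def test_far_init_fails(disk_field):
    res = sk.evolve(circle_contour(110.0), disk_field, sk.SnakeParams())
    assert sk.mean_radial_error(res.contour, CENTER, 60.0) > 5.0


def test_fixed_point_idempotence(disk_field):
    params = sk.SnakeParams()
    res = sk.evolve(circle_contour(66.0), disk_field, params)
    again = sk.evolve(res.contour, disk_field, params)
    assert again.converged and again.n_iter == 1


def test_evolve_requires_enough_points(disk_field):
    with pytest.raises(ValueError):
        sk.evolve(circle_contour(60.0, n=6), disk_field, sk.SnakeParams())


def test_divergence_guard():
    # a strong constant outward force field pushes the contour out of frame
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    img = ((xx - 32) ** 2 + (yy - 32) ** 2) / 5000.0  # steep radial ramp
    field = sk.external_energy(np.clip(img, 0, 1), 1.0)
    big = sk.SnakeParams(alpha=0.0, beta=0.0, force_scale=1e7, max_iter=50, tol=0.0)
    with pytest.raises(sk.SnakeDivergenceError):
        sk.evolve(circle_contour(20.0, 32, center=(32, 32)), field, big)


def test_snake_params_validation():
    with pytest.raises(ValueError):
        sk.SnakeParams(alpha=-1)
    with pytest.raises(ValueError):
        sk.SnakeParams(sigma=0)
    with pytest.raises(ValueError):
        sk.SnakeParams(max_iter=0)
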