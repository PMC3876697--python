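import numpy as np
import pytest

import snakedit as sk

CENTER = (127.5, 127.5)


def circle_contour(radius: float, n: int = 48, center=CENTER) -> sk.Contour:
    t = 2.0 * np.pi * np.arange(n) / n
    return sk.Contour(np.column_stack([center[0] + radius * np.cos(t),
                                       center[1] + radius * np.sin(t)]))


@pytest.fixture(scope="session")
def disk_phantom():
    return sk.make_disk()  # radius 60, blur 2, noiseless, 256²


@pytest.fixture(scope="session")
def disk_field(disk_phantom):
    return sk.external_energy(disk_phantom.image, 2.0)


@pytest.fixture(scope="session")
def star_phantom():
    return sk.make_star()  # 5 tips, r_outer 80, r_inner 45, blur 2


@pytest.fixture(scope="session")
def star_field(star_phantom):
    return sk.external_energy(star_phantom.image, 2.0)


@pytest.fixture(scope="session")
def star_snake(star_phantom, star_field):
    """Converged snake on the star, started from the 5%-dilated truth."""
    c = np.asarray(CENTER)
    init = sk.resample_uniform(
        sk.Contour(c + 1.05 * (star_phantom.truth.points - c)), 144)
    return sk.evolve(init, star_field, sk.SnakeParams())
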