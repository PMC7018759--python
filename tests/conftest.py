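import numpy as np
import pytest

from octaline.data import LumenContour
from octaline.phantom import Lesion, PhantomConfig, generate_pullback


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def circle_contour(radius: float, n_theta: int = 496) -> LumenContour:
    return LumenContour(boundary_r=np.full(n_theta, float(radius)))


def ellipse_contour(a: float, b: float, n_theta: int = 496, phase: float = 0.0) -> LumenContour:
    """Boundary r(θ) of an origin-centered ellipse with semi-axes a, b."""
    t = 2 * np.pi * np.arange(n_theta) / n_theta - phase
    r = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    return LumenContour(boundary_r=r)


@pytest.fixture(scope="session")
def small_phantom():
    """Small speckled phantom with one calcium and one lipid lesion."""
    cfg = PhantomConfig(
        n_frames=8,
        n_r=360,
        n_theta=96,
        lumen_radius_px=100.0,
        guidewire_width=6,
        guidewire_center_theta=80,
        wall_depth_px=230,
        lesions=[
            Lesion("calcium", theta_start=10, theta_extent=20, z_start=1, z_extent=5),
            Lesion("lipid", theta_start=45, theta_extent=18, z_start=2, z_extent=6),
        ],
        voi_id="fixture",
        seed=7,
    )
    pullback, masks, contours, labels = generate_pullback(cfg)
    return cfg, pullback, masks, contours, labels
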