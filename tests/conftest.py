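import numpy as np
import pytest

from secflow import (
    BendSpec,
    Centerline,
    FrenetFrameSet,
    HelixSpec,
    make_helix_centerline,
    make_multibend_centerline,
)
from secflow.sections import make_slices


@pytest.fixture
def helix():
    """Helix a=3, b=4 mm: kappa=0.12, tau=0.16 mm^-1 in closed form."""
    return make_helix_centerline(HelixSpec(a=3.0, b=4.0, arc_length=80.0, spacing=0.15))


@pytest.fixture
def circle():
    """Planar circle of radius 4 mm: kappa=0.25 mm^-1, tau=0."""
    return make_helix_centerline(HelixSpec(a=4.0, b=0.0, arc_length=20.0, spacing=0.15))


@pytest.fixture
def multibend():
    """Three-bend fixture with ground-truth landmarks in metadata."""
    bends = [BendSpec(0.25, 15.0, 25.0), BendSpec(0.20, 15.0, -30.0),
             BendSpec(0.30, 15.0, 20.0)]
    return make_multibend_centerline(bends, spacing=0.15, seed=11)


def straight_tube(n_points: int = 41, radius: float = 2.0, spacing: float = 0.5):
    """Straight tube along z with hand-built (valid) frames.

    A straight centerline has zero curvature so discrete Frenet frames
    are undefined; tests that need a trivial geometry supply this
    constant frame instead.
    """
    z = spacing * np.arange(n_points)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    c = Centerline(pts, radius=np.full(n_points, radius))
    n = len(c)
    frames = FrenetFrameSet(
        abscissa=c.abscissa.copy(),
        t=np.tile([0.0, 0.0, 1.0], (n, 1)),
        n=np.tile([1.0, 0.0, 0.0], (n, 1)),
        b=np.tile([0.0, 1.0, 0.0], (n, 1)),
        kappa=np.zeros(n),
        tau=np.zeros(n),
        valid=np.ones(n, dtype=bool),
    )
    return c, frames


@pytest.fixture
def tube_slice():
    """One fully-masked slice of the straight tube (16 x 64 polar grid)."""
    c, frames = straight_tube()
    s = make_slices(c, frames, n_rho=16, n_theta=64, stride=len(c) // 2)[1]
    s.mask = np.ones(len(s.points), dtype=bool)
    return s


def poiseuille(slice_, u_peak: float = 0.5):
    """Assign an axisymmetric parabolic axial field directly to a slice."""
    v_ax = u_peak * (1.0 - slice_.rho**2)
    slice_.v = v_ax[:, None] * slice_.t
    slice_.mask = np.ones(len(slice_.points), dtype=bool)
    return slice_
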