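import numpy as np
import pytest

from shapesect import Contour


@pytest.fixture
def unit_square():
    return Contour([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def l_hexagon():
    # L-shape decomposable into rectangles [0,2]x[0,1] and [0,1]x[1,2]
    return Contour([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]])


def make_circle(radius=1.0, n=1000, center=(0.0, 0.0), ccw=True, start_top=False):
    """Uniformly sampled circle polygon."""
    th = 2 * np.pi * np.arange(n) / n
    if start_top:
        th = th + np.pi / 2
    if not ccw:
        th = -th
    return Contour(np.column_stack([
        center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)
    ]))


@pytest.fixture
def circle_factory():
    return make_circle


def make_stadium(m=200):
    """Two unit-radius semicircles joined by straight edges of length 2."""
    xs = np.linspace(-1, 1, m, endpoint=False)
    bottom = np.column_stack([xs, -np.ones(m)])
    ang = np.linspace(-np.pi / 2, np.pi / 2, m, endpoint=False)
    right = np.column_stack([1 + np.cos(ang), np.sin(ang)])
    top = np.column_stack([np.linspace(1, -1, m, endpoint=False), np.ones(m)])
    ang2 = np.linspace(np.pi / 2, 3 * np.pi / 2, m, endpoint=False)
    left = np.column_stack([-1 + np.cos(ang2), np.sin(ang2)])
    return Contour(np.vstack([bottom, right, top, left]))


@pytest.fixture
def stadium():
    return make_stadium()


def relative_l2(a: Contour, b: Contour) -> float:
    """Section distance normalized by the r.m.s. vertex norm of ``a``."""
    from shapesect import section_distance

    scale = np.sqrt(np.mean(np.sum(a.vertices**2, axis=1)))
    return section_distance(a, b) / scale
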