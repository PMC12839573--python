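"""Standardization of contours over the finite-dimensional shape-preserving groups.

Five steps, applied in a fixed order: travel direction (counterclockwise),
starting point (vertex of largest vertical component), scale (unit length or
unit enclosed area), position (a designated center at the origin) and rotation
(principal ellipse axes, or the tip-to-centroid segment made vertical).

The composed :func:`normalize` iterates the five steps to their joint fixed
point.  A single pass is not a projection: the starting-point rule reads the
vertical coordinate, which the rotation step subsequently changes.  Iterating
converges (the height of the chosen start vertex above the area centroid
strictly increases whenever the choice changes) and makes the composition
idempotent and invariant under rotations of the input, which is what a
canonical representative requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import (
    Contour,
    area_centroid,
    contour_centroid,
    polyline_length,
    signed_area,
)
from .errors import AmbiguousEllipseError, DegenerateAreaError, ShapesectError

__all__ = [
    "NormConfig",
    "standardize_direction",
    "standardize_start",
    "standardize_scale",
    "standardize_position",
    "standardize_rotation",
    "normalize",
]

_DIRECTION = ("ccw", "off")
_START = ("max_vertical", "off")
_SCALE = ("unit_length", "unit_area", "off")
_POSITION = ("start_origin", "contour_centroid", "area_centroid", "off")
_ROTATION = ("ellipse_axes", "tip_vertical", "off")


@dataclass(frozen=True)
class NormConfig:
    """Which standardization strategy to use for each group factor.

    The defaults are the strategies that behave best on leaf-outline data:
    counterclockwise travel, start at the topmost point (the leaf tip), unit
    contour length, area centroid at the origin, and the tip-to-centroid
    segment vertical.
    """

    direction: str = "ccw"
    start: str = "max_vertical"
    scale: str = "unit_length"
    position: str = "area_centroid"
    rotation: str = "tip_vertical"

    def __post_init__(self) -> None:
        for value, allowed, key in (
            (self.direction, _DIRECTION, "direction"),
            (self.start, _START, "start"),
            (self.scale, _SCALE, "scale"),
            (self.position, _POSITION, "position"),
            (self.rotation, _ROTATION, "rotation"),
        ):
            if value not in allowed:
                raise ShapesectError(f"unknown {key} strategy {value!r}; allowed: {allowed}")

    @staticmethod
    def off() -> "NormConfig":
        """Configuration with every step disabled (raw contours)."""
        return NormConfig("off", "off", "off", "off", "off")

    @staticmethod
    def from_dict(d: dict) -> "NormConfig":
        return NormConfig(**{k: d[k] for k in
                             ("direction", "start", "scale", "position", "rotation") if k in d})

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "start": self.start,
            "scale": self.scale,
            "position": self.position,
            "rotation": self.rotation,
        }


def standardize_direction(c: Contour) -> Contour:
    """Make the contour travel counterclockwise (positive signed area).

    Clockwise inputs get their vertex order reversed with vertex 0 kept fixed;
    counterclockwise inputs are returned unchanged.
    """
    a = signed_area(c)
    scale = max(polyline_length(c), 1.0)
    if abs(a) < 1e-12 * scale**2:
        raise DegenerateAreaError("cannot orient a contour with zero enclosed area")
    if a > 0:
        return c
    v = c.vertices
    return c.with_vertices(np.vstack([v[:1], v[:0:-1]]))


def standardize_start(c: Contour) -> Contour:
    """Roll the vertex list so vertex 0 has the largest vertical component.

    Ties broken by smallest x, then smallest original index.
    """
    v = c.vertices
    y, x = v[:, 1], v[:, 0]
    ymax = y.max()
    cand = np.flatnonzero(y == ymax)
    cand = cand[x[cand] == x[cand].min()]
    idx = int(cand[0])
    if idx == 0:
        return c
    return c.with_vertices(np.roll(v, -idx, axis=0))


def standardize_scale(c: Contour, mode: str = "unit_length") -> Contour:
    """Scale about the origin to unit perimeter or unit enclosed area."""
    if mode == "unit_length":
        factor = 1.0 / polyline_length(c)
    elif mode == "unit_area":
        a = abs(signed_area(c))
        if a < 1e-30:
            raise DegenerateAreaError("cannot scale a zero-area contour to unit area")
        factor = 1.0 / np.sqrt(a)
    else:
        raise ShapesectError(f"unknown scale mode {mode!r}")
    return c.with_vertices(c.vertices * factor)


def standardize_position(c: Contour, mode: str = "area_centroid") -> Contour:
    """Translate so a designated center lands at the origin."""
    if mode == "start_origin":
        center = c.vertices[0]
    elif mode == "contour_centroid":
        center = contour_centroid(c)
    elif mode == "area_centroid":
        center = area_centroid(c)
    else:
        raise ShapesectError(f"unknown position mode {mode!r}")
    return c.with_vertices(c.vertices - center)


def _rotate_about(v: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    r = np.array([[ca, -sa], [sa, ca]])
    return (v - center) @ r.T + center


def _boundary_covariance(c: Contour) -> np.ndarray:
    """Arc-length-weighted second central moment of the boundary points."""
    v = c.vertices
    nxt = np.vstack([v[1:], v[:1]])
    lens = np.linalg.norm(nxt - v, axis=1)
    mids = 0.5 * (v + nxt)
    center = (mids * lens[:, None]).sum(axis=0) / lens.sum()
    d = mids - center
    return (d[:, :, None] * d[:, None, :] * lens[:, None, None]).sum(axis=0) / lens.sum()


def standardize_rotation(c: Contour, mode: str = "tip_vertical") -> Contour:
    """Standardize orientation in space.

    ``ellipse_axes``: rotate (about the area centroid) so the approximating
    ellipse of the boundary has its minor axis horizontal and major axis
    vertical; the residual half-turn ambiguity is fixed by requiring the
    boundary point farthest from the centroid to have non-negative y (then
    non-negative x).

    ``tip_vertical``: rotate about the area centroid so the segment from the
    centroid to vertex 0 (the tip) points along +y.
    """
    center = area_centroid(c)
    if mode == "tip_vertical":
        d = c.vertices[0] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12 * max(polyline_length(c), 1.0):
            raise ShapesectError("tip coincides with the area centroid; rotation undefined")
        angle = np.pi / 2 - np.arctan2(d[1], d[0])
        return c.with_vertices(_rotate_about(c.vertices, center, angle))
    if mode != "ellipse_axes":
        raise ShapesectError(f"unknown rotation mode {mode!r}")
    cov = _boundary_covariance(c)
    evals, evecs = np.linalg.eigh(cov)
    if (evals[1] - evals[0]) <= 1e-9 * max(evals[1], 1e-300):
        raise AmbiguousEllipseError("principal moments are equal; ellipse orientation undefined")
    major = evecs[:, 1]
    # proper rotation sending minor -> x, major -> y
    minor = np.array([major[1], -major[0]])
    r = np.vstack([minor, major])
    out = (c.vertices - center) @ r.T + center
    ctr = contour_centroid(Contour(out))
    far = out[np.argmax(np.linalg.norm(out - ctr, axis=1))] - ctr
    if far[1] < -1e-12 or (abs(far[1]) <= 1e-12 and far[0] < 0):
        out = _rotate_about(out, center, np.pi)
    return c.with_vertices(out)


def _start_farthest(c: Contour) -> Contour:
    """Roll so vertex 0 is the vertex farthest from the area centroid.

    This is the stable fixed point of composing the max-vertical start rule
    with the tip-vertical rotation: once the farthest vertex points up it is
    the max-y vertex (every height is bounded by the distance to the
    centroid), so the max-vertical postcondition holds there — and unlike the
    raw max-y pick, the rule does not depend on how the input is rotated.
    Ties broken by smallest index.
    """
    d = np.linalg.norm(c.vertices - area_centroid(c), axis=1)
    idx = int(np.argmax(d))
    if idx == 0:
        return c
    return c.with_vertices(np.roll(c.vertices, -idx, axis=0))


def _one_pass(c: Contour, cfg: NormConfig) -> Contour:
    if cfg.direction == "ccw":
        c = standardize_direction(c)
    if cfg.start == "max_vertical":
        if cfg.rotation == "tip_vertical":
            c = _start_farthest(c)
        else:
            c = standardize_start(c)
    if cfg.scale != "off":
        c = standardize_scale(c, cfg.scale)
    if cfg.position != "off":
        c = standardize_position(c, cfg.position)
    if cfg.rotation != "off":
        c = standardize_rotation(c, cfg.rotation)
    return c


def normalize(c: Contour, cfg: NormConfig | None = None, max_iter: int = 100) -> Contour:
    """Apply the enabled standardization steps in their fixed order, iterated
    to the joint fixed point.

    Idempotent: normalizing a normalized contour returns it unchanged (up to
    floating-point round-off).
    """
    if cfg is None:
        cfg = NormConfig()
    prev = None
    for _ in range(max_iter):
        c = _one_pass(c, cfg)
        v = c.vertices
        if prev is not None and prev.shape == v.shape:
            scale = max(np.abs(v).max(), 1e-30)
            if np.max(np.abs(v - prev)) <= 1e-12 * scale:
                break
        prev = v
    return c
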