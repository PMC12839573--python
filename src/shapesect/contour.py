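"""Discrete differential geometry of closed planar polylines.

A contour is an ordered list of N planar vertices, implicitly closed (vertex
N-1 connects back to vertex 0).  The parameter domain is t in [0, 1) with
vertex i sitting at t = i/N; evaluation between vertices is piecewise linear.
The y-axis points up; angles are in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import (
    DegenerateAreaError,
    ExteriorReferenceError,
    InvalidContourError,
    InvalidMapError,
)

__all__ = [
    "Contour",
    "ParamMap",
    "polyline_length",
    "signed_area",
    "contour_centroid",
    "area_centroid",
    "signed_curvature",
    "winding_angle",
    "apply_param_map",
    "point_in_polygon",
    "evaluate",
    "is_simple",
]


@dataclass(frozen=True)
class Contour:
    """Closed planar polyline.

    Parameters
    ----------
    vertices : (N, 2) array of float
        Ordered vertices; the closing edge from the last vertex back to the
        first is implicit (no duplicated closing row).
    label : int, optional
        Class label for supervised workflows.
    name : str, optional
        Free-form identifier.
    """

    vertices: np.ndarray
    label: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidContourError(f"vertices must be (N, 2), got {v.shape}")
        if v.shape[0] < 3:
            raise InvalidContourError(f"need at least 3 vertices, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise InvalidContourError("vertices contain non-finite values")
        edges = np.diff(np.vstack([v, v[:1]]), axis=0)
        if np.any(np.all(edges == 0.0, axis=1)):
            raise InvalidContourError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edge_vectors(self) -> np.ndarray:
        """(N, 2) edge vectors, including the closing edge."""
        v = self.vertices
        return np.vstack([v[1:], v[:1]]) - v

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def with_vertices(self, vertices: np.ndarray) -> "Contour":
        return Contour(vertices, label=self.label, name=self.name)


@dataclass(frozen=True)
class ParamMap:
    """Discretized monotone map of [0, 1] onto itself, fixing the endpoints.

    ``values[j]`` is the image of t_j = j/(M-1) on the uniform grid.  The map
    is non-decreasing; it is strictly increasing except in the generalized
    (curvature-only, lambda = 0) case where it may plateau over flat pieces.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise InvalidMapError("ParamMap needs a 1-d array of >= 2 values")
        if abs(v[0]) > 1e-9 or abs(v[-1] - 1.0) > 1e-9:
            raise InvalidMapError("ParamMap must fix 0 and 1")
        if np.any(np.diff(v) < -1e-12):
            raise InvalidMapError("ParamMap must be non-decreasing")
        v = v.copy()
        v[0], v[-1] = 0.0, 1.0
        object.__setattr__(self, "values", np.maximum.accumulate(v))

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.values.size)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.grid, self.values)

    def invert(self, u: np.ndarray) -> np.ndarray:
        """Left-most preimage of ``u`` under the piecewise-linear map.

        Plateaus (possible only at lambda = 0) are inverted to their left
        edge, the well-defined limit of the diffeomorphism case.
        """
        u = np.asarray(u, dtype=float)
        vals, grid = self.values, self.grid
        idx = np.searchsorted(vals, u, side="left")
        idx = np.clip(idx, 0, vals.size - 1)
        exact = vals[idx] == u
        lo = np.clip(idx - 1, 0, vals.size - 1)
        denom = vals[idx] - vals[lo]
        safe = np.where(denom > 0, denom, 1.0)
        frac = (u - vals[lo]) / safe
        t = grid[lo] + frac * (grid[idx] - grid[lo])
        return np.where(exact, grid[idx], t)

    @staticmethod
    def identity(m: int) -> "ParamMap":
        return ParamMap(np.linspace(0.0, 1.0, m))


def polyline_length(c: Contour) -> float:
    """Total length of the closed polyline (closing edge included)."""
    return float(c.edge_lengths().sum())


def signed_area(c: Contour) -> float:
    """Shoelace area; positive iff the contour travels counterclockwise."""
    v = c.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yn - xn * y))


def contour_centroid(c: Contour) -> np.ndarray:
    """Arc-length-weighted mean of the boundary points.

    Discretized exactly for a polyline: each edge contributes its midpoint
    weighted by its length.  Invariant under resampling of the same polyline.
    """
    v = c.vertices
    nxt = np.vstack([v[1:], v[:1]])
    lengths = np.linalg.norm(nxt - v, axis=1)
    mids = 0.5 * (v + nxt)
    return (mids * lengths[:, None]).sum(axis=0) / lengths.sum()


def area_centroid(c: Contour) -> np.ndarray:
    """Centroid of the region enclosed by the contour (polygon centroid).

    Orientation-independent; raises on (near-)zero enclosed area.
    """
    v = c.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    scale = max(polyline_length(c), 1.0)
    if abs(a) < 1e-12 * scale**2:
        raise DegenerateAreaError("enclosed area is numerically zero")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def signed_curvature(c: Contour) -> np.ndarray:
    """Per-vertex signed curvature, units 1/length.

    kappa_i = (exterior turning angle at vertex i) / (mean of the two adjacent
    edge lengths).  Positive where the contour turns counterclockwise; the sum
    of turning angles is exactly +2*pi for a CCW simple contour.
    """
    e = c.edge_vectors()
    prev = np.roll(e, 1, axis=0)
    cross = prev[:, 0] * e[:, 1] - prev[:, 1] * e[:, 0]
    dot = np.sum(prev * e, axis=1)
    turn = np.arctan2(cross, dot)
    lens = c.edge_lengths()
    half = 0.5 * (np.roll(lens, 1) + lens)
    return turn / half


def turning_angles(c: Contour) -> np.ndarray:
    """Exterior turning angle at each vertex (radians); sums to 2*pi*winding."""
    e = c.edge_vectors()
    prev = np.roll(e, 1, axis=0)
    cross = prev[:, 0] * e[:, 1] - prev[:, 1] * e[:, 0]
    dot = np.sum(prev * e, axis=1)
    return np.arctan2(cross, dot)


def point_in_polygon(p: np.ndarray, c: Contour) -> bool:
    """True iff ``p`` is strictly interior to the contour (boundary excluded)."""
    return bool(Polygon(c.vertices).contains(Point(p[0], p[1])))


def winding_angle(c: Contour, ref: np.ndarray) -> np.ndarray:
    """Unwrapped angle of the vector ref -> gamma(t) along the contour.

    Returns N+1 values on the vertex grid t = i/N, i = 0..N, with w(0) = 0.
    For a simple contour with interior ``ref``, w(1) = +2*pi (CCW) or -2*pi
    (CW).
    """
    ref = np.asarray(ref, dtype=float)
    if not point_in_polygon(ref, c):
        raise ExteriorReferenceError("reference point is not strictly interior")
    v = np.vstack([c.vertices, c.vertices[:1]]) - ref
    phi = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
    return phi - phi[0]


def evaluate(c: Contour, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear evaluation of the contour at parameters t (mod 1)."""
    t = np.asarray(t, dtype=float)
    n = c.n_vertices
    s = np.mod(t, 1.0) * n
    near = np.rint(s)
    s = np.where(np.abs(s - near) < 1e-9, near, s)  # snap to vertices
    s = np.mod(s, n)
    i = np.minimum(s.astype(int), n - 1)
    frac = s - i
    v = c.vertices
    nxt = v[(i + 1) % n]
    return v[i] * (1.0 - frac)[:, None] + nxt * frac[:, None]


def apply_param_map(c: Contour, m: ParamMap, n_out: int) -> Contour:
    """Resample ``c`` at parameters Phi^{-1}(j/n_out), j = 0..n_out-1.

    Realizes gamma o Phi^{-1} on samples.  With the identity map and
    n_out = N the input vertices are returned bit-exactly.
    """
    if n_out < 3:
        raise InvalidContourError("need at least 3 output samples")
    u = np.arange(n_out) / n_out
    t = m.invert(u)
    return c.with_vertices(evaluate(c, t))


def is_simple(c: Contour) -> bool:
    """Non-self-intersection check (O(N^2) via shapely); test/fixture use."""
    from shapely.geometry import LinearRing

    try:
        return bool(LinearRing(c.vertices).is_simple)
    except Exception:
        return False
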