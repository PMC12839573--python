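"""Seeded generator of labeled leaf-like contours and nuisance transforms.

Shapes are smooth radial-Fourier outlines r(theta) = 1 + sum_k a_k cos(k*theta
+ phi_k) around the origin, optionally with a peduncle: a narrow Gaussian
radial bump emulating a leaf stalk, which adds a lot of boundary length and
curvature but almost no enclosed area.  Outlines are star-shaped about the
origin by construction (hence simple whenever r > 0); a dedicated crescent
builder produces the non-star-shaped, exterior-centroid case.

Nuisance transforms apply the full symmetry group under seeded randomness:
rotation, translation, scaling, optional direction flip, cyclic roll of the
starting vertex, and a random monotone reparameterization.  Each transform
draws from its own named random stream so adding one never perturbs another.

Class-spec defaults model a mid-size labeled outline study: 5 classes with
distinct harmonic signatures (two with peduncles), per-sample amplitude jitter
of 0.02, and contours densely sampled then resampled to roughly constant
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contour import Contour, ParamMap, apply_param_map, signed_area
from .errors import ShapesectError
from .canonical import arclength_map
from .metric import LabeledShapeSet

__all__ = [
    "ShapeClassSpec",
    "make_shape",
    "make_crescent",
    "nuisance_transform",
    "random_reparam_map",
    "make_dataset",
    "stratified_split",
    "default_class_specs",
]

# fixed stream tags: adding a transform must never shift existing streams
_STREAMS = {
    "jitter": 11,
    "rotation": 21,
    "translation": 22,
    "scale": 23,
    "flip": 24,
    "roll": 25,
    "reparam": 26,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class ShapeClassSpec:
    """Recipe for one class of radial-Fourier leaf outlines.

    amplitudes/phases : per-harmonic a_k and phi_k for k = 1, 2, ...
        sum |a_k| < 1 keeps the radius positive, hence the outline simple.
    peduncle : optional (length, angular_width_rad, attachment_angle_rad)
        Narrow outward bump; its area contribution stays below ~2% of the
        blade so area-based quantities are peduncle-insensitive.
    noise : per-sample amplitude jitter (std of Gaussian perturbation of a_k).
    samples_per_class : default m when building a dataset.
    """

    amplitudes: tuple = ()
    phases: tuple = ()
    peduncle: tuple | None = None
    noise: float = 0.02
    samples_per_class: int = 10
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.phases) not in (0, len(self.amplitudes)):
            raise ShapesectError("phases must match amplitudes in length")
        if sum(abs(a) for a in self.amplitudes) >= 0.95:
            raise ShapesectError("sum |a_k| must stay below 1 for a simple outline")
        if self.peduncle is not None and self.peduncle[1] <= 0:
            raise ShapesectError("peduncle width must be positive")


def _radius(spec: ShapeClassSpec, theta: np.ndarray, amps: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    phases = spec.phases if spec.phases else (0.0,) * len(spec.amplitudes)
    for k, (a, ph) in enumerate(zip(amps, phases), start=1):
        r = r + a * np.cos(k * theta + ph)
    if spec.peduncle is not None:
        length, width, angle = spec.peduncle
        d = np.angle(np.exp(1j * (theta - angle)))
        r = r + length * np.exp(-0.5 * (d / width) ** 2)
    return r


def make_shape(spec: ShapeClassSpec, seed: int, n_points: int = 1000) -> Contour:
    """One deterministic, simple, CCW outline of ``n_points`` vertices.

    The radial profile is evaluated on a dense angular grid and then resampled
    to roughly constant speed, so thin features (peduncles) are adequately
    sampled.  Jittered realizations whose radius dips too low are retried a
    bounded number of times with fresh jitter.
    """
    rng = _rng(seed, "jitter")
    amps = np.asarray(spec.amplitudes, dtype=float)
    dense = max(8 * n_points, 4096)
    theta = 2 * np.pi * np.arange(dense) / dense
    for _ in range(5):
        a = amps + spec.noise * rng.standard_normal(amps.shape) if amps.size else amps
        r = _radius(spec, theta, a)
        if r.min() > 0.05:
            break
    else:
        raise ShapesectError("could not realize a positive-radius outline")
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    dense_c = Contour(verts)
    return apply_param_map(dense_c, arclength_map(dense_c), n_points)


def make_crescent(
    n_points: int = 400,
    outer_radius: float = 1.0,
    width: float = 0.15,
    span: float = 5.3,
) -> Contour:
    """Thin annular-arc polygon whose area centroid lies outside the region.

    Exercises the interior-reference fallback path of the clock construction.
    """
    half = n_points // 2
    r_in = outer_radius - width
    a0, a1 = -span / 2.0, span / 2.0
    ang = np.linspace(a0, a1, half)
    outer = np.column_stack([outer_radius * np.cos(ang), outer_radius * np.sin(ang)])
    inner = np.column_stack([r_in * np.cos(ang[::-1]), r_in * np.sin(ang[::-1])])
    c = Contour(np.vstack([outer, inner]))
    if signed_area(c) < 0:
        c = c.with_vertices(c.vertices[::-1])
    return c


def random_reparam_map(seed: int, knots: int = 64, sigma: float = 1.0) -> ParamMap:
    """Random strictly increasing map of [0,1]: normalized cumulative softplus
    of seeded Gaussian increments."""
    rng = _rng(seed, "reparam")
    g = rng.standard_normal(knots) * sigma
    w = np.logaddexp(0.0, g)  # softplus: strictly positive
    cum = np.concatenate([[0.0], np.cumsum(w)])
    return ParamMap(cum / cum[-1])


def nuisance_transform(
    c: Contour,
    seed: int,
    rotate: bool = True,
    translate: bool = True,
    rescale: bool = True,
    flip: bool = True,
    roll: bool = True,
    reparam: bool = True,
) -> Contour:
    """Seeded random element of the full symmetry group applied to ``c``.

    Rotation uniform on [0, 2*pi), translation uniform in [-2, 2]^2, scale
    log-uniform in [1/2, 2], a fair-coin orientation flip, a uniform cyclic
    roll of the vertex list and a random monotone reparameterization.
    """
    v = c.vertices
    n = v.shape[0]
    if reparam:
        c2 = apply_param_map(Contour(v), random_reparam_map(seed), n)
        v = c2.vertices
    if roll:
        k = int(_rng(seed, "roll").integers(0, n))
        v = np.roll(v, -k, axis=0)
    if flip and _rng(seed, "flip").random() < 0.5:
        v = np.vstack([v[:1], v[:0:-1]])
    if rotate:
        ang = float(_rng(seed, "rotation").uniform(0.0, 2 * np.pi))
        ca, sa = np.cos(ang), np.sin(ang)
        v = v @ np.array([[ca, sa], [-sa, ca]])
    if rescale:
        s = float(np.exp(_rng(seed, "scale").uniform(np.log(0.5), np.log(2.0))))
        v = v * s
    if translate:
        v = v + _rng(seed, "translation").uniform(-2.0, 2.0, size=2)
    return c.with_vertices(v)


def make_dataset(
    specs: list,
    seed: int,
    n_points: int = 1000,
    samples_per_class: int | None = None,
    nuisance: bool = True,
) -> LabeledShapeSet:
    """Labeled set of per-class realizations, each under its own nuisance draw.

    Deterministic in (specs, seed); labels are 1..K in spec order.
    """
    if len(specs) < 2:
        raise ShapesectError("need at least 2 class specs")
    contours, labels = [], []
    names = {}
    for ci, spec in enumerate(specs, start=1):
        names[ci] = spec.name or f"class_{ci}"
        m = samples_per_class if samples_per_class is not None else spec.samples_per_class
        for si in range(m):
            child = int(
                np.random.SeedSequence([int(seed), ci, si]).generate_state(1)[0] % (2**31)
            )
            shape = make_shape(spec, child, n_points)
            if nuisance:
                shape = nuisance_transform(shape, child)
            contours.append(shape.with_vertices(shape.vertices))
            labels.append(ci)
    return LabeledShapeSet(contours, np.asarray(labels), names)


def stratified_split(ds: LabeledShapeSet, train_fraction: float, seed: int):
    """Disjoint stratified (train, test) index split covering all samples."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    train_idx, test_idx = [], []
    for k in ds.classes:
        idx = ds.class_indices(k)
        perm = rng.permutation(idx)
        n_train = max(1, int(round(train_fraction * idx.size)))
        n_train = min(n_train, idx.size - 1) if idx.size > 1 else n_train
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx, test_idx = sorted(map(int, train_idx)), sorted(map(int, test_idx))
    return ds.subset(train_idx), ds.subset(test_idx)


def default_class_specs() -> list:
    """Five leaf-like classes with distinct harmonic signatures.

    Class 1: broad ovate blade with peduncle; class 2: elongated three-lobed;
    class 3: five-lobed (maple-like) with peduncle; class 4: narrow elliptic
    blade; class 5: wavy-margined blade with a pointed drip tip.  Every class
    has one vertex clearly farthest from the area centroid (the tip), so the
    canonical start point is stable under per-sample jitter; a first harmonic
    alone would not do (r = 1 + a*cos(theta) is nearly a translated circle).
    """
    return [
        ShapeClassSpec((0.25, 0.05), (0.0, 0.3), peduncle=(0.55, 0.035, np.pi),
                       name="ovate_peduncle"),
        ShapeClassSpec((0.15, 0.2, 0.12), (0.0, 0.0, 0.5), name="three_lobed"),
        ShapeClassSpec((0.22, 0.0, 0.0, 0.0, 0.15), (0.0, 0.0, 0.0, 0.0, 0.2),
                       peduncle=(0.5, 0.04, np.pi), name="five_lobed_peduncle"),
        ShapeClassSpec((0.45, 0.18), (0.0, 0.0), noise=0.015, name="narrow_elliptic"),
        ShapeClassSpec((0.15, 0.2, 0.0, 0.0, 0.0, 0.06), (0.0,) * 6,
                       peduncle=(0.3, 0.06, 0.0), name="wavy_margin"),
    ]
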