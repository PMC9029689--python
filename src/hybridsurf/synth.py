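"""Voxelized analytic phantoms with exact signed-distance ground truth.

Desk-scale stand-ins for segmented anatomy: a smooth sphere (large flat-ish
regions), a torus (sustained high curvature), a narrow-neck dumbbell (the
feature a too-large implicit tolerance smooths away) and a two-component
object (the component-merging failure mode of over-smoothed implicits).
Every phantom carries its analytic signed-distance function (SDF, negative
inside, mm) so reconstruction error can be measured against exact geometry.
Voxelization is ``SDF(voxel center) < 0``; everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .volume import SegmentationVolume

SDF = Callable[[np.ndarray], np.ndarray]

_SHAPES = ("sphere", "torus", "dumbbell", "two_spheres", "half_space")


@dataclass
class PhantomSpec:
    """Analytic phantom description.

    ``params`` are in mm and depend on the shape:

    - sphere: center, radius
    - torus: center, ring_radius, tube_radius (axis = z)
    - dumbbell: center, radius, half_separation, neck_radius (axis = x)
    - two_spheres: center, radius, half_separation (axis = x)
    - half_space: z0 (foreground where z < z0)
    """

    shape: str
    params: dict
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_flip_fraction: float = 0.0
    noise_seed: int = 0
    name: str = field(default="")

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {_SHAPES}")
        if not self.name:
            self.name = self.shape

    def sdf(self) -> SDF:
        return _make_sdf(self.shape, self.params)


def _sphere_sdf(center, radius) -> SDF:
    center = np.asarray(center, dtype=float)

    def f(p: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(p) - center, axis=-1) - radius

    return f


def _capsule_sdf(a, b, radius) -> SDF:
    """Distance to a segment a-b minus radius (a cylinder with round caps)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)

    def f(p: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(p) - a
        t = np.clip((q @ ab) / denom, 0.0, 1.0)
        return np.linalg.norm(q - t[:, None] * ab, axis=-1) - radius

    return f


def _make_sdf(shape: str, params: dict) -> SDF:
    if shape == "sphere":
        return _sphere_sdf(params["center"], params["radius"])
    if shape == "torus":
        center = np.asarray(params["center"], dtype=float)
        R, r = float(params["ring_radius"]), float(params["tube_radius"])

        def torus(p: np.ndarray) -> np.ndarray:
            q = np.atleast_2d(p) - center
            rho = np.hypot(q[..., 0], q[..., 1]) - R
            return np.hypot(rho, q[..., 2]) - r

        return torus
    if shape == "two_spheres":
        center = np.asarray(params["center"], dtype=float)
        s = float(params["half_separation"])
        f1 = _sphere_sdf(center + (s, 0, 0), params["radius"])
        f2 = _sphere_sdf(center - (s, 0, 0), params["radius"])
        return lambda p: np.minimum(f1(p), f2(p))
    if shape == "dumbbell":
        center = np.asarray(params["center"], dtype=float)
        s = float(params["half_separation"])
        f1 = _sphere_sdf(center + (s, 0, 0), params["radius"])
        f2 = _sphere_sdf(center - (s, 0, 0), params["radius"])
        neck = _capsule_sdf(center - (s, 0, 0), center + (s, 0, 0), params["neck_radius"])
        return lambda p: np.minimum(np.minimum(f1(p), f2(p)), neck(p))
    if shape == "half_space":
        z0 = float(params["z0"])
        return lambda p: np.atleast_2d(p)[..., 2] - z0
    raise ValueError(shape)


def make_phantom(spec: PhantomSpec) -> tuple[SegmentationVolume, SDF]:
    """Voxelize a phantom on its grid and return the mask plus the exact SDF.

    Foreground = voxels whose center has negative signed distance.  Shapes
    other than half_space must stay >= 2 voxels away from the grid border;
    otherwise the error message states the grid size that would fit.
    """
    sdf = spec.sdf()
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    centers = origin + idx * spacing
    inside = sdf(centers) < 0
    grid = inside.reshape(spec.grid_shape).astype(np.uint8)

    if spec.shape != "half_space":
        fg = np.argwhere(grid)
        if len(fg) == 0:
            raise ValueError("phantom produces an empty mask on this grid")
        lo, hi = fg.min(axis=0), fg.max(axis=0)
        shape = np.array(spec.grid_shape)
        if (lo < 2).any() or (hi > shape - 3).any():
            needed = tuple(int(n) for n in (hi - lo + 1) + 4)
            raise ValueError(
                f"shape does not fit with a 2-voxel margin in grid {spec.grid_shape}; "
                f"needs at least {needed}"
            )

    if spec.noise_flip_fraction > 0:
        rng = np.random.default_rng(spec.noise_seed)
        flip = rng.random(grid.shape) < spec.noise_flip_fraction
        grid = np.where(flip, 1 - grid, grid).astype(np.uint8)

    return SegmentationVolume(grid, spacing, origin), sdf


def phantom_suite(spacing=(1.0, 1.0, 1.0)) -> list[tuple[str, SegmentationVolume, SDF]]:
    """The four standard regression fixtures.

    - ``sphere``: r = 10 mm — smooth, low curvature everywhere.
    - ``torus``: ring 7 mm, tube 3 mm — sustained high curvature.
    - ``dumbbell``: two r = 6 mm lobes bridged by a 2 mm neck — the narrow
      feature that a large implicit tolerance rounds off.
    - ``two_spheres``: two r = 8 mm components with a 3 mm gap — the
      component-merging failure mode.
    """
    out = []
    for spec in standard_specs(spacing):
        vol, sdf = make_phantom(spec)
        out.append((spec.name, vol, sdf))
    return out


def standard_specs(spacing=(1.0, 1.0, 1.0)) -> list[PhantomSpec]:
    sx, sy, sz = spacing
    return [
        PhantomSpec(
            "sphere",
            {"center": (13.5 * sx, 13.5 * sy, 13.5 * sz), "radius": 10.0},
            (28, 28, 28),
            spacing,
        ),
        PhantomSpec(
            "torus",
            {"center": (13.5 * sx, 13.5 * sy, 6.5 * sz), "ring_radius": 7.0, "tube_radius": 3.0},
            (28, 28, 14),
            spacing,
        ),
        PhantomSpec(
            "dumbbell",
            {
                "center": (16.5 * sx, 8.5 * sy, 8.5 * sz),
                "radius": 6.0,
                "half_separation": 7.0,
                "neck_radius": 2.0,
            },
            (34, 18, 18),
            spacing,
        ),
        PhantomSpec(
            "two_spheres",
            {"center": (19.5 * sx, 10.5 * sy, 10.5 * sz), "radius": 8.0, "half_separation": 9.5},
            (40, 22, 22),
            spacing,
        ),
    ]
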