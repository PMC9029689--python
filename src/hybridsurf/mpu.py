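"""Multi-level Partition of Unity implicit surfaces.

An adaptive octree covers the oriented boundary point cloud; every cell fits
a local quadric to the points inside its support ball and cells whose fit
error exceeds the user tolerance ``tol`` split into eight children.  The
global signed field blends the leaf quadrics with compactly supported
quadratic-B-spline weights (a partition of unity over the covered region).
Sign convention: negative inside the object, positive outside (normals point
outward).  ``tol`` is the single knob trading smoothness against fidelity:
large values stop refinement early and smooth detail away, small values
track the points closely.

The build is fully deterministic: no randomness, point order fixed by input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .isosurface import EmptySurfaceError, ScalarFieldGrid, extract_isosurface
from .mesh import TriangleMesh
from .volume import BoundaryPointSet

_SQRT3 = float(np.sqrt(3.0))
_OCTANT_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 1) for dy in (-1, 1) for dz in (-1, 1)], dtype=float
)


def bspline_weight(r: np.ndarray, R: float) -> np.ndarray:
    """Quadratic B-spline bump b(1.5 r / R): C^1, positive on [0, R), 0 beyond."""
    t = 1.5 * np.asarray(r, dtype=float) / R
    w = np.zeros_like(t)
    near = t <= 0.5
    mid = (t > 0.5) & (t < 1.5)
    w[near] = 0.75 - t[near] ** 2
    w[mid] = 0.5 * (1.5 - t[mid]) ** 2
    return w


# ---------------------------------------------------------------------------
# local fits


@dataclass
class LocalFit:
    """One cell's local implicit: bivariate quadric, general quadric or plane.

    - ``bivariate``: height-field quadric over the plane orthogonal to the
      mean normal; frame rows (u, v, w) with w outward;
      f = w - (c0 + c1 u + c2 v + c3 u^2 + c4 uv + c5 v^2).
    - ``general``: trivariate quadric on scaled coordinates y = (p - o)/s
      with 10 monomial coefficients [1, x, y, z, x2, y2, z2, xy, xz, yz].
    - ``plane``: f = n . (p - o), the rank-deficiency fallback.
    """

    kind: str
    origin: np.ndarray
    frame: np.ndarray | None = None
    coeffs: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale: float = 1.0

    def value(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        if self.kind == "plane":
            return (p - self.origin) @ self.coeffs
        if self.kind == "bivariate":
            loc = (p - self.origin) @ self.frame.T
            u, v, w = loc[:, 0], loc[:, 1], loc[:, 2]
            c = self.coeffs
            return w - (c[0] + c[1] * u + c[2] * v + c[3] * u * u + c[4] * u * v + c[5] * v * v)
        y = (p - self.origin) / self.scale
        x1, x2, x3 = y[:, 0], y[:, 1], y[:, 2]
        c = self.coeffs
        return self.scale * (
            c[0] + c[1] * x1 + c[2] * x2 + c[3] * x3
            + c[4] * x1 * x1 + c[5] * x2 * x2 + c[6] * x3 * x3
            + c[7] * x1 * x2 + c[8] * x1 * x3 + c[9] * x2 * x3
        )

    def gradient(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        if self.kind == "plane":
            return np.broadcast_to(self.coeffs, p.shape).copy()
        if self.kind == "bivariate":
            loc = (p - self.origin) @ self.frame.T
            u, v = loc[:, 0], loc[:, 1]
            c = self.coeffs
            du = -(c[1] + 2 * c[3] * u + c[4] * v)
            dv = -(c[2] + c[4] * u + 2 * c[5] * v)
            dw = np.ones_like(u)
            return np.column_stack([du, dv, dw]) @ self.frame
        y = (p - self.origin) / self.scale
        x1, x2, x3 = y[:, 0], y[:, 1], y[:, 2]
        c = self.coeffs
        g = np.column_stack(
            [
                c[1] + 2 * c[4] * x1 + c[7] * x2 + c[8] * x3,
                c[2] + 2 * c[5] * x2 + c[7] * x1 + c[9] * x3,
                c[3] + 2 * c[6] * x3 + c[8] * x1 + c[9] * x2,
            ]
        )
        return g

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "origin": self.origin.tolist(), "scale": self.scale,
             "coeffs": self.coeffs.tolist()}
        if self.frame is not None:
            d["frame"] = self.frame.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LocalFit":
        return cls(
            d["kind"],
            np.asarray(d["origin"], dtype=float),
            None if "frame" not in d else np.asarray(d["frame"], dtype=float),
            np.asarray(d["coeffs"], dtype=float),
            d.get("scale", 1.0),
        )


def _orthonormal_frame(w: np.ndarray) -> np.ndarray:
    """Rows (u, v, w) with w the given unit vector."""
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.vstack([u, v, w])


def _plane_fit(pts, normals, weights) -> LocalFit:
    n = normals.sum(axis=0)
    norm = np.linalg.norm(n)
    n = n / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    origin = np.average(pts, axis=0, weights=np.maximum(weights, 1e-12))
    return LocalFit("plane", origin, None, n)


def fit_local_quadric(
    local_points: np.ndarray,
    local_normals: np.ndarray,
    center: np.ndarray,
    R: float,
    *,
    normal_cone_deg: float = 90.0,
    aux_tree: cKDTree | None = None,
) -> tuple[LocalFit, float]:
    """Fit one cell's local implicit and report its Taubin fit error.

    A bivariate (height-field) quadric is used when every local normal lies
    within ``normal_cone_deg`` of the mean normal (a single-sheet patch);
    otherwise a general trivariate quadric constrained by off-surface points
    at +/- d along the normals.  Rank-deficient systems fall back to a plane
    fit and never fail.  The error is
    ``max_i  (w_i / w(0)) * |f(p_i)| / ||grad f(p_i)||`` over the support
    points — a first-order point-to-surface distance weighted by the cell's
    own blending weight.
    """
    pts = np.atleast_2d(local_points)
    nrm = np.atleast_2d(local_normals)
    r = np.linalg.norm(pts - center, axis=1)
    w = bspline_weight(r, R) / 0.75
    w_fit = np.maximum(w, 1e-9)

    mean_n = nrm.sum(axis=0)
    mean_norm = np.linalg.norm(mean_n)
    single_sheet = False
    if mean_norm > 1e-12:
        mean_n = mean_n / mean_norm
        single_sheet = float((nrm @ mean_n).min()) > np.cos(np.deg2rad(normal_cone_deg))

    fit: LocalFit | None = None
    if single_sheet:
        frame = _orthonormal_frame(mean_n)
        origin = np.average(pts, axis=0, weights=w_fit)
        loc = (pts - origin) @ frame.T
        u, v, h = loc[:, 0], loc[:, 1], loc[:, 2]
        A = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
        sw = np.sqrt(w_fit)
        coeffs, _, rank, _ = np.linalg.lstsq(A * sw[:, None], h * sw, rcond=None)
        if rank == 6 and np.isfinite(coeffs).all():
            fit = LocalFit("bivariate", origin, frame, coeffs)
    if fit is None and not single_sheet:
        # general 3D quadric constrained by off-surface auxiliary points
        if len(pts) > 1:
            d_nn, _ = cKDTree(pts).query(pts, k=2)
            d = 0.5 * float(np.mean(d_nn[:, 1]))
        else:
            d = 0.1 * R
        d = max(d, 1e-6)
        aux_pos, aux_val, aux_w = [], [], []
        ref = aux_tree if aux_tree is not None else cKDTree(pts)
        for sign in (1.0, -1.0):
            cand = pts + sign * d * nrm
            dist, _ = ref.query(cand)
            ok = dist >= d * (1.0 - 1e-9)
            aux_pos.append(cand[ok])
            aux_val.append(np.full(ok.sum(), sign * d))
            aux_w.append(w_fit[ok])
        P = np.concatenate([pts] + aux_pos)
        target = np.concatenate([np.zeros(len(pts))] + aux_val)
        ww = np.concatenate([w_fit] + aux_w)
        y = (P - center) / R
        x1, x2, x3 = y[:, 0], y[:, 1], y[:, 2]
        A = np.column_stack(
            [np.ones_like(x1), x1, x2, x3, x1 * x1, x2 * x2, x3 * x3,
             x1 * x2, x1 * x3, x2 * x3]
        )
        sw = np.sqrt(ww)
        coeffs, _, rank, _ = np.linalg.lstsq(A * sw[:, None], (target / R) * sw, rcond=None)
        if rank == 10 and np.isfinite(coeffs).all():
            fit = LocalFit("general", center.copy(), None, coeffs, scale=R)
    if fit is None:
        fit = _plane_fit(pts, nrm, w_fit)

    f = fit.value(pts)
    g = np.linalg.norm(fit.gradient(pts), axis=1)
    err = np.abs(f) / np.maximum(g, 1e-12)
    fit_error = float(np.max(w * err)) if len(err) else 0.0
    return fit, fit_error


# ---------------------------------------------------------------------------
# octree


@dataclass
class MPUCell:
    """Octree cell: cube, support radius, local fit and refinement state."""

    center: np.ndarray
    half_width: float
    depth: int
    support_radius: float = 0.0
    local_fit: LocalFit | None = None
    fit_error: float = np.inf
    at_max_depth: bool = False
    n_support_points: int = 0
    children: list["MPUCell"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_fitted_leaves(self):
        if self.is_leaf:
            if self.local_fit is not None:
                yield self
        else:
            for c in self.children:
                yield from c.iter_fitted_leaves()


@dataclass
class MPUModel:
    """Evaluable MPU implicit: blended octree of local quadric fits."""

    root: MPUCell
    tol: float
    points: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self._refresh_leaf_cache()

    def _refresh_leaf_cache(self) -> None:
        leaves = list(self.root.iter_fitted_leaves())
        self._leaves = leaves
        self._centers = np.array([c.center for c in leaves]).reshape(-1, 3)
        self._radii = np.array([c.support_radius for c in leaves])
        self._center_tree = cKDTree(self._centers)
        self._point_tree = cKDTree(self.points)

    @property
    def leaves(self) -> list[MPUCell]:
        return self._leaves

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)

    def evaluate(self, x, return_covered: bool = False):
        """Blended signed field at x ((3,) or (N, 3)); ~ signed distance, mm.

        Points outside every support ball get a fallback value (flagged in
        the coverage mask when ``return_covered``): the signed distance to
        the nearest input point, oriented by that point's normal,
        ``sign((x - p) . n) ||x - p||``.  Uncovered space lies away from the
        surface, so the fallback magnitude is bounded below there and cannot
        create a spurious zero crossing — unlike extrapolating a local
        quadric, whose second sheet may re-cross zero far from its cell.
        """
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        q = np.atleast_2d(x)
        num = np.zeros(len(q))
        den = np.zeros(len(q))
        qtree = cKDTree(q)
        for leaf, c, R in zip(self._leaves, self._centers, self._radii):
            idx = qtree.query_ball_point(c, R)
            if not idx:
                continue
            idx = np.asarray(idx)
            w = bspline_weight(np.linalg.norm(q[idx] - c, axis=1), R)
            num[idx] += w * leaf.local_fit.value(q[idx])
            den[idx] += w
        covered = den > 0
        vals = np.empty(len(q))
        vals[covered] = num[covered] / den[covered]
        if (~covered).any():
            miss = q[~covered]
            dist, nearest = self._point_tree.query(miss)
            delta = miss - self.points[nearest]
            side = np.sign(np.einsum("ij,ij->i", delta, self.normals[nearest]))
            vals[~covered] = np.where(side == 0, dist, side * dist)
        if scalar:
            return (float(vals[0]), bool(covered[0])) if return_covered else float(vals[0])
        return (vals, covered) if return_covered else vals

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        def cell_dict(c: MPUCell) -> dict:
            return {
                "center": c.center.tolist(),
                "half_width": c.half_width,
                "depth": c.depth,
                "support_radius": c.support_radius,
                "fit_error": None if not np.isfinite(c.fit_error) else c.fit_error,
                "at_max_depth": c.at_max_depth,
                "n_support_points": c.n_support_points,
                "local_fit": None if c.local_fit is None else c.local_fit.to_dict(),
                "children": [cell_dict(ch) for ch in c.children],
            }

        payload = json.dumps(
            {
                "tol": self.tol,
                "points": self.points.tolist(),
                "normals": self.normals.tolist(),
                "root": cell_dict(self.root),
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "MPUModel":
        def parse(d: dict) -> MPUCell:
            cell = MPUCell(
                np.asarray(d["center"], dtype=float),
                d["half_width"],
                d["depth"],
                d["support_radius"],
                None if d["local_fit"] is None else LocalFit.from_dict(d["local_fit"]),
                np.inf if d["fit_error"] is None else d["fit_error"],
                d["at_max_depth"],
                d["n_support_points"],
            )
            cell.children = [parse(ch) for ch in d["children"]]
            return cell

        data = json.loads(payload)
        return cls(
            parse(data["root"]),
            data["tol"],
            np.asarray(data["points"], dtype=float),
            np.asarray(data["normals"], dtype=float),
        )


def build_mpu(
    points: BoundaryPointSet | np.ndarray,
    tol: float,
    max_depth: int = 8,
    alpha: float = 0.75,
    n_min: int = 15,
    normals: np.ndarray | None = None,
) -> MPUModel:
    """Build the adaptive octree of local quadric fits.

    Each cell gathers the points within R = alpha x cell diagonal, growing R
    by 10% steps until at least ``n_min`` points are covered, fits a local
    quadric and refines (8 children) wherever the fit error exceeds ``tol``
    until ``max_depth``.  Child octants whose initial support ball is empty
    are dropped from the blend.
    """
    if isinstance(points, BoundaryPointSet):
        pts, nrm = points.points, points.normals
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if normals is None:
            raise ValueError("normals are required when passing a raw point array")
        nrm = np.atleast_2d(np.asarray(normals, dtype=float))
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if len(pts) < n_min:
        raise ValueError(f"need at least n_min={n_min} points, got {len(pts)}")

    tree = cKDTree(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    half = 0.5 * float((hi - lo).max()) * 1.01 + 1e-9
    root_center = 0.5 * (lo + hi)

    def build_cell(center: np.ndarray, half_width: float, depth: int) -> MPUCell | None:
        R = alpha * 2.0 * half_width * _SQRT3
        idx = tree.query_ball_point(center, R)
        if not idx:
            return None
        while len(idx) < n_min:
            R *= 1.1
            idx = tree.query_ball_point(center, R)
        idx = np.asarray(sorted(idx))
        fit, err = fit_local_quadric(pts[idx], nrm[idx], center, R, aux_tree=tree)
        cell = MPUCell(center.copy(), half_width, depth, R, fit, err,
                       n_support_points=len(idx))
        if err > tol and depth < max_depth:
            children = []
            for off in _OCTANT_OFFSETS:
                child = build_cell(center + off * half_width / 2.0, half_width / 2.0, depth + 1)
                if child is not None:
                    children.append(child)
            if children:
                cell.children = children
        if cell.is_leaf and err > tol:
            cell.at_max_depth = True
        return cell

    root = build_cell(root_center, half, 0)
    assert root is not None  # len(pts) >= n_min guarantees support
    return MPUModel(root, tol, pts.copy(), nrm.copy())


def polygonize(
    model: MPUModel,
    resolution: float,
    margin: float | None = None,
) -> TriangleMesh:
    """Triangulate the zero level set on a uniform grid of the given step.

    The field is sampled over the model's bounding box expanded by
    ``margin`` (default: 3 grid steps) and handed to the shared
    marching-cubes extractor at isovalue 0.  No smoothing post-process is
    applied: smoothness comes from the implicit itself.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lo, hi = model.bounding_box()
    if margin is None:
        margin = 3.0 * resolution
    lo = lo - margin
    hi = hi + margin
    shape = np.maximum(np.ceil((hi - lo) / resolution).astype(int) + 1, 2)
    grids = np.meshgrid(*[lo[a] + resolution * np.arange(shape[a]) for a in range(3)],
                        indexing="ij")
    q = np.column_stack([g.ravel() for g in grids])
    vals = np.empty(len(q))
    chunk = 200_000
    for s in range(0, len(q), chunk):
        vals[s:s + chunk] = model.evaluate(q[s:s + chunk])
    # negative-inside convention -> negate so the object is the >= iso side
    fieldgrid = ScalarFieldGrid(-vals.reshape(tuple(shape)), np.full(3, resolution), lo)
    try:
        return extract_isosurface(fieldgrid, 0.0)
    except EmptySurfaceError as exc:
        raise EmptySurfaceError(
            f"MPU zero level set absent in sampled box {lo} .. {hi}: {exc}"
        ) from exc
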