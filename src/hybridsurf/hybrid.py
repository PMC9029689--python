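"""Hybrid reconstruction: keep whichever surface is locally closer.

The two base reconstructions disagree in characteristic ways: the
marching-cubes / Flying-Edges mesh is faithful to the mask but needs
smoothing that can pull flat regions away, while the MPU implicit is
inherently smooth but can round off narrow features or merge nearby
components.  The hybrid compares both against the segmentation boundary
triangle by triangle — for each MPU triangle the nearest FE triangle (by
centroid) and the nearest segmentation point P are found, and the triangle
whose centroid is closer to P wins:

    delta(T_MPU, P, T_FE) = min(||C_MPU - P||, ||C_FE - P||)

The winning triangles' vertices are merged into one oriented point cloud
(normals recovered from the source meshes, shared vertices welded) and an
MPU implicit is refit with a small tolerance — the merged cloud is dense, so
a small tolerance yields a smooth and accurate final surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import isosurface, mpu
from .config import RunConfig
from .mesh import TriangleMesh
from .volume import BoundaryPointSet, SegmentationVolume, extract_boundary_points


@dataclass
class TriangleCorrespondence:
    """One row of the MPU -> FE -> segmentation matching."""

    mpu_triangle: int
    fe_triangle: int
    seg_point: int
    d_mpu: float
    d_fe: float
    winner: str  # "MPU" or "FE"

    @property
    def delta(self) -> float:
        return min(self.d_mpu, self.d_fe)


def match_triangles(
    mpu_mesh: TriangleMesh,
    fe_mesh: TriangleMesh,
    seg: BoundaryPointSet | np.ndarray,
    tie_rule: str = "fe",
) -> list[TriangleCorrespondence]:
    """Match every MPU triangle to its nearest FE triangle and seg point.

    Matching is one-directional (MPU -> FE) and uses triangle centroids, so
    the distances entering the min are exactly the ||C - P|| of the selection
    rule.  Ties go to FE, the mask-faithful method.  Meshes whose bounding
    boxes do not overlap trigger a misalignment warning but still match.
    """
    seg_pts = seg.points if isinstance(seg, BoundaryPointSet) else np.atleast_2d(np.asarray(seg, dtype=float))
    if len(seg_pts) == 0:
        raise ValueError("empty segmentation point set")
    if mpu_mesh.n_faces == 0 or fe_mesh.n_faces == 0:
        raise ValueError("both meshes must be non-empty")

    lo_a, hi_a = mpu_mesh.vertices.min(axis=0), mpu_mesh.vertices.max(axis=0)
    lo_b, hi_b = fe_mesh.vertices.min(axis=0), fe_mesh.vertices.max(axis=0)
    if (hi_a < lo_b).any() or (hi_b < lo_a).any():
        warnings.warn(
            "MPU and FE bounding boxes do not overlap; meshes are probably "
            "in different frames",
            stacklevel=2,
        )

    c_mpu = mpu_mesh.centroids()
    c_fe = fe_mesh.centroids()
    _, fe_idx = cKDTree(c_fe).query(c_mpu)
    _, p_idx = cKDTree(seg_pts).query(c_mpu)
    d_mpu = np.linalg.norm(c_mpu - seg_pts[p_idx], axis=1)
    d_fe = np.linalg.norm(c_fe[fe_idx] - seg_pts[p_idx], axis=1)

    if tie_rule not in ("fe", "mpu"):
        raise ValueError(f"tie_rule must be 'fe' or 'mpu', got {tie_rule!r}")
    rows = []
    for i in range(len(c_mpu)):
        if tie_rule == "fe":
            winner = "MPU" if d_mpu[i] < d_fe[i] else "FE"
        else:
            winner = "FE" if d_fe[i] < d_mpu[i] else "MPU"
        rows.append(
            TriangleCorrespondence(
                i, int(fe_idx[i]), int(p_idx[i]), float(d_mpu[i]), float(d_fe[i]), winner
            )
        )
    return rows


def select_triangles(
    correspondences: list[TriangleCorrespondence],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split winners into kept triangle index sets.

    Returns (kept MPU indices, kept FE indices, per-row delta).  An FE
    triangle can win several matches; duplicates are removed.
    """
    if not correspondences:
        raise ValueError("empty correspondence list")
    kept_mpu = np.array(
        sorted(r.mpu_triangle for r in correspondences if r.winner == "MPU"), dtype=np.int64
    )
    kept_fe = np.unique(
        np.array([r.fe_triangle for r in correspondences if r.winner == "FE"], dtype=np.int64)
    )
    deltas = np.array([r.delta for r in correspondences])
    return kept_mpu, kept_fe, deltas


def merge_and_extract_points(
    mpu_mesh: TriangleMesh,
    fe_mesh: TriangleMesh,
    kept_mpu: np.ndarray,
    kept_fe: np.ndarray,
    weld_tol: float | None = None,
) -> BoundaryPointSet:
    """Vertices of all kept triangles, welded into one oriented point cloud.

    Vertices closer than ``weld_tol`` (default 1e-6 x joint bounding-box
    diagonal) collapse into one point at their mean; each merged point
    carries the area-weighted average of its source vertex normals,
    renormalized.  Normals come from the source meshes, not from the volume.
    """
    if len(kept_mpu) == 0 and len(kept_fe) == 0:
        raise ValueError("empty selection: no triangles were kept")

    pos_parts, nrm_parts = [], []
    for mesh, kept in ((mpu_mesh, kept_mpu), (fe_mesh, kept_fe)):
        if len(kept) == 0:
            continue
        if mesh.vertex_normals is None:
            mesh.compute_vertex_normals()
        vids = np.unique(mesh.faces[kept].ravel())
        pos_parts.append(mesh.vertices[vids])
        nrm_parts.append(mesh.vertex_normals[vids])
    pos = np.concatenate(pos_parts)
    nrm = np.concatenate(nrm_parts)

    lo, hi = pos.min(axis=0), pos.max(axis=0)
    if weld_tol is None:
        weld_tol = 1e-6 * float(np.linalg.norm(hi - lo))

    # single-linkage clusters of points within weld_tol
    if weld_tol > 0:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(weld_tol, output_type="ndarray")
    else:
        _, inverse, counts = np.unique(
            pos, axis=0, return_inverse=True, return_counts=True
        )
        dup_groups = inverse
        pairs = None
    n = len(pos)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if pairs is None:
        first_of = {}
        for i, g in enumerate(dup_groups):
            if g in first_of:
                parent[i] = first_of[g]
            else:
                first_of[g] = i
    else:
        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    k = labels.max() + 1

    merged_pos = np.zeros((k, 3))
    merged_nrm = np.zeros((k, 3))
    counts = np.zeros(k)
    np.add.at(merged_pos, labels, pos)
    np.add.at(merged_nrm, labels, nrm)
    np.add.at(counts, labels, 1.0)
    merged_pos /= counts[:, None]
    norm = np.linalg.norm(merged_nrm, axis=1)
    merged_nrm /= np.where(norm > 0, norm, 1.0)[:, None]
    return BoundaryPointSet(merged_pos, merged_nrm, None)


@dataclass
class HybridResult:
    """Final mesh plus the intermediate products and provenance report."""

    mesh: TriangleMesh
    fe_mesh: TriangleMesh
    mpu_mesh: TriangleMesh
    seg_points: BoundaryPointSet
    correspondences: list[TriangleCorrespondence]
    report: dict


def hybrid_reconstruct(
    seg_volume: SegmentationVolume,
    config: RunConfig | None = None,
) -> HybridResult:
    """Run the full hybrid pipeline on a binary mask.

    Stages: (1) FE mesh from the mask (smoothed per config); (2) MPU mesh
    from the boundary point cloud; (3) triangle matching, selection and
    point merging; (4) MPU refit on the merged cloud with a small tolerance
    and final polygonization.  Deterministic throughout.  Errors from a
    stage are re-raised tagged with the stage name.
    """
    cfg = config if config is not None else RunConfig()
    stage = "fe"
    try:
        fe_mesh = isosurface.extract_from_mask(
            seg_volume, isovalue=cfg.isovalue, pad=cfg.pad_mask
        )
        if cfg.smoothing.enabled:
            fe_mesh = isosurface.smooth_mesh(
                fe_mesh, cfg.smoothing.iterations, cfg.smoothing.lamb, cfg.smoothing.mu
            )

        stage = "mpu"
        seg_points = extract_boundary_points(seg_volume, sigma=cfg.normal_sigma)
        resolution = cfg.mpu.resolution
        if resolution is None:
            resolution = 0.5 * float(seg_volume.spacing.min())
        model = mpu.build_mpu(
            seg_points, tol=cfg.mpu.tol, max_depth=cfg.mpu.max_depth,
            alpha=cfg.mpu.alpha, n_min=cfg.mpu.n_min,
        )
        mpu_mesh = mpu.polygonize(model, resolution)

        stage = "match"
        rows = match_triangles(mpu_mesh, fe_mesh, seg_points, cfg.hybrid.tie_rule)
        kept_mpu, kept_fe, deltas = select_triangles(rows)
        if cfg.hybrid.symmetric:
            # optional union with the reverse direction (FE -> MPU)
            rev = match_triangles(fe_mesh, mpu_mesh, seg_points, cfg.hybrid.tie_rule)
            rev_fe = np.array(
                sorted(r.mpu_triangle for r in rev if r.winner == "MPU"), dtype=np.int64
            )  # roles swapped: "MPU" rows are FE triangles here
            rev_mpu = np.unique(
                np.array([r.fe_triangle for r in rev if r.winner == "FE"], dtype=np.int64)
            )
            kept_fe = np.union1d(kept_fe, rev_fe)
            kept_mpu = np.union1d(kept_mpu, rev_mpu)

        stage = "merge"
        merged = merge_and_extract_points(
            mpu_mesh, fe_mesh, kept_mpu, kept_fe, cfg.hybrid.weld_tol
        )

        stage = "refit"
        refit_tol = cfg.hybrid.refit_tol
        if refit_tol is None:
            refit_tol = 0.25 * float(seg_volume.spacing.min())
        refit = mpu.build_mpu(
            merged, tol=refit_tol, max_depth=cfg.mpu.max_depth,
            alpha=cfg.mpu.alpha, n_min=cfg.mpu.n_min,
        )
        final = mpu.polygonize(refit, resolution)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    n_rows = len(rows)
    d_mpu = np.array([r.d_mpu for r in rows])
    d_fe = np.array([r.d_fe for r in rows])
    report = {
        "config": cfg.to_dict(),
        "stages": {
            "fe": {"vertices": fe_mesh.n_vertices, "triangles": fe_mesh.n_faces},
            "mpu": {
                "vertices": mpu_mesh.n_vertices,
                "triangles": mpu_mesh.n_faces,
                "leaves": len(model.leaves),
            },
            "match": {
                "rows": n_rows,
                "winner_fraction_mpu": float((d_mpu < d_fe).mean()),
                "winner_fraction_fe": float((d_fe <= d_mpu).mean()),
                "mean_d_mpu": float(d_mpu.mean()),
                "mean_d_fe": float(d_fe.mean()),
                "mean_delta": float(deltas.mean()),
            },
            "merge": {
                "kept_mpu_triangles": int(len(kept_mpu)),
                "kept_fe_triangles": int(len(kept_fe)),
                "merged_points": len(merged),
            },
            "refit": {
                "tol": refit_tol,
                "leaves": len(refit.leaves),
                "vertices": final.n_vertices,
                "triangles": final.n_faces,
            },
        },
    }
    return HybridResult(final, fe_mesh, mpu_mesh, seg_points, rows, report)


def reconstruct(
    seg_volume: SegmentationVolume,
    method: str = "hybrid",
    config: RunConfig | None = None,
) -> tuple[TriangleMesh, dict]:
    """Reconstruct with one of the three methods: 'fe', 'mpu' or 'hybrid'."""
    cfg = config if config is not None else RunConfig()
    if method == "fe":
        mesh = isosurface.extract_from_mask(seg_volume, cfg.isovalue, cfg.pad_mask)
        if cfg.smoothing.enabled:
            mesh = isosurface.smooth_mesh(
                mesh, cfg.smoothing.iterations, cfg.smoothing.lamb, cfg.smoothing.mu
            )
        return mesh, {"config": cfg.to_dict(), "method": "fe",
                      "triangles": mesh.n_faces, "vertices": mesh.n_vertices}
    if method == "mpu":
        pts = extract_boundary_points(seg_volume, sigma=cfg.normal_sigma)
        model = mpu.build_mpu(pts, tol=cfg.mpu.tol, max_depth=cfg.mpu.max_depth,
                              alpha=cfg.mpu.alpha, n_min=cfg.mpu.n_min)
        resolution = cfg.mpu.resolution
        if resolution is None:
            resolution = 0.5 * float(seg_volume.spacing.min())
        mesh = mpu.polygonize(model, resolution)
        return mesh, {"config": cfg.to_dict(), "method": "mpu",
                      "triangles": mesh.n_faces, "vertices": mesh.n_vertices,
                      "leaves": len(model.leaves)}
    if method == "hybrid":
        result = hybrid_reconstruct(seg_volume, cfg)
        return result.mesh, result.report
    raise ValueError(f"unknown method {method!r}; choose fe, mpu or hybrid")
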