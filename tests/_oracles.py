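"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct method available —
exhaustive loops, closed forms — staying independent of the library code
paths it checks (the marching-cubes reference shares only the case table,
which is the contract under test, not the traversal).
"""

from __future__ import annotations

import numpy as np

from hybridsurf.mc_tables import CORNER_OFFSETS, EDGE_CORNERS, TRI_TABLE


def brute_force_boundary(grid: np.ndarray) -> np.ndarray:
    """All foreground voxels with a background 6-neighbor, by triple loop."""
    nx, ny, nz = grid.shape
    out = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not grid[i, j, k]:
                    continue
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + d[0], j + d[1], k + d[2]
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not grid[a, b, c]:
                        out.append((i, j, k))
                        break
    return np.array(out, dtype=np.int64).reshape(-1, 3)


def brute_force_edge_flags(values: np.ndarray, iso: float):
    """Exhaustive endpoint comparison for every x/y/z grid edge."""
    inside = values >= iso
    nx, ny, nz = values.shape
    ex = np.zeros((nx - 1, ny, nz), dtype=bool)
    ey = np.zeros((nx, ny - 1, nz), dtype=bool)
    ez = np.zeros((nx, ny, nz - 1), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if i + 1 < nx:
                    ex[i, j, k] = inside[i, j, k] != inside[i + 1, j, k]
                if j + 1 < ny:
                    ey[i, j, k] = inside[i, j, k] != inside[i, j + 1, k]
                if k + 1 < nz:
                    ez[i, j, k] = inside[i, j, k] != inside[i, j, k + 1]
    return ex, ey, ez


def naive_marching_cubes(values: np.ndarray, iso: float, spacing, origin) -> np.ndarray:
    """Exhaustive per-cube extraction: (T, 3, 3) triangle corner positions.

    Visits every cube independently, recomputes each vertex by direct
    interpolation (no shared-edge indexing, no metadata passes).
    """
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = values.shape
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                base = np.array([i, j, k])
                corner_vals = [values[tuple(base + off)] for off in CORNER_OFFSETS]
                case = 0
                for c, v in enumerate(corner_vals):
                    if v >= iso:
                        case |= 1 << c
                for tri in TRI_TABLE[case]:
                    pts = []
                    for e in tri:
                        a, b = EDGE_CORNERS[e]
                        va, vb = corner_vals[a], corner_vals[b]
                        t = (iso - va) / (vb - va)
                        p = base + CORNER_OFFSETS[a] + t * (CORNER_OFFSETS[b] - CORNER_OFFSETS[a])
                        pts.append(origin + p * spacing)
                    pts = np.asarray(pts)
                    area = 0.5 * np.linalg.norm(
                        np.cross(pts[1] - pts[0], pts[2] - pts[0])
                    )
                    if area > 1e-12 * float(spacing.max()) ** 2:
                        tris.append(pts)
    return np.asarray(tris, dtype=float).reshape(-1, 3, 3)


def triangle_multiset(tri_corners: np.ndarray, decimals: int = 9) -> set:
    """Canonical vertex-order-independent representation of a triangle soup."""
    out = []
    for t in np.round(tri_corners, decimals):
        out.append(tuple(sorted(map(tuple, t))))
    return set(out)


def oracle_point_triangle(p: np.ndarray, tri: np.ndarray) -> float:
    """Closest-distance via the 7-candidate construction (3 vertices, 3
    clamped edge projections, in-triangle plane projection)."""
    a, b, c = tri
    cands = [a, b, c]
    for u, v in ((a, b), (a, c), (b, c)):
        d = v - u
        s = float(np.clip(np.dot(p - u, d) / np.dot(d, d), 0.0, 1.0))
        cands.append(u + s * d)
    n = np.cross(b - a, c - a)
    nn = float(n @ n)
    if nn > 0:
        q = p - (np.dot(p - a, n) / nn) * n
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if den > 0:
            w1 = (d11 * d20 - d01 * d21) / den
            w2 = (d00 * d21 - d01 * d20) / den
            if w1 >= 0 and w2 >= 0 and w1 + w2 <= 1:
                cands.append(q)
    return min(float(np.linalg.norm(p - x)) for x in cands)


def brute_force_point_mesh(points: np.ndarray, tri_corners: np.ndarray) -> np.ndarray:
    return np.array(
        [min(oracle_point_triangle(p, t) for t in tri_corners) for p in points]
    )


def brute_force_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Double-loop symmetric Hausdorff distance."""
    def directed(X, Y):
        worst = 0.0
        for x in X:
            best = min(float(np.linalg.norm(x - y)) for y in Y)
            worst = max(worst, best)
        return worst

    return max(directed(A, B), directed(B, A))
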