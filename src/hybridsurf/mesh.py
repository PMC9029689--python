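"""Indexed triangle mesh in world (mm) coordinates.

The container shared by all three reconstruction paths.  Geometry lives in
plain numpy arrays; file I/O and generic mesh algorithms are delegated to
:mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class TriangleMesh:
    """Triangle mesh with vertices in world millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (T, 3) int array
        Vertex indices; orientation is counter-clockwise seen from outside.
    vertex_normals : (V, 3) float array, optional
        Unit outward normals; computed lazily when absent.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> np.ndarray:
        """(T, 3, 3) array of triangle corner positions."""
        return self.vertices[self.faces]

    def centroids(self) -> np.ndarray:
        return self.triangle_corners().mean(axis=1)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals and triangle areas (mm^2)."""
        tc = self.triangle_corners()
        cross = np.cross(tc[:, 1] - tc[:, 0], tc[:, 2] - tc[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        areas = 0.5 * norm
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / np.where(norm > 0, norm, 1.0)[:, None]
        return normals, areas

    def area(self) -> float:
        return float(self.face_normals_areas()[1].sum())

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, renormalized."""
        fn, areas = self.face_normals_areas()
        acc = np.zeros_like(self.vertices)
        w = fn * areas[:, None]
        for c in range(3):
            np.add.at(acc, self.faces[:, c], w)
        norm = np.linalg.norm(acc, axis=1)
        acc /= np.where(norm > 0, norm, 1.0)[:, None]
        self.vertex_normals = acc
        return acc

    def edges(self) -> np.ndarray:
        """(3T, 2) undirected edges, lower index first."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def edge_face_counts(self) -> np.ndarray:
        """Per-unique-edge incident-triangle counts (2 everywhere = watertight)."""
        _, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return counts

    def is_watertight(self) -> bool:
        counts = self.edge_face_counts()
        return bool(len(counts)) and bool((counts == 2).all())

    def euler_characteristic(self) -> int:
        n_edges = len(np.unique(self.edges(), axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def connected_component_count(self) -> int:
        return len(self.to_trimesh().split(only_watertight=False))

    def volume(self) -> float:
        """Signed volume (positive for outward orientation), mm^3."""
        tc = self.triangle_corners()
        return float(np.einsum("ij,ij->i", tc[:, 0], np.cross(tc[:, 1], tc[:, 2])).sum() / 6.0)

    # -- interop ------------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))

    def save(self, path) -> None:
        """Write PLY / OBJ / STL, chosen by extension."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path) -> "TriangleMesh":
        tm = trimesh.load(str(path), process=False, force="mesh")
        return cls.from_trimesh(tm)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
        )
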