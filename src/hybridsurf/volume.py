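"""Binary segmentation volumes, boundary points and normals.

World coordinates use the voxel-center convention: voxel (i, j, k) sits at
``origin + (i, j, k) * spacing`` with 0-based indices, all in millimetres.
Anisotropic spacing (e.g. the common 1:1.3 in-plane-to-slice ratio of MR
acquisitions) is carried through every computation.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateMaskError(ValueError):
    """Mask is all-background or all-foreground: it has no boundary."""


class UnsupportedVolumeError(ValueError):
    """The file does not contain a single-channel 3D scalar volume."""


_NEIGHBOR_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


@dataclass
class SegmentationVolume:
    """Binary occupancy grid with voxel spacing and world origin."""

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise UnsupportedVolumeError(
                f"expected a 3D volume, got shape {self.grid.shape}"
            )
        uniq = np.unique(self.grid)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("grid values must be exactly 0 or 1")
        self.grid = self.grid.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if (self.spacing <= 0).any():
            raise ValueError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World mm position of voxel centers for (N, 3) integer indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def boundary_mask(self) -> np.ndarray:
        """Foreground voxels with >= 1 background 6-neighbor (out-of-bounds
        counts as background, so border-touching objects keep a boundary)."""
        fg = self.grid.astype(bool)
        padded = np.pad(fg, 1, mode="constant", constant_values=False)
        has_bg = np.zeros_like(fg)
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            sl = tuple(slice(1 + d, s + 1 + d) for d, s in zip((dx, dy, dz), fg.shape))
            has_bg |= ~padded[sl]
        return fg & has_bg


@dataclass
class BoundaryPointSet:
    """Voxel-center points on the segmentation boundary with outward normals."""

    points: np.ndarray
    normals: np.ndarray
    source_voxel: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if len(self.points) != len(self.normals):
            raise ValueError("points and normals length mismatch")
        if self.source_voxel is not None:
            self.source_voxel = np.asarray(self.source_voxel, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    def export_ply(self, path) -> None:
        """ASCII PLY point cloud with per-point normals."""
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self)}\n")
            for prop in ("x", "y", "z", "nx", "ny", "nz"):
                fh.write(f"property float {prop}\n")
            fh.write("end_header\n")
            for p, n in zip(self.points, self.normals):
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")


# ---------------------------------------------------------------------------
# file I/O


def _read_nrrd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimal NRRD reader: raw / gzip encodings, 3D scalar data."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise UnsupportedVolumeError(f"{path}: not a NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, val = text.partition(":")
            header[key.strip().lower()] = val.lstrip("= ").strip()
        payload = fh.read()

    sizes = tuple(int(s) for s in header["sizes"].split())
    dtype = np.dtype(
        {
            "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "int8": "i1",
            "short": "i2", "unsigned short": "u2", "uint16": "u2", "int16": "i2",
            "int": "i4", "unsigned int": "u4", "int32": "i4", "uint32": "u4",
            "float": "f4", "double": "f8",
        }[header["type"]]
    )
    if header.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    encoding = header.get("encoding", "raw")
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise UnsupportedVolumeError(f"{path}: unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    # NRRD is fastest-axis-first
    array = data.reshape(sizes[::-1]).transpose(range(len(sizes))[::-1])

    spacing = np.ones(3)
    origin = np.zeros(3)
    if "spacings" in header:
        spacing = np.array([float(s) for s in header["spacings"].split()][:3])
    elif "space directions" in header:
        dirs = [
            d for d in header["space directions"].replace("(", " ").replace(")", " ").split()
            if d and d != "none"
        ]
        mat = np.array([float(v) for v in ",".join(dirs).split(",") if v]).reshape(-1, 3)
        spacing = np.linalg.norm(mat, axis=1)[:3]
    if "space origin" in header:
        origin = np.array(
            [float(v) for v in header["space origin"].strip("() ").split(",")]
        )[:3]
    return array, spacing, origin


def _write_nrrd(path, grid: np.ndarray, spacing, origin) -> None:
    header = (
        "NRRD0004\n"
        "type: uchar\n"
        "dimension: 3\n"
        f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        "encoding: gzip\n"
        "endian: little\n"
        f"spacings: {spacing[0]} {spacing[1]} {spacing[2]}\n"
        f"space origin: ({origin[0]},{origin[1]},{origin[2]})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(gzip.compress(np.ascontiguousarray(grid.transpose(2, 1, 0)).tobytes()))


def load_mask(path) -> SegmentationVolume:
    """Load a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) binary mask.

    Non-binary values are binarized as ``value > 0.5``.  Spacing and origin
    come from the header; the voxel axis order of the file is kept.
    """
    name = str(path)
    if name.endswith(".nrrd"):
        data, spacing, origin = _read_nrrd(name)
    else:
        import nibabel as nib

        img = nib.load(name)
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    if data.ndim != 3:
        raise UnsupportedVolumeError(
            f"{path}: expected a 3D scalar volume, got shape {data.shape}"
        )
    grid = (data.astype(float) > 0.5).astype(np.uint8)
    return SegmentationVolume(grid, spacing, origin)


def save_mask(volume: SegmentationVolume, path) -> None:
    """Write a mask as NIfTI or NRRD, chosen by extension."""
    name = str(path)
    if name.endswith(".nrrd"):
        _write_nrrd(name, volume.grid, volume.spacing, volume.origin)
        return
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.grid.astype(np.uint8), affine), name)


# ---------------------------------------------------------------------------
# boundary points and normals


def extract_boundary_points(
    volume: SegmentationVolume, sigma: float = 1.0
) -> BoundaryPointSet:
    """Voxel centers of all foreground voxels with a background 6-neighbor.

    Normals are attached by :func:`estimate_normals` with the given Gaussian
    width (in voxels).
    """
    n_fg = int(volume.grid.sum())
    if n_fg == 0 or n_fg == volume.grid.size:
        raise DegenerateMaskError(
            "mask is all-background or all-foreground; no boundary exists"
        )
    voxels = np.argwhere(volume.boundary_mask())
    points = volume.world_coordinates(voxels)
    pts = BoundaryPointSet(points, np.zeros_like(points), voxels)
    return estimate_normals(volume, pts, sigma=sigma)


def estimate_normals(
    volume: SegmentationVolume, points: BoundaryPointSet, sigma: float = 1.0
) -> BoundaryPointSet:
    """Outward unit normals from the binary volume.

    The occupancy grid is Gaussian-smoothed (``sigma`` in voxels) and the
    normal is the normalized *negative* gradient sampled by central
    differences at each source voxel — pointing from foreground toward
    background.  Per-axis spacing divides the differences, so anisotropic
    voxels give geometrically correct directions.  Voxels with a vanishing
    gradient (isolated voxels at sigma=0) fall back to the mean direction
    toward their background 6-neighbors.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if points.source_voxel is None:
        raise ValueError("points must carry source voxels")
    occ = volume.grid.astype(float)
    # nearest-mode padding keeps planar symmetry exact near grid borders
    smooth = ndimage.gaussian_filter(occ, sigma=sigma, mode="nearest") if sigma > 0 else occ
    grads = np.gradient(smooth, *volume.spacing)  # central differences / spacing
    vox = points.source_voxel
    g = np.stack([grads[a][vox[:, 0], vox[:, 1], vox[:, 2]] for a in range(3)], axis=1)
    normals = -g
    norm = np.linalg.norm(normals, axis=1)

    weak = norm < 1e-12
    if weak.any():
        padded = np.pad(volume.grid.astype(bool), 1, constant_values=False)
        for row in np.nonzero(weak)[0]:
            i, j, k = vox[row]
            direction = np.zeros(3)
            for off in _NEIGHBOR_OFFSETS:
                if not padded[i + 1 + off[0], j + 1 + off[1], k + 1 + off[2]]:
                    direction += off * volume.spacing
            if np.linalg.norm(direction) < 1e-12:
                if sigma == 0:
                    raise ValueError(
                        f"cannot orient normal at voxel ({i}, {j}, {k}): "
                        "zero gradient and symmetric background neighborhood"
                    )
                # perfectly symmetric isolated voxel: every direction is
                # equally (in)valid; pick +z deterministically
                warnings.warn(
                    f"arbitrary normal assigned at symmetric voxel ({i}, {j}, {k})",
                    stacklevel=2,
                )
                direction = np.array([0.0, 0.0, 1.0])
            normals[row] = direction
            norm[row] = np.linalg.norm(direction)
    normals = normals / norm[:, None]
    return BoundaryPointSet(points.points, normals, vox)


# ---------------------------------------------------------------------------
# contour stacks


def contours_to_points(
    contours: list[dict],
    spacing,
    origin=(0.0, 0.0, 0.0),
    grid_shape: tuple[int, int, int] | None = None,
    sigma: float = 1.0,
) -> tuple[BoundaryPointSet, SegmentationVolume]:
    """Convert per-slice pixel contours into oriented 3D boundary points.

    Each contour is ``{"slice": int, "pixels": [[x, y], ...]}`` in pixel
    coordinates; the 3D point of pixel (x, y) on slice s is
    ``origin + (x * sx, y * sy, s * sz)``.  Contours are also rasterized
    (scanline fill per slice) into a :class:`SegmentationVolume` from which
    the point normals are estimated.  Self-intersecting contours raise a
    warning and are filled as-is.
    """
    from skimage.draw import polygon2mask

    if not contours:
        raise ValueError("empty contour list")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)

    all_xy = []
    for c in contours:
        px = np.asarray(c["pixels"], dtype=float).reshape(-1, 2)
        if len(px) < 3:
            raise ValueError("each contour needs >= 3 pixels")
        if int(c["slice"]) != c["slice"]:
            raise ValueError("slice indices must be integers")
        all_xy.append(px)

    slices = np.array([int(c["slice"]) for c in contours])
    if grid_shape is None:
        max_x = int(np.ceil(max(p[:, 0].max() for p in all_xy))) + 2
        max_y = int(np.ceil(max(p[:, 1].max() for p in all_xy))) + 2
        grid_shape = (max_x, max_y, int(slices.max()) + 2)

    grid = np.zeros(grid_shape, dtype=np.uint8)
    points = []
    voxels = []
    for c, px in zip(contours, all_xy):
        s = int(c["slice"])
        try:
            from shapely.geometry import Polygon

            if not Polygon(px).is_valid:
                warnings.warn(
                    f"self-intersecting contour on slice {s}; filling as drawn",
                    stacklevel=2,
                )
        except Exception:  # pragma: no cover - shapely is optional here
            pass
        mask2d = polygon2mask(grid_shape[:2], px)  # rows = x, cols = y
        grid[:, :, s] |= mask2d.astype(np.uint8)
        pts3 = np.column_stack([px[:, 0], px[:, 1], np.full(len(px), s, dtype=float)])
        points.append(origin + pts3 * spacing)
        voxels.append(np.column_stack([np.rint(px).astype(np.int64), np.full(len(px), s, dtype=np.int64)]))

    volume = SegmentationVolume(grid, spacing, origin)
    pts = BoundaryPointSet(
        np.concatenate(points), np.zeros((sum(map(len, points)), 3)), np.concatenate(voxels)
    )
    pts = estimate_normals(volume, pts, sigma=sigma)
    return pts, volume
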