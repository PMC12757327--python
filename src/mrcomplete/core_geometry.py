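"""Point-cloud data model, file I/O, preprocessing and dataset splitting.

A :class:`PointCloud` is an ordered array of 3D coordinates; order is
preserved by I/O (scanners emit points in acquisition order and duplicate
returns are legitimate data). Preprocessing follows the usual completion
pipeline convention: recenter on the axis-aligned bounding-box midpoint,
then scale by half the longest-axis extent so the cloud is bounded by
(-1, 1) and touches ±1 on its longest axis.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PointCloud",
    "BoundingBox",
    "DatasetSplit",
    "read_cloud",
    "write_cloud",
    "center",
    "normalize",
    "random_rotation_augment",
    "rotation_from_angles",
    "split_dataset",
]


class CloudParseError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


@dataclass
class PointCloud:
    """An ordered set of 3D points.

    Parameters
    ----------
    points
        ``(n, 3)`` float array. Coordinates are unitless after
        normalization, raw scanner units before.
    label
        Optional object-class tag (models are trained per class).
    source
        Optional provenance (file path or generator description).
    """

    points: np.ndarray
    label: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a point cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """A copy of this cloud with replaced coordinates, keeping metadata."""
        return PointCloud(points, label=self.label, source=self.source)

    def bounding_box(self) -> "BoundingBox":
        return BoundingBox(self.points.min(axis=0), self.points.max(axis=0))


@dataclass
class BoundingBox:
    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, dtype=np.float64)
        self.max_corner = np.asarray(self.max_corner, dtype=np.float64)
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")

    @property
    def midpoint(self) -> np.ndarray:
        return self.min_corner + (self.max_corner - self.min_corner) / 2.0

    @property
    def extent(self) -> np.ndarray:
        return self.max_corner - self.min_corner


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    seed: int

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.val), set(self.test)]
        total = len(self.train) + len(self.val) + len(self.test)
        union = set().union(*groups)
        if len(union) != total:
            raise ValueError("split partitions must be pairwise disjoint")

    def to_json(self) -> str:
        return json.dumps(
            {"train": list(self.train), "val": list(self.val),
             "test": list(self.test), "seed": self.seed},
            indent=2,
        )


# ---------------------------------------------------------------------------
# File I/O: XYZ text dialect and vertex-only PLY.
# ---------------------------------------------------------------------------

def _coords(cloud) -> np.ndarray:
    """Accept a PointCloud or an (n, 3) array-like; return float64 array."""
    if isinstance(cloud, PointCloud):
        return cloud.points
    pts = np.asarray(cloud, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {pts.shape}")
    return pts


def _read_xyz(path: str) -> np.ndarray:
    rows = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 3:
                raise CloudParseError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise CloudParseError(
                    f"{path}:{lineno}: non-numeric coordinate in {body!r}"
                ) from None
    if not rows:
        raise CloudParseError(f"{path}: no points found")
    return np.asarray(rows, dtype=np.float64)


def _read_ply(path: str) -> np.ndarray:
    # trimesh handles both ascii and binary-little-endian PLY.
    import trimesh

    loaded = trimesh.load(path, file_type="ply", process=False)
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 3 or verts.shape[0] == 0:
        raise CloudParseError(f"{path}: PLY file contains no vertices")
    return verts


def read_cloud(path: str, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from an XYZ text file or a PLY file.

    Points are returned in file order; no reordering or deduplication.
    ``format`` is inferred from the extension when omitted.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = ext if ext in ("xyz", "ply") else "xyz"
    if format == "xyz":
        pts = _read_xyz(path)
    elif format == "ply":
        pts = _read_ply(path)
    else:
        raise ValueError(f"unknown point-cloud format {format!r}")
    return PointCloud(pts, source=str(path))


def write_cloud(cloud, path: str, format: Optional[str] = None) -> None:
    """Write a cloud as XYZ text (9 significant digits) or ascii PLY."""
    pts = _coords(cloud)
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = ext if ext in ("xyz", "ply") else "xyz"
    if format == "xyz":
        with open(path, "w") as fh:
            for x, y, z in pts:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    elif format == "ply":
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(pts)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "end_header\n"
            )
            for x, y, z in pts:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    else:
        raise ValueError(f"unknown point-cloud format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def center(cloud: PointCloud) -> PointCloud:
    """Recenter on the bounding-box midpoint.

    The per-axis offset is ``min + (max - min)/2`` — the box midpoint, not
    the centroid; the two differ for clouds with asymmetric point density.
    """
    pts = _coords(cloud)
    mid = pts.min(axis=0) + (pts.max(axis=0) - pts.min(axis=0)) / 2.0
    out = pts - mid
    if isinstance(cloud, PointCloud):
        return cloud.with_points(out)
    return PointCloud(out)


def normalize(cloud: PointCloud, *, center_tol: float = 1e-6) -> PointCloud:
    """Scale a centered cloud into the (-1, 1) box.

    Divides by half the extent of the longest axis, so the cloud touches
    ±1 on that axis and stays within ±1 on the others.
    """
    pts = _coords(cloud)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    mid = lo + (hi - lo) / 2.0
    extent = hi - lo
    scale = float(extent.max()) / 2.0
    if scale <= 0.0:
        raise ValueError("degenerate cloud: all points identical, no scale defined")
    if np.abs(mid).max() > center_tol * max(1.0, scale):
        raise ValueError(
            "cloud is not centered (bounding-box midpoint "
            f"{mid} exceeds tolerance); call center() first"
        )
    out = pts / scale
    if isinstance(cloud, PointCloud):
        return cloud.with_points(out)
    return PointCloud(out)


def rotation_from_angles(angles: Sequence[float]) -> np.ndarray:
    """Proper rotation matrix from angles about x, y, z (applied x→y→z)."""
    return Rotation.from_euler("xyz", angles).as_matrix()


def random_rotation_augment(
    cloud: PointCloud, seed: int, angles: Optional[Sequence[float]] = None
) -> PointCloud:
    """Rotate a cloud about the origin by seeded random Euler angles.

    Three independent angles are drawn uniformly from [0, 2π) and composed
    in x→y→z order; ``angles`` overrides the draw (used for deterministic
    augmentation recipes). The transform is a proper rotation (det = +1),
    so all pairwise distances are preserved.
    """
    pts = _coords(cloud)
    if angles is None:
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0.0, 2.0 * math.pi, size=3)
    rot = rotation_from_angles(angles)
    out = pts @ rot.T
    if isinstance(cloud, PointCloud):
        return cloud.with_points(out)
    return PointCloud(out)


def split_dataset(ids: Iterable, seed: int) -> DatasetSplit:
    """Shuffle and split identifiers 60/20/20 into train/val/test.

    ``floor(0.6 n)`` to train, ``floor(0.2 n)`` to val, remainder to test.
    Requires at least 5 identifiers so every partition is non-empty.
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 identifiers to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = int(math.floor(0.6 * n))
    n_val = int(math.floor(0.2 * n))
    return DatasetSplit(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
    )
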