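"""Procedural cartons, parametric plants, and LiDAR-like partial scans.

The generators emulate a desk-scale scanning benchmark: carton (box)
surfaces and simulated plants (a vertical stem with attached branch
cylinders and elliptical leaf discs), each emitted as a centered cloud
normalized to the (-1, 1) box at a fixed point count. Partial
observations are produced the way terrestrial LiDAR degrades real
scans — an occlusion mask (half-space crop or back-hemisphere removal),
a sparsity schedule (seeded uniform thinning), and isotropic Gaussian
measurement noise, applied in that order.

Plant presets 1..5 increase structural complexity (branch and leaf
count), spanning straightforward external contours to intricate ones.
No claim of botanical realism is made: the plants are cylinders and
discs, standing in for scanned artificial plants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core_geometry import PointCloud, _coords, center, normalize

__all__ = [
    "ShapeSpec",
    "PlantParams",
    "ScanSpec",
    "make_carton",
    "make_plant",
    "plant_preset",
    "simulate_partial_scan",
    "carton_dataset",
    "plant_dataset",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class PlantParams:
    """Morphology of a procedural plant.

    Units are arbitrary pre-normalization lengths; the stem is vertical
    (z axis). Branches attach at evenly spread heights on the upper stem
    with golden-angle azimuths; each branch tip may carry one elliptical
    leaf disc.
    """

    stem_height: float = 1.6
    stem_radius: float = 0.05
    branch_count: int = 4
    branch_length: float = 0.55
    branch_radius: float = 0.02
    branch_angle: float = math.radians(55.0)  # elevation from the stem axis
    leaf_count: int = 4
    leaf_size: float = 0.16  # semi-major axis of the leaf ellipse

    def __post_init__(self) -> None:
        if self.stem_height <= 0 or self.stem_radius <= 0:
            raise ValueError("stem dimensions must be positive")
        if self.branch_count < 0 or self.leaf_count < 0:
            raise ValueError("branch and leaf counts must be nonnegative")
        if self.branch_count > 0 and (
            self.branch_length <= 0 or self.branch_radius <= 0
        ):
            raise ValueError("branch dimensions must be positive")
        if self.leaf_count > self.branch_count:
            raise ValueError("at most one leaf per branch tip")
        if self.leaf_count > 0 and self.leaf_size <= 0:
            raise ValueError("leaf size must be positive")


@dataclass
class ShapeSpec:
    """Recipe for one synthetic complete shape."""

    kind: str  # "carton" | "plant"
    n_points: int = 2048
    carton_extents: Tuple[float, float, float] = (1.0, 0.7, 0.5)
    plant_params: PlantParams = field(default_factory=PlantParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("carton", "plant"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.n_points < 512:
            raise ValueError("n_points must be at least 512")
        if self.kind == "carton" and any(e <= 0 for e in self.carton_extents):
            raise ValueError("carton extents must be positive")


@dataclass
class ScanSpec:
    """Degradation recipe for a LiDAR-like partial observation.

    ``occlusion`` is ``None`` (no occlusion), ``("halfspace", normal,
    offset)`` — drop points with ``p·normal > offset`` — or
    ``("viewpoint", direction)`` — keep the hemisphere facing the
    scanner direction. ``sparsity`` is the keep-fraction ρ ∈ (0, 1];
    ``noise_sigma`` the isotropic Gaussian noise sd added last.
    """

    occlusion: Optional[tuple] = None
    sparsity: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity keep-fraction must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.occlusion is not None:
            kind = self.occlusion[0]
            if kind not in ("halfspace", "viewpoint"):
                raise ValueError(f"unknown occlusion kind {kind!r}")


def _allocate(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` points by weight."""
    weights = np.asarray(weights, dtype=np.float64)
    shares = weights / weights.sum() * total
    counts = np.floor(shares).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(shares - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def make_carton(spec: ShapeSpec) -> PointCloud:
    """Box-surface cloud: points sampled uniformly by area over 6 faces.

    Every emitted point lies on a face, so (pre-normalization) at least
    one coordinate equals ± the axis half-extent exactly.
    """
    if spec.kind != "carton":
        raise ValueError("spec.kind must be 'carton'")
    ex = np.asarray(spec.carton_extents, dtype=np.float64)
    half = ex / 2.0
    rng = np.random.default_rng(spec.seed)
    # face areas: two faces per axis, area = product of the other extents
    areas = np.array([ex[1] * ex[2], ex[1] * ex[2],
                      ex[0] * ex[2], ex[0] * ex[2],
                      ex[0] * ex[1], ex[0] * ex[1]])
    counts = _allocate(areas, spec.n_points)
    pts = []
    for face, cnt in enumerate(counts):
        axis, sign = divmod(face, 2)
        others = [a for a in range(3) if a != axis]
        p = np.empty((cnt, 3))
        p[:, axis] = half[axis] if sign == 0 else -half[axis]
        for o in others:
            p[:, o] = rng.uniform(-half[o], half[o], size=cnt)
        pts.append(p)
    cloud = PointCloud(np.concatenate(pts), label="carton",
                       source=f"carton(seed={spec.seed})")
    return normalize(center(cloud))


def _sample_cylinder(rng, base, axis_dir, length, radius, n):
    """Uniform points on a cylinder's lateral surface."""
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis_dir @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis_dir, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    t = rng.uniform(0.0, length, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return (
        base[None, :]
        + t[:, None] * axis_dir[None, :]
        + radius * (np.cos(phi)[:, None] * u[None, :]
                    + np.sin(phi)[:, None] * v[None, :])
    )


def _sample_leaf(rng, tip, branch_dir, size, n):
    """Uniform points on an elliptical disc attached at a branch tip."""
    branch_dir = branch_dir / np.linalg.norm(branch_dir)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(branch_dir @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = branch_dir  # leaf grows outward along the branch
    v = np.cross(branch_dir, ref)
    v /= np.linalg.norm(v)
    a, b = size, size * 0.5  # semi-axes
    r = np.sqrt(rng.uniform(0.0, 1.0, size=n))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    # centered one semi-axis beyond the tip so the disc sits on the stalk end
    return (
        tip[None, :]
        + (a * (1.0 + r * np.cos(phi)))[:, None] * u[None, :]
        + (b * r * np.sin(phi))[:, None] * v[None, :]
    )


def make_plant(spec: ShapeSpec) -> PointCloud:
    """Stem + branches + leaves cloud, centered and normalized.

    Points are allocated to components in proportion to surface area and
    sampled uniformly on each. A stem-only plant (0 branches) is a bare
    cylinder about the vertical axis.
    """
    if spec.kind != "plant":
        raise ValueError("spec.kind must be 'plant'")
    p = spec.plant_params
    rng = np.random.default_rng(spec.seed)

    components = []  # (area, sampler)
    stem_area = 2.0 * math.pi * p.stem_radius * p.stem_height
    components.append(
        (stem_area,
         lambda n: _sample_cylinder(rng, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                                    p.stem_height, p.stem_radius, n))
    )
    branch_dirs = []
    branch_tips = []
    for b in range(p.branch_count):
        azimuth = b * _GOLDEN_ANGLE + rng.uniform(-0.2, 0.2)
        frac = 0.35 + 0.6 * (b + 1) / (p.branch_count + 1)
        base = np.array([0.0, 0.0, frac * p.stem_height])
        d = np.array([
            math.sin(p.branch_angle) * math.cos(azimuth),
            math.sin(p.branch_angle) * math.sin(azimuth),
            math.cos(p.branch_angle),
        ])
        length = p.branch_length * rng.uniform(0.8, 1.2)
        branch_dirs.append(d)
        branch_tips.append(base + length * d)
        area = 2.0 * math.pi * p.branch_radius * length
        components.append(
            (area,
             lambda n, base=base, d=d, length=length: _sample_cylinder(
                 rng, base, d, length, p.branch_radius, n))
        )
    for leaf in range(p.leaf_count):
        tip = branch_tips[leaf]
        d = branch_dirs[leaf]
        area = math.pi * p.leaf_size * (p.leaf_size * 0.5)
        components.append(
            (area,
             lambda n, tip=tip, d=d: _sample_leaf(rng, tip, d, p.leaf_size, n))
        )

    counts = _allocate(np.array([c[0] for c in components]), spec.n_points)
    parts = [sampler(int(cnt)) for (area, sampler), cnt in
             zip(components, counts) if cnt > 0]
    cloud = PointCloud(np.concatenate(parts), label="plant",
                       source=f"plant(seed={spec.seed})")
    return normalize(center(cloud))


def plant_preset(level: int, seed: int = 0, n_points: int = 2048) -> ShapeSpec:
    """Plant recipe of complexity ``level`` in 1..5.

    Branch and leaf counts grow with the level, moving from simple
    contours (level 1) to intricate exteriors (level 5).
    """
    if not 1 <= level <= 5:
        raise ValueError("plant preset level must be in 1..5")
    params = PlantParams(
        branch_count=2 * level,
        leaf_count=2 * level,
        branch_length=0.55 + 0.05 * level,
        leaf_size=0.18 - 0.01 * level,
    )
    return ShapeSpec(kind="plant", n_points=n_points,
                     plant_params=params, seed=seed)


def simulate_partial_scan(cloud, scan: ScanSpec) -> PointCloud:
    """Degrade a complete cloud into a LiDAR-like partial observation.

    Order of operations: occlusion mask, then sparsity thinning (keeps
    ``ceil(ρ·n)`` of the surviving points, preserving input order), then
    Gaussian noise. With ``ρ = 1`` and ``noise_sigma = 0`` and no
    occlusion the input is returned unchanged.
    """
    pts = _coords(cloud)
    rng = np.random.default_rng(scan.seed)

    if scan.occlusion is not None:
        kind = scan.occlusion[0]
        if kind == "halfspace":
            _, normal, offset = scan.occlusion
            normal = np.asarray(normal, dtype=np.float64)
            keep = pts @ normal <= offset
        else:  # viewpoint: keep the hemisphere facing the scanner
            direction = np.asarray(scan.occlusion[1], dtype=np.float64)
            keep = pts @ direction >= 0.0
        pts = pts[keep]
        if pts.shape[0] == 0:
            raise ValueError("occlusion removed every point; empty scan")

    if scan.sparsity < 1.0:
        n_keep = int(math.ceil(scan.sparsity * pts.shape[0]))
        chosen = rng.choice(pts.shape[0], size=n_keep, replace=False)
        pts = pts[np.sort(chosen)]

    if scan.noise_sigma > 0.0:
        pts = pts + rng.normal(0.0, scan.noise_sigma, size=pts.shape)

    label = cloud.label if isinstance(cloud, PointCloud) else None
    return PointCloud(pts, label=label, source="partial_scan")


def carton_dataset(n: int, seed: int = 0, n_points: int = 2048) -> List[PointCloud]:
    """``n`` cartons with seeded random extents (edge ratios in [0.4, 1])."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        extents = tuple(rng.uniform(0.4, 1.0, size=3))
        shape_seed = int(rng.integers(0, 2**31 - 1))
        out.append(make_carton(ShapeSpec(
            kind="carton", n_points=n_points,
            carton_extents=extents, seed=shape_seed)))
    return out


def plant_dataset(n: int, preset: int, seed: int = 0,
                  n_points: int = 2048) -> List[PointCloud]:
    """``n`` plants of one complexity preset with seeded per-shape variation."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        shape_seed = int(rng.integers(0, 2**31 - 1))
        out.append(make_plant(plant_preset(preset, seed=shape_seed,
                                           n_points=n_points)))
    return out
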