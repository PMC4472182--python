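"""Synthetic contrast-enhanced hepatic-CT-like phantoms with known truth.

Real hepatic CT offers low contrast between vessels (~100–230 on the
8-bit windowed scale) and liver parenchyma, blurred vessel edges from the
partial volume effect, and noise.  The phantoms emulate exactly those
features: an analytic tree of cylindrical tube segments rasterized over a
darker background, Gaussian-blurred (partial volume: intensities fall off
from vessel center to edge), with additive per-tissue Gaussian noise.
Ground truth is the *pre-blur* analytic tube mask (voxel centers within a
segment radius), so edge-recovery comparisons between methods are
meaningful.

All randomness flows from a single integer ``rng_seed``; no global state.
Voxel centers sit at ``index * spacing`` mm (node-centered convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .scene_io import Scene, SegmentationMask

__all__ = [
    "TubeSegment",
    "PhantomSpec",
    "PhantomResult",
    "TwoSystemPhantom",
    "generate_phantom",
    "branching_tree",
    "default_branching_spec",
    "two_system_phantom",
    "spec_to_yaml",
    "spec_from_yaml",
]


@dataclass(frozen=True)
class TubeSegment:
    """A cylindrical vessel segment: endpoints in mm, radius in mm.

    ``radius_end`` enables a linear taper from ``radius`` at ``start``
    to ``radius_end`` at ``end``; by default the radius is constant.
    """

    start: Tuple[float, float, float]
    end: Tuple[float, float, float]
    radius: float
    radius_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.radius <= 0 or (self.radius_end is not None and self.radius_end <= 0):
            raise ValueError("tube radii must be > 0")


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic hepatic-CT-like volume.

    Intensities are on the 8-bit scale; the defaults place vessels at
    160 +/- 10 (inside the 100–230 vessel band) over parenchyma at
    80 +/- 10, with 0.5 mm partial-volume blur.  ``vessel_sd`` /
    ``background_sd`` model tissue noise per class; ``noise_sd`` is an
    optional extra global (scanner) noise term, off by default.
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_mean: float = 80.0
    background_sd: float = 10.0
    vessel_mean: float = 160.0
    vessel_sd: float = 10.0
    tree: List[TubeSegment] = field(default_factory=list)
    blur_sigma_mm: float = 0.5
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_mean <= self.background_mean:
            raise ValueError("vessel_mean must exceed background_mean (bright vessels)")


@dataclass
class PhantomResult:
    scene: Scene
    truth: SegmentationMask
    spec: PhantomSpec


@dataclass
class TwoSystemPhantom:
    """Two disjoint vessel trees joined by a short weak bridge strand."""

    scene: Scene
    truth: SegmentationMask          # both trees (the bridge is not truth)
    truth_a: SegmentationMask        # tree containing the suggested seed
    truth_b: SegmentationMask
    bridge_voxels: List[Tuple[int, int, int]]
    seed: Tuple[int, int, int]
    spec: PhantomSpec


def _segment_distance(points: np.ndarray, seg: TubeSegment) -> np.ndarray:
    """Distance (mm) from each point to the segment axis, and local radius."""
    p0 = np.asarray(seg.start, dtype=np.float64)
    p1 = np.asarray(seg.end, dtype=np.float64)
    axis = p1 - p0
    length2 = float(axis @ axis)
    if length2 == 0:
        t = np.zeros(len(points))
    else:
        t = np.clip((points - p0) @ axis / length2, 0.0, 1.0)
    closest = p0 + t[:, None] * axis
    dist = np.linalg.norm(points - closest, axis=1)
    if seg.radius_end is None:
        radius = np.full_like(dist, seg.radius)
    else:
        radius = seg.radius + t * (seg.radius_end - seg.radius)
    return dist, radius


def rasterize_tree(
    tree: Sequence[TubeSegment],
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within radius of any segment."""
    mask = np.zeros(shape, dtype=bool)
    spacing = np.asarray(spacing, dtype=np.float64)
    for seg in tree:
        r_max = max(seg.radius, seg.radius_end or 0.0)
        lo_mm = np.minimum(seg.start, seg.end) - r_max
        hi_mm = np.maximum(seg.start, seg.end) + r_max
        lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
        hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        dist, radius = _segment_distance(idx * spacing, seg)
        inside = dist <= radius
        mask[tuple(idx[inside].T)] = True
    return mask


def _check_tree_inside(spec: PhantomSpec) -> None:
    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    for seg in spec.tree:
        r = max(seg.radius, seg.radius_end or 0.0)
        for point in (seg.start, seg.end):
            p = np.asarray(point, dtype=np.float64)
            if np.any(p - r < 0) or np.any(p + r > extent):
                raise ValueError(f"tube segment {seg} extends outside the volume")


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render a spec: rasterize, blur (partial volume), add noise, clamp to 8 bits.

    Deterministic given ``spec.rng_seed``.  The returned truth mask is the
    pre-blur analytic tube set.
    """
    if not spec.tree:
        raise ValueError("phantom spec has an empty vessel tree")
    _check_tree_inside(spec)
    truth = rasterize_tree(spec.tree, spec.shape, spec.spacing)
    ideal = np.where(truth, spec.vessel_mean, spec.background_mean).astype(np.float64)
    if spec.blur_sigma_mm > 0:
        sigma_vox = [spec.blur_sigma_mm / s for s in spec.spacing]
        image = ndimage.gaussian_filter(ideal, sigma=sigma_vox)
    else:
        image = ideal
    rng = np.random.default_rng(spec.rng_seed)
    sd_field = np.where(truth, spec.vessel_sd, spec.background_sd)
    if np.any(sd_field > 0):
        image = image + rng.standard_normal(spec.shape) * sd_field
    if spec.noise_sd > 0:
        image = image + rng.standard_normal(spec.shape) * spec.noise_sd
    values = np.floor(np.clip(image, 0.0, 255.0) + 0.5).astype(np.uint8)
    scene = Scene(values, spec.spacing)
    return PhantomResult(scene, SegmentationMask(truth, spec.spacing), spec)


def _orthonormal(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def branching_tree(
    root: Tuple[float, float, float] = (32.0, 32.0, 6.0),
    direction: Tuple[float, float, float] = (0.0, 0.0, 1.0),
    levels: int = 3,
    trunk_length: float = 22.0,
    trunk_radius: float = 3.0,
    radius_decay: float = 0.7,
    length_decay: float = 0.7,
    angle_spread_deg: float = 40.0,
    rng_seed: int = 0,
    shape: Tuple[int, int, int] = (64, 64, 64),
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> List[TubeSegment]:
    """Deterministic recursive bifurcating tree (portal-vein-like morphology).

    Each segment spawns two children tilted ``angle_spread_deg`` off the
    parent axis at a random (seeded) azimuth, with radius and length
    scaled by the decay factors; a tree of ``levels`` levels has
    2**levels - 1 segments.  Segments that would exit the volume are
    truncated to stay inside (with a warning).
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    rng = np.random.default_rng(rng_seed)
    extent = (np.asarray(shape) - 1) * np.asarray(spacing, dtype=np.float64)
    segments: List[TubeSegment] = []

    def clamp(point: np.ndarray, radius: float) -> np.ndarray:
        clamped = np.clip(point, radius, extent - radius)
        if not np.allclose(clamped, point):
            warnings.warn("tree segment truncated at volume boundary", stacklevel=2)
        return clamped

    def grow(start: np.ndarray, d: np.ndarray, length: float, radius: float, level: int) -> None:
        end = clamp(start + d * length, radius)
        segments.append(TubeSegment(tuple(start), tuple(end), radius))
        if level + 1 >= levels:
            return
        theta = np.deg2rad(angle_spread_deg)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        u, v = _orthonormal(d)
        for offset in (0.0, np.pi):
            lateral = np.cos(phi + offset) * u + np.sin(phi + offset) * v
            child = np.cos(theta) * d + np.sin(theta) * lateral
            child /= np.linalg.norm(child)
            grow(end, child, length * length_decay, radius * radius_decay, level + 1)

    d0 = np.asarray(direction, dtype=np.float64)
    d0 /= np.linalg.norm(d0)
    start0 = clamp(np.asarray(root, dtype=np.float64), trunk_radius)
    grow(start0, d0, trunk_length, trunk_radius, 0)
    return segments


def default_branching_spec(rng_seed: int = 0) -> PhantomSpec:
    """The default study phantom: a 3-level branching tree in a 64^3 volume."""
    spec = PhantomSpec(rng_seed=rng_seed)
    spec.tree = branching_tree(rng_seed=rng_seed, shape=spec.shape, spacing=spec.spacing)
    return spec


def two_system_phantom(
    bridge_intensity: Optional[float] = 140.0,
    rng_seed: int = 0,
    shape: Tuple[int, int, int] = (48, 48, 64),
    radius: float = 2.0,
    blur_sigma_mm: float = 0.5,
    vessel_sd: float = 10.0,
    background_sd: float = 10.0,
) -> TwoSystemPhantom:
    """Two disjoint tubes whose near ends are joined by a 1–2 voxel strand.

    Emulates the weak connectivity at vessel ends through which one seed
    can reach a second vessel system: the strand voxel(s) on the axis
    between the tubes are painted at ``bridge_intensity`` — intermediate
    between parenchyma and vessel, like a partial-volume-dimmed vessel
    end; ``bridge_intensity=None`` removes the strand.  Tree B is made
    distinctly larger than tree A (the seeded one) so that its joining
    produces a marked jump in a region-growing trace.  The truth marks
    both trees but never the bridge.
    """
    c = float(shape[0] // 2)  # on-grid axis so the strand is a clean voxel column
    tube_a = TubeSegment((c, c, 6.0), (c, c, 20.0), radius)
    tube_b = TubeSegment((c, c, 26.0), (c, c, 54.0), radius * 1.25)
    spec = PhantomSpec(
        shape=shape,
        tree=[tube_a, tube_b],
        blur_sigma_mm=blur_sigma_mm,
        vessel_sd=vessel_sd,
        background_sd=background_sd,
        rng_seed=rng_seed,
    )
    result = generate_phantom(spec)
    truth_a = SegmentationMask(
        rasterize_tree([tube_a], shape, spec.spacing), spec.spacing
    )
    truth_b = SegmentationMask(
        rasterize_tree([tube_b], shape, spec.spacing), spec.spacing
    )
    ci = int(c)
    axis_gap = [
        (ci, ci, z)
        for z in range(shape[2])
        if not (truth_a.values[ci, ci, z] or truth_b.values[ci, ci, z])
        and truth_a.values[ci, ci, : z].any()
        and truth_b.values[ci, ci, z:].any()
    ]
    values = result.scene.values.copy()
    if bridge_intensity is not None:
        for voxel in axis_gap:
            values[voxel] = int(round(bridge_intensity))
    scene = Scene(values, spec.spacing)
    seed = (ci, ci, 13)  # mid-tube A
    return TwoSystemPhantom(
        scene=scene,
        truth=result.truth,
        truth_a=truth_a,
        truth_b=truth_b,
        bridge_voxels=axis_gap,
        seed=seed,
        spec=spec,
    )


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    data = asdict(spec)
    data["tree"] = [
        {"start": [float(x) for x in s.start], "end": [float(x) for x in s.end],
         "radius": float(s.radius),
         "radius_end": None if s.radius_end is None else float(s.radius_end)}
        for s in spec.tree
    ]
    data["shape"] = [int(n) for n in spec.shape]
    data["spacing"] = [float(s) for s in spec.spacing]
    for key in ("background_mean", "background_sd", "vessel_mean", "vessel_sd",
                "blur_sigma_mm", "noise_sd"):
        data[key] = float(data[key])
    data["rng_seed"] = int(data["rng_seed"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    tree = [
        TubeSegment(tuple(s["start"]), tuple(s["end"]), s["radius"], s.get("radius_end"))
        for s in data.pop("tree", [])
    ]
    data["shape"] = tuple(data.get("shape", (64, 64, 64)))
    data["spacing"] = tuple(data.get("spacing", (1.0, 1.0, 1.0)))
    return PhantomSpec(tree=tree, **data)
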