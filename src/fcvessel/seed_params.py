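"""Seed-local estimation of the vessel intensity statistics (m, s).

A cube (default 20x20x20 voxels) centered on the user's seed contains both
vessel and surrounding parenchyma; Otsu's method splits its intensities
into two classes, the brighter of which is taken as the vessel class
(contrast-enhanced vessels are brighter than liver parenchyma).  The mean
m and standard deviation s of that class parameterize the affinity
Gaussian, and the seed voxel's own intensity is replaced by m so that the
segmentation does not depend on whether the seed was clicked at the vessel
center or near its edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .affinity import AffinityParams
from .scene_io import Scene

__all__ = [
    "SeedSpec",
    "extract_cube",
    "otsu_threshold",
    "estimate_params",
    "replace_seed_value",
]

#: Lower bound on s: keeps the affinity Gaussian non-singular when the
#: sampled vessel class is (near-)constant, e.g. on noiseless phantoms.
S_FLOOR = 0.5


@dataclass(frozen=True)
class SeedSpec:
    """A seed voxel index plus the edge length of its sampling cube."""

    index: Tuple[int, int, int]
    cube_edge: int = 20

    def __post_init__(self) -> None:
        if self.cube_edge < 1:
            raise ValueError(f"cube_edge must be >= 1, got {self.cube_edge}")


def _cube_slices(scene: Scene, seed: SeedSpec):
    if not scene.contains(seed.index):
        raise ValueError(f"seed {seed.index} outside scene of shape {scene.shape}")
    slices = []
    for i, n in zip(seed.index, scene.shape):
        lo = i - seed.cube_edge // 2
        hi = lo + seed.cube_edge
        slices.append(slice(max(lo, 0), min(hi, n)))
    return tuple(slices)


def extract_cube(scene: Scene, seed: SeedSpec) -> np.ndarray:
    """Intensities of the axis-aligned cube centered on the seed.

    An even edge cannot be exactly centered; each axis spans
    [i - edge//2, i - edge//2 + edge), i.e. edge//2 voxels below the seed
    plane and edge - edge//2 - 1 above.  The cube is truncated at the
    scene borders.  Returns a flat array.
    """
    return scene.values[_cube_slices(scene, seed)].ravel()


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's two-class threshold over the 8-bit intensity range.

    Returns the threshold t in 0..255 maximizing the between-class
    variance of {v <= t} vs {v > t}; ties resolve to the smallest t.
    Raises on constant input (no two-class split exists).
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("otsu_threshold: empty input")
    ints = values.astype(np.int64)
    if np.any(ints < 0) or np.any(ints > 255):
        raise ValueError("otsu_threshold expects intensities in 0..255")
    hist = np.bincount(ints, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate cube: single intensity")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * levels)
    mu_total = sum0[-1]
    w1 = total - w0
    # between-class variance for threshold t = each index; undefined where
    # either class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (mu_total - sum0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def estimate_params(scene: Scene, seed: SeedSpec) -> AffinityParams:
    """Estimate (m, s) of the vessel class from the seed cube via Otsu.

    The vessel class is the Otsu class with the higher mean (the brighter
    one).  s uses the population convention (divisor N) and is floored at
    0.5 intensity units.  Raises if the seed's own intensity falls in the
    darker class — the seed was placed outside a vessel.
    """
    cube = extract_cube(scene, seed)
    t = otsu_threshold(cube)
    seed_value = float(scene.values[seed.index])
    if seed_value <= t:
        raise ValueError(
            f"seed not in vessel class: seed intensity {seed_value} <= Otsu threshold {t}"
        )
    vessel = cube[cube > t].astype(np.float64)
    m = float(vessel.mean())
    s = max(float(vessel.std()), S_FLOOR)
    return AffinityParams(m=m, s=s)


def replace_seed_value(scene: Scene, seed: SeedSpec, params: AffinityParams) -> Scene:
    """Copy of the scene with the seed voxel set to round(m) (half-up)."""
    values = scene.values.copy()
    values[seed.index] = np.floor(params.m + 0.5).astype(values.dtype)
    return Scene(values, scene.spacing)
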