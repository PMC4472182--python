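"""Fuzzy connectedness propagation: the connectivity scene CS.

The fuzzy connectedness of a voxel d to the seed is the strength of the
strongest 6-connected path from the seed to d, where a path's strength is
its weakest link affinity (max-min path strength).  CS holds this value
for every voxel; thresholding CS yields the segmentation.

Two routes are provided:

* :func:`compute_connectivity` — the production algorithm: Dijkstra-style
  propagation with a max-priority queue.  Pop the voxel with maximal CS,
  relax each 6-neighbor e with f_min = min(CS(c), mu_k(c, e)), re-queue on
  improvement.  Max-min Dijkstra is exact regardless of how ties in the
  queue are broken, so the result is invariant to the tie rule (exposed as
  ``tie_break`` purely so tests can verify this).
* :func:`connectivity_oracle` — an independent brute-force fixpoint
  (Bellman–Ford-style iterated max-min relaxation) for small scenes,
  used to cross-check the queue implementation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .affinity import AffinityLUT, AffinityParams, _pair_gauss, adjacency, affinity, build_lut
from .scene_io import Scene

__all__ = [
    "ConnectivityScene",
    "path_strength",
    "connectivity_oracle",
    "compute_connectivity",
]


@dataclass
class ConnectivityScene:
    """Per-voxel fuzzy connectedness to the seed, in [0, 1]."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    seed: Tuple[int, int, int]

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def path_strength(path: Sequence[Tuple[int, int, int]], scene: Scene, params: AffinityParams) -> float:
    """Strength of a path = its weakest link affinity.

    A single-voxel path has strength 1.0 (empty minimum over links).
    Raises if consecutive voxels are not 6-adjacent.
    """
    if len(path) == 0:
        raise ValueError("path must contain at least one voxel")
    strength = 1.0
    for c, d in zip(path[:-1], path[1:]):
        if not adjacency(c, d):
            raise ValueError(f"path voxels {c} and {d} are not 6-adjacent")
        link = affinity(float(scene.values[tuple(c)]), float(scene.values[tuple(d)]), params)
        strength = min(strength, link)
    return strength


def _link_affinities(values: np.ndarray, params: AffinityParams):
    """Affinity arrays for the three positive axis directions.

    Indexes a per-pair-sum table built with the canonical scalar
    evaluation so the oracle's link values are bit-identical to the
    production routes.
    """
    v = values.astype(np.int64)
    if v.min() < 0 or v.max() > 255:
        raise ValueError("oracle requires intensities in 0..255")
    by_sum = np.array([_pair_gauss(float(t), params.m, params.s) for t in range(511)])
    links = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        links.append(by_sum[v[tuple(lo)] + v[tuple(hi)]])
    return links


def connectivity_oracle(scene: Scene, seed: Tuple[int, int, int], params: AffinityParams) -> ConnectivityScene:
    """Brute-force max-min fixpoint (test oracle for small scenes).

    Repeats the relaxation CS(d) <- max(CS(d), min(CS(c), mu_k(c, d))) over
    all 6-neighbor pairs until nothing changes.  Iterated max-min
    relaxation converges to the exact strongest-path strength.
    """
    if not scene.contains(seed):
        raise ValueError(f"seed {seed} outside scene of shape {scene.shape}")
    links = _link_affinities(scene.values, params)
    cs = np.zeros(scene.shape, dtype=np.float64)
    cs[tuple(seed)] = 1.0
    while True:
        prev = cs.copy()
        for axis, link in enumerate(links):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            np.maximum(cs[hi], np.minimum(cs[lo], link), out=cs[hi])
            np.maximum(cs[lo], np.minimum(cs[hi], link), out=cs[lo])
        if np.array_equal(cs, prev):
            break
    return ConnectivityScene(cs, scene.spacing, tuple(seed))


def compute_connectivity(
    scene: Scene,
    seed: Tuple[int, int, int],
    lut: AffinityLUT | None = None,
    params: AffinityParams | None = None,
    affinity_floor: float = 0.0,
    tie_break: str = "fifo",
    pop_log: list | None = None,
) -> ConnectivityScene:
    """Connectivity scene via max-priority-queue propagation.

    Exactly one of ``lut`` (tabulated affinities, the fast path) or
    ``params`` (direct per-pair evaluation of the affinity Gaussian) must
    be given; both routes produce bit-identical CS on 8-bit scenes.
    ``affinity_floor`` optionally prunes links with affinity <= floor
    (default 0, i.e. off: the Gaussian is positive in floating point for
    all but extreme intensity gaps, so every in-bounds neighbor is
    normally considered).  Unreached voxels keep CS = 0.

    The queue uses lazy re-insertion: an improved voxel is pushed again
    and stale entries are skipped on pop.  ``pop_log``, if provided,
    collects the CS value of every non-stale pop (they form a
    non-increasing sequence).
    """
    if (lut is None) == (params is None):
        raise ValueError("pass exactly one of lut= or params=")
    if not scene.contains(seed):
        raise ValueError(f"seed {seed} outside scene of shape {scene.shape}")
    if tie_break not in ("fifo", "lifo"):
        raise ValueError(f"tie_break must be 'fifo' or 'lifo', got {tie_break!r}")

    values = np.asarray(scene.values)
    if values.min() < 0 or values.max() > 255:
        raise ValueError("compute_connectivity requires intensities in 0..255 "
                         "(apply window_to_byte first)")
    nx, ny, nz = values.shape
    # flat python structures: much faster than per-voxel numpy indexing
    flat_vals = values.astype(np.int64).ravel().tolist()
    if lut is not None:
        table = lut.table.ravel().tolist()
        m = s = None
    else:
        table = None
        m, s = params.m, params.s
    gauss = _pair_gauss

    sy = nz
    sx = ny * nz
    n_total = nx * ny * nz
    cs = [0.0] * n_total
    seed_flat = (seed[0] * ny + seed[1]) * nz + seed[2]
    cs[seed_flat] = 1.0

    # heap entries: (-cs, order, flat_index); order implements the tie rule
    counter = 0
    sign = 1 if tie_break == "fifo" else -1
    heap = [(-1.0, 0, seed_flat)]

    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        neg, _, c = pop(heap)
        cs_c = -neg
        if cs_c < cs[c]:
            continue  # stale entry
        if pop_log is not None:
            pop_log.append(cs_c)
        z = c % nz
        rem = c // nz
        y = rem % ny
        x = rem // ny
        fc = flat_vals[c]
        row = fc * 256 if table is not None else 0
        for e, in_bounds in (
            (c - sx, x > 0),
            (c + sx, x < nx - 1),
            (c - sy, y > 0),
            (c + sy, y < ny - 1),
            (c - 1, z > 0),
            (c + 1, z < nz - 1),
        ):
            if not in_bounds:
                continue
            if table is not None:
                aff = table[row + flat_vals[e]]
            else:
                aff = gauss(fc + flat_vals[e], m, s)
            if aff <= affinity_floor:
                continue
            f_min = cs_c if cs_c < aff else aff
            if f_min > cs[e]:
                cs[e] = f_min
                counter += 1
                push(heap, (-f_min, sign * counter, e))

    out = np.array(cs, dtype=np.float64).reshape(values.shape)
    return ConnectivityScene(out, scene.spacing, tuple(seed))
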