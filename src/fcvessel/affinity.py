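"""Fuzzy adjacency and fuzzy affinity, with a 256x256 lookup-table fast path.

The local *affinity* between two voxels c, d is

    mu_k(c, d) = mu_alpha(c, d) * exp(-1/2 * (((f(c)+f(d))/2 - m) / s)^2)

where ``mu_alpha`` is the hard 6-adjacency indicator, ``f`` the intensity,
and ``m``, ``s`` the mean and standard deviation of the vessel class.  The
general weighted two-term form (weights w1, w2 summing to 1) is carried in
:class:`AffinityParams`, but only the Gaussian term is active (w1=1, w2=0);
no second feature function is defined.

Because intensities are 8-bit, all 65,536 possible intensity pairs can be
tabulated once (:func:`build_lut`); propagation then reads affinities from
the table instead of re-evaluating the exponential.  The table stores full
double precision so a lookup is bit-identical to direct evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AffinityParams", "AffinityLUT", "adjacency", "affinity", "build_lut", "lookup"]


@dataclass(frozen=True)
class AffinityParams:
    """Vessel-class intensity statistics parameterizing the affinity Gaussian.

    m, s are on the 8-bit intensity scale; s must be positive.  w1 weights
    the Gaussian intensity term and w2 a hypothetical second term (unused,
    fixed 0 by default); they must sum to 1.
    """

    m: float
    s: float
    w1: float = 1.0
    w2: float = 0.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"affinity std s must be > 0, got {self.s}")
        if abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValueError(f"weights must satisfy w1 + w2 = 1, got {self.w1}, {self.w2}")
        if self.w2 != 0.0:
            raise NotImplementedError("only the Gaussian term is implemented (w2 must be 0)")


def adjacency(c, d) -> int:
    """Hard 6-adjacency: 1 iff the indices are identical or face neighbors."""
    dist2 = sum((ci - di) ** 2 for ci, di in zip(c, d))
    return 1 if dist2 <= 1 else 0


def _pair_gauss(pair_sum: float, m: float, s: float) -> float:
    """Gaussian affinity term evaluated with scalar exp.

    All affinity routes (scalar, LUT, oracle) funnel through this one
    expression: numpy's vectorized exp can differ from its scalar path by
    one ulp, which would break the bit-equality between the LUT and
    direct evaluation, so the scalar path is canonical.
    """
    return float(np.exp(-0.5 * ((pair_sum / 2.0 - m) / s) ** 2))


def affinity(fc: float, fd: float, params: AffinityParams, adjacent: int = 1) -> float:
    """Affinity of an intensity pair: Gaussian of the pair mean around m.

    The pair mean is computed in floating point (no integer truncation).
    """
    if not adjacent:
        return 0.0
    return _pair_gauss(fc + fd, params.m, params.s)


@dataclass(frozen=True)
class AffinityLUT:
    """Precomputed affinity for every 8-bit intensity pair (assumed adjacent)."""

    table: np.ndarray
    params: AffinityParams

    def __post_init__(self) -> None:
        if self.table.shape != (256, 256):
            raise ValueError(f"LUT must be 256x256, got {self.table.shape}")


def build_lut(params: AffinityParams) -> AffinityLUT:
    """Tabulate affinity over all intensity pairs (0,0)..(255,255).

    The Gaussian depends only on the pair sum, so the 65,536 entries
    reduce to 511 distinct values.
    """
    by_sum = np.array([_pair_gauss(float(t), params.m, params.s) for t in range(511)])
    table = by_sum[np.add.outer(np.arange(256), np.arange(256))]
    return AffinityLUT(table, params)


def lookup(lut: AffinityLUT, fc: int, fd: int) -> float:
    """Read the affinity of an intensity pair; out-of-range values clamp to [0,255]."""
    a = min(max(int(fc), 0), 255)
    b = min(max(int(fd), 0), 255)
    return float(lut.table[a, b])
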