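"""Automatic threshold selection from the connectivity-scene histogram.

Voxels of one vessel system "hang together" at similar, high connectivity
values and show up as a peak in the histogram of CS; parenchyma that was
reached only through weak links piles up at low values.  The watershed-like
search walks in from the high end: the endpoint EP is the largest
threshold at which the segmented volume still reaches the anatomical cap
on total hepatic vessel volume (50 ml by default — portal vein alone
averages ~11.6 ml, and hepatic vein and artery add the rest), and the
suggested threshold T is EP itself if the histogram peaks there, otherwise
the first peak between EP and 1.0.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .connectedness import ConnectivityScene
from .scene_io import SegmentationMask

__all__ = [
    "ConnectivityHistogram",
    "ThresholdResult",
    "histogram",
    "volume_above",
    "find_peaks",
    "suggest_threshold",
    "apply_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 1000
DEFAULT_MAX_VOLUME_ML = 50.0
DEFAULT_SMOOTH_WINDOW = 9

#: A histogram peak only counts as a vessel peak if the (smoothed) counts
#: rise by at least this factor (in 1+count space) above the lowest point
#: passed since the endpoint EP.  CS histograms are log-scale objects:
#: genuine vessel peaks stand orders of magnitude above the valley, while
#: Poisson wiggles on near-empty bins rarely sustain a factor 3.
DEFAULT_MIN_PEAK_RISE = 3.0


@dataclass
class ConnectivityHistogram:
    """Histogram of positive CS values over (0, 1].

    Unreached voxels (CS == 0) are excluded: they carry no path to the
    seed and would otherwise dominate the counts.  ``bin_edges`` has one
    more entry than ``counts``; bin i spans [edges[i], edges[i+1]), the
    last bin including 1.0.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    voxel_volume_ml: float

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["bin_left", "bin_right", "count"])
            for left, right, count in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
                writer.writerow([f"{left:.6g}", f"{right:.6g}", int(count)])


@dataclass
class ThresholdResult:
    """Outcome of the adaptive search: threshold T >= endpoint EP."""

    T: float
    EP: float
    ep_is_peak: bool
    volume_at_T_ml: float


def histogram(cs: ConnectivityScene, bins: int = DEFAULT_BINS) -> ConnectivityHistogram:
    """Histogram the positive connectivity values into ``bins`` bins over (0, 1]."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    positive = cs.values[cs.values > 0]
    counts, edges = np.histogram(positive, bins=bins, range=(0.0, 1.0))
    return ConnectivityHistogram(edges, counts.astype(np.int64), cs.voxel_volume_mm3 / 1000.0)


def volume_above(h: float, hist: ConnectivityHistogram) -> float:
    """Segmented volume (ml) at threshold h: voxel volume x count of CS >= h.

    Evaluated at bin-edge resolution; h is snapped down to the nearest bin
    edge.  Non-increasing in h.
    """
    edges = hist.bin_edges
    if h <= edges[0]:
        idx = 0
    else:
        # snap into the containing bin; h = 1.0 falls in the last bin
        idx = min(int(np.searchsorted(edges, h, side="right")) - 1, hist.n_bins - 1)
    return float(hist.counts[idx:].sum()) * hist.voxel_volume_ml


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return counts.astype(np.float64)
    kernel = np.ones(window)
    num = np.convolve(counts.astype(np.float64), kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=np.float64), kernel, mode="same")
    return num / den  # edge bins averaged over the in-range part only


def find_peaks(hist: ConnectivityHistogram, smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> List[int]:
    """Indices of local maxima of the moving-average-smoothed counts.

    Bin i is a peak iff smoothed[i] > smoothed[i-1] (strict on the left,
    so a plateau resolves to its left edge) and smoothed[i] >= smoothed[i+1];
    boundary bins use the one-sided comparison only.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    s = _smooth(hist.counts, smooth_window)
    n = len(s)
    peaks = []
    for i in range(n):
        left_ok = i == 0 or s[i] > s[i - 1]
        right_ok = i == n - 1 or s[i] >= s[i + 1]
        if left_ok and right_ok:
            peaks.append(i)
    return peaks


def suggest_threshold(
    hist: ConnectivityHistogram,
    max_volume_ml: float = DEFAULT_MAX_VOLUME_ML,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_peak_rise: float = DEFAULT_MIN_PEAK_RISE,
) -> ThresholdResult:
    """EP-then-peak threshold search over the CS histogram.

    EP is the largest positive bin edge h with volume_above(h) >=
    max_volume_ml; if even the lowest positive edge keeps less than the
    cap (small scenes, e.g. phantoms), EP falls back to the lowest
    positive edge.  If the bin starting at EP is itself a significant
    peak, T = EP; otherwise T is the left edge of the first *significant*
    peak bin strictly above EP — a local maximum whose smoothed count
    rises by at least ``min_peak_rise`` (factor, in 1+count space) above
    the lowest smoothed count passed since EP.  Insignificant local
    maxima are Poisson wiggles of near-empty bins, not vessel peaks.  If
    no significant peak lies above EP, T falls back to EP with a warning.
    """
    if hist.counts.sum() == 0:
        raise ValueError("histogram is empty: no voxel has positive connectivity")
    edges = hist.bin_edges
    # cumulative volume at every edge (volume_above(edges[i]) for each i;
    # the top edge 1.0 keeps the last bin, matching volume_above)
    tail_counts = np.concatenate([np.cumsum(hist.counts[::-1])[::-1], [hist.counts[-1]]])
    volumes = tail_counts * hist.voxel_volume_ml
    positive = np.arange(1, len(edges))  # candidate edges, excluding 0.0
    qualifying = positive[volumes[positive] >= max_volume_ml]
    if len(qualifying):
        ep_idx = int(qualifying[-1])
    else:
        ep_idx = 1
        logger.warning(
            "total histogram volume %.3f ml below cap %.3f ml; "
            "endpoint falls back to the lowest positive bin edge",
            volumes[1], max_volume_ml,
        )
    ep = float(edges[ep_idx])
    ep_bin = min(ep_idx, hist.n_bins - 1)
    peaks = find_peaks(hist, smooth_window)
    smoothed = _smooth(hist.counts, smooth_window)
    ep_is_peak = ep_bin in peaks and _ep_peak_significant(smoothed, ep_bin, min_peak_rise)
    if ep_is_peak:
        t = ep
    else:
        t_bin = _first_significant_peak(smoothed, peaks, ep_bin, min_peak_rise)
        if t_bin is not None:
            t = float(edges[t_bin])
        else:
            logger.warning("no significant histogram peak above EP=%.4f; "
                           "falling back to T = EP", ep)
            t = ep
    return ThresholdResult(T=t, EP=ep, ep_is_peak=ep_is_peak, volume_at_T_ml=volume_above(t, hist))


def _first_significant_peak(smoothed, peaks, ep_bin, min_peak_rise):
    """First local-max bin above ep_bin rising min_peak_rise-fold over the valley."""
    peak_set = set(peaks)
    valley = smoothed[ep_bin]
    for i in range(ep_bin + 1, len(smoothed)):
        valley = min(valley, smoothed[i])
        if i in peak_set and 1.0 + smoothed[i] >= min_peak_rise * (1.0 + valley):
            return i
    return None


def _ep_peak_significant(smoothed, ep_bin, min_peak_rise):
    """Is the EP bin a significant peak?  Judged by its topographic prominence."""
    from scipy.signal import peak_prominences

    if not (0 < ep_bin < len(smoothed) - 1):
        # boundary bin: compare against the inner neighbor's side only
        inner = smoothed[1] if ep_bin == 0 else smoothed[-2]
        return 1.0 + smoothed[ep_bin] >= min_peak_rise * (1.0 + min(inner, smoothed.min()))
    prominence = peak_prominences(smoothed, [ep_bin])[0][0]
    base = smoothed[ep_bin] - prominence
    return 1.0 + smoothed[ep_bin] >= min_peak_rise * (1.0 + base)


def apply_threshold(cs: ConnectivityScene, T: float) -> SegmentationMask:
    """Segment the connectivity scene: mask = (CS >= T); the seed is always kept."""
    if not (0.0 < T <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {T}")
    mask = cs.values >= T
    mask[tuple(cs.seed)] = True
    return SegmentationMask(mask, cs.spacing)
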