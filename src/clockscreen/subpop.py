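"""Histogram-based subpopulation detection within a decoy population.

Independent first-generation (T1) transformants of the same construct carry
insertions at different genomic positions, so a single decoy population can
contain phenotypically distinct subgroups. This module re-implements the
screen's histogram rule set for splitting a population's control-normalized
period values into subpopulations:

1. bin the normalized values into uniform-width bins;
2. find histogram peaks and the troughs between them;
3. count seedlings per peak (between its flanking troughs);
4. discard peaks that hold fewer than 3 seedlings, sit only one bin away
   from another peak, or rise fewer than 3 counts above their higher
   flanking trough; discarded peaks merge across the shallower trough;
5. if two or more peaks survive, split the population at the trough
   locations; otherwise it is unimodal.

The operation is metric-agnostic but is applied to period differences in the
screen pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("clockscreen.subpop")

__all__ = [
    "Histogram",
    "SubpopGroup",
    "SubpopPartition",
    "build_histogram",
    "find_peaks_troughs",
    "detect_subpopulations",
]


@dataclass(frozen=True)
class Histogram:
    """Uniform-width histogram: ``len(bin_edges) == len(counts) + 1``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")


@dataclass(frozen=True)
class SubpopGroup:
    plant_ids: tuple
    mean_diff: float
    n: int


@dataclass(frozen=True)
class SubpopPartition:
    """Disjoint assignment of a population's values into histogram subgroups.

    ``division_points`` are the hour locations (trough bin boundaries) that
    separate consecutive groups; ``is_multimodal`` is true iff at least two
    groups survived the discard rules.
    """

    groups: tuple[SubpopGroup, ...]
    division_points: tuple[float, ...]
    is_multimodal: bool
    untestable: bool = False


def build_histogram(values, bin_width: float = 0.5, origin: float = 0.0) -> Histogram:
    """Bin values into half-open bins [edge, edge + width) anchored at origin.

    The origin defaults to 0, the concurrent control mean on the normalized
    scale. A value exactly on an edge belongs to the upper bin.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be binned")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor((v - origin) / bin_width).astype(int)
    k_min, k_max = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - k_min, minlength=k_max - k_min + 1)
    edges = origin + np.arange(k_min, k_max + 2) * bin_width
    return Histogram(bin_edges=edges, counts=counts)


def _bin_index(values: np.ndarray, hist: Histogram) -> np.ndarray:
    w = hist.bin_edges[1] - hist.bin_edges[0]
    return np.floor((values - hist.bin_edges[0]) / w).astype(int)


def _find_peaks(counts: np.ndarray) -> list[int]:
    """Bins strictly exceeding both neighbours; boundary bins compare to their
    single neighbour; the leftmost bin of an equal-count plateau is the
    candidate."""
    c = counts
    n = len(c)
    peaks: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and c[j + 1] == c[i]:
            j += 1
        left = c[i - 1] if i > 0 else -np.inf
        right = c[j + 1] if j + 1 < n else -np.inf
        if c[i] > left and c[i] > right:
            peaks.append(i)
        i = j + 1
    return peaks


def _troughs_between(counts: np.ndarray, peaks: list[int]) -> list[int]:
    """Leftmost minimum-count bin strictly between each pair of consecutive peaks."""
    troughs = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = counts[a + 1 : b]
        troughs.append(a + 1 + int(np.argmin(seg)))
    return troughs


def find_peaks_troughs(hist: Histogram) -> tuple[list[int], list[int]]:
    """Return (peak bin indices, trough bin indices).

    Troughs are the minimum-count bins between consecutive peaks plus the
    minimum-count bins of the end segments outside the outermost peaks (when
    those segments are non-empty).
    """
    c = hist.counts
    peaks = _find_peaks(c)
    if not peaks:
        return [], []
    troughs: list[int] = []
    if peaks[0] > 0:
        troughs.append(int(np.argmin(c[: peaks[0]])))
    troughs.extend(_troughs_between(c, peaks))
    if peaks[-1] < len(c) - 1:
        seg = c[peaks[-1] + 1 :]
        troughs.append(peaks[-1] + 1 + int(np.argmin(seg)))
    return peaks, troughs


def _regions(n_bins: int, troughs: list[int]) -> list[tuple[int, int]]:
    """Contiguous bin ranges [start, stop] per peak, splitting at interior
    troughs; a trough bin is assigned to the group on its left."""
    bounds = [-1] + troughs + [n_bins - 1]
    return [(bounds[k] + 1, bounds[k + 1]) for k in range(len(bounds) - 1)]


def detect_subpopulations(
    values,
    plant_ids=None,
    bin_width: float = 0.5,
    origin: float = 0.0,
    min_n: int = 3,
    min_prominence: int = 3,
    min_separation_bins: int = 2,
) -> SubpopPartition:
    """Partition normalized values into subpopulations by the histogram rules.

    A surviving subpopulation holds at least ``min_n`` seedlings, its peak
    rises at least ``min_prominence`` counts above the higher of its two
    flanking troughs (segments beyond the outermost peaks count as troughs;
    the empty space outside the histogram counts as zero), and retained peaks
    are separated by at least ``min_separation_bins`` bins. When a peak is
    discarded its seedlings merge with the neighbouring group across the
    shallower flanking trough (the deepest trough in the merged gap becomes
    the new division). With fewer than two survivors the population is
    unimodal and one group holds every value.

    Fewer than ``min_n`` values in total yields a single group flagged
    ``untestable``.
    """
    v = np.asarray(values, dtype=float)
    if plant_ids is None:
        plant_ids = np.arange(v.size)
    ids = np.asarray(plant_ids)
    if ids.shape != v.shape:
        raise ValueError("plant_ids must match values in length")

    def single(untestable: bool = False) -> SubpopPartition:
        return SubpopPartition(
            groups=(SubpopGroup(tuple(ids.tolist()), float(np.mean(v)), int(v.size)),),
            division_points=(),
            is_multimodal=False,
            untestable=untestable,
        )

    if v.size < min_n:
        logger.info("population of %d values (< %d): untestable", v.size, min_n)
        return single(untestable=True)

    hist = build_histogram(v, bin_width=bin_width, origin=origin)
    counts = hist.counts
    bin_of = _bin_index(v, hist)
    peaks = _find_peaks(counts)

    while len(peaks) >= 2:
        troughs = _troughs_between(counts, peaks)
        regions = _regions(len(counts), troughs)
        members = [int(counts[a : b + 1].sum()) for a, b in regions]
        # flanking trough counts; outside the histogram is empty (count 0)
        flanks = []
        for k, p in enumerate(peaks):
            left = counts[troughs[k - 1]] if k > 0 else (counts[:p].min() if p > 0 else 0)
            right = (
                counts[troughs[k]]
                if k < len(troughs)
                else (counts[p + 1 :].min() if p < len(counts) - 1 else 0)
            )
            flanks.append((int(left), int(right)))

        violating = set()
        for k, p in enumerate(peaks):
            if members[k] < min_n:
                violating.add(k)
            if counts[p] - max(flanks[k]) < min_prominence:
                violating.add(k)
        for k in range(len(peaks) - 1):
            if peaks[k + 1] - peaks[k] - 1 < min_separation_bins:
                violating.add(k)
                violating.add(k + 1)
        if not violating:
            break
        # discard the weakest violating peak (lowest bin count, then fewest
        # members, then leftmost) and recompute: the deepest trough of the
        # merged gap survives as the division, so members cross the shallower
        drop = min(violating, key=lambda k: (counts[peaks[k]], members[k], peaks[k]))
        logger.debug("discarding peak at bin %d (count %d)", peaks[drop], counts[peaks[drop]])
        peaks = [p for k, p in enumerate(peaks) if k != drop]

    if len(peaks) < 2:
        return single()

    troughs = _troughs_between(counts, peaks)
    regions = _regions(len(counts), troughs)
    groups = []
    for a, b in regions:
        mask = (bin_of >= a) & (bin_of <= b)
        groups.append(
            SubpopGroup(
                plant_ids=tuple(ids[mask].tolist()),
                mean_diff=float(np.mean(v[mask])),
                n=int(mask.sum()),
            )
        )
    division_points = tuple(float(hist.bin_edges[t + 1]) for t in troughs)
    return SubpopPartition(
        groups=tuple(groups), division_points=division_points, is_multimodal=True
    )
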