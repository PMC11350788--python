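"""Habitability classification and range areas.

Averaged suitability maps are split into four habitability zones (non, low,
medium, high) with Jenks natural breaks — the optimal 1-D partition
minimizing total within-class sum of squared deviations, computed exactly by
dynamic programming (divide-and-conquer optimization over the concave-Monge
cost, O(k n log n)).  The species' potential range is the union of the low,
medium and high zones; its area is the geodesic sum of member cell areas.

Breaks are fitted once per species on the *current* suitability surface and
reused for all future projections, so current and future ranges are
thresholded identically and range change is never confounded with threshold
drift.

Interval convention: values equal to a break go to the upper class
(left-closed on the upper classes); a cell at break b2 is medium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import GridSpec, cell_area_km2  # noqa: F401  (re-export)
from .sdm import SuitabilityMap

CLASS_NAMES = ("non", "low", "medium", "high")


@dataclass(frozen=True)
class BreakSet:
    """Ordered class thresholds; class i is [b_i, b_{i+1})."""

    thresholds: tuple[float, ...]
    source: str = "current"
    sample_size: int = 0

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"breaks must be strictly increasing: {self.thresholds}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"thresholds": list(self.thresholds), "source": self.source,
             "sample_size": self.sample_size}, indent=2))


@dataclass
class HabitatClassMap:
    grid: GridSpec
    classes: np.ndarray          # int codes 0..k-1; masked cells -1
    breaks: BreakSet


@dataclass
class BinaryRange:
    grid: GridSpec
    flags: np.ndarray            # bool presence
    area_km2: float


def _fisher_jenks_partition(unique_sorted: np.ndarray, counts: np.ndarray,
                            k: int) -> list[int]:
    """Start index of each class in the optimal k-partition of sorted values.

    Operates on unique values with multiplicities, so class boundaries always
    fall between distinct values and the resulting thresholds are strictly
    increasing.  DP over class layers; within a layer the optimal split
    position is monotone in j (the weighted-SSD cost matrix is Monge), so
    each layer is solved by divide-and-conquer in O(n log n) cost
    evaluations.
    """
    n = unique_sorted.size
    c = counts.astype(float)
    prefix0 = np.concatenate([[0.0], np.cumsum(c)])
    prefix1 = np.concatenate([[0.0], np.cumsum(unique_sorted * c)])
    prefix2 = np.concatenate([[0.0], np.cumsum(unique_sorted**2 * c)])

    def cost(i: int, j: int) -> float:
        w = prefix0[j + 1] - prefix0[i]
        s1 = prefix1[j + 1] - prefix1[i]
        s2 = prefix2[j + 1] - prefix2[i]
        return s2 - s1 * s1 / w

    # D[j] = optimal cost of partitioning values[0..j] into the current
    # number of classes; A[m][j] = argmin split for reconstruction.
    D = np.array([cost(0, j) for j in range(n)])
    arg = np.zeros((k, n), dtype=int)

    for m in range(1, k):
        newD = np.full(n, np.inf)

        def solve(jlo: int, jhi: int, ilo: int, ihi: int, D=D, newD=newD, m=m) -> None:
            if jlo > jhi:
                return
            jmid = (jlo + jhi) // 2
            best, best_i = np.inf, ilo
            for i in range(max(ilo, m), min(ihi, jmid) + 1):
                c = D[i - 1] + cost(i, jmid)
                if c < best:
                    best, best_i = c, i
            newD[jmid] = best
            arg[m][jmid] = best_i
            solve(jlo, jmid - 1, ilo, best_i)
            solve(jmid + 1, jhi, best_i, ihi)

        solve(m, n - 1, m, n - 1)
        D = newD

    starts = [0] * k
    j = n - 1
    for m in range(k - 1, 0, -1):
        starts[m] = int(arg[m][j])
        j = starts[m] - 1
    return starts


def jenks_breaks(values, n_classes: int = 4, max_sample: int = 10_000,
                 seed: int = 0, source: str = "current") -> BreakSet:
    """Fisher-Jenks natural breaks.

    Returns the ``n_classes - 1`` thresholds, each the smallest value of its
    upper class, so that classification by ``value >= threshold`` reproduces
    the optimal partition.  Values are subsampled (seeded, without
    replacement) to ``max_sample`` when larger.
    """
    full = np.asarray(values, dtype=float).ravel()
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if np.unique(full).size < n_classes:
        raise ValueError(
            f"need >= {n_classes} distinct values, got {np.unique(full).size}")
    values = full
    if full.size > max_sample:
        rng = np.random.default_rng(seed)
        values = rng.choice(full, size=max_sample, replace=False)
        if np.unique(values).size < n_classes:  # degenerate subsample; rare
            values = full
    uniq, counts = np.unique(values, return_counts=True)
    starts = _fisher_jenks_partition(uniq, counts, n_classes)
    thresholds = tuple(float(uniq[s]) for s in starts[1:])
    return BreakSet(thresholds, source=source, sample_size=values.size)


def jenks_objective(values, thresholds) -> float:
    """Total within-class SSD induced by a threshold set (for oracle checks)."""
    values = np.sort(np.asarray(values, dtype=float).ravel())
    edges = [-np.inf, *thresholds, np.inf]
    total = 0.0
    for lo, hi in zip(edges, edges[1:]):
        cls = values[(values >= lo) & (values < hi)]
        if cls.size:
            total += float(((cls - cls.mean()) ** 2).sum())
    return total


def classify(suitability: SuitabilityMap, breaks: BreakSet) -> HabitatClassMap:
    """Threshold a suitability map into habitability classes.

    ``class = sum(p >= b_i)``: non below b1, then low/medium/high, values at
    a break going up.  Masked cells get code -1.
    """
    p = suitability.values
    classes = np.zeros(p.shape, dtype=int)
    for b in breaks.thresholds:
        classes += (p >= b).astype(int)
    if suitability.mask is not None:
        classes[suitability.mask] = -1
    return HabitatClassMap(suitability.grid, classes, breaks)


def to_binary_range(classmap: HabitatClassMap) -> BinaryRange:
    """Potential range = union of the low, medium and high classes."""
    flags = classmap.classes >= 1
    areas = classmap.grid.cell_areas_km2()
    return BinaryRange(classmap.grid, flags, float(areas[flags].sum()))
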