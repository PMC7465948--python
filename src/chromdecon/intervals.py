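"""Retention-time intervals and per-interval data cubes.

The deconvolution operates interval by interval: the analyst (or the
advisory :func:`suggest_intervals`) partitions the run into retention-time
windows, and for each window a sample x elution x mass cube is sliced out
of the co-registered replicate set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

from .augment import ReplicateSet

__all__ = [
    "Interval",
    "IntervalCube",
    "load_interval_config",
    "suggest_intervals",
    "build_cube",
]


@dataclass(frozen=True)
class Interval:
    """Half-open retention-time window [start_time, end_time) in minutes."""

    start_time: float
    end_time: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_time >= self.end_time:
            raise ValueError(
                f"interval {self.label!r}: start {self.start_time} >= "
                f"end {self.end_time}"
            )

    def contains(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.start_time) & (times < self.end_time)


@dataclass
class IntervalCube:
    """K slabs of shape I_int x J: one elution x mass matrix per member."""

    slabs: list
    interval: Interval
    member_ids: list
    mz_axis: np.ndarray
    scan_times: np.ndarray  # the I_int scan times inside the interval

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.slabs}
        if len(shapes) != 1:
            raise ValueError(f"slab shapes differ: {shapes}")
        if any(np.any(s < 0) for s in self.slabs):
            raise ValueError("cube intensities must be non-negative")

    @property
    def n_members(self) -> int:
        return len(self.slabs)

    @property
    def shape(self):
        return (self.n_members,) + self.slabs[0].shape

    def total_sumsq(self) -> float:
        return float(sum(np.sum(s * s) for s in self.slabs))


def load_interval_config(path, allow_overlap: bool = False) -> list:
    """Load and validate an interval list from YAML or JSON.

    The file holds a list of ``{start, end, label}`` mappings (or
    ``[start, end, label]`` sequences). Intervals are sorted by start time.
    Overlaps are rejected unless ``allow_overlap`` is set: deliberately
    re-covering an unresolved region with more than one interval is a valid
    strategy when neighbouring compounds share near-identical spectra.
    """
    text = open(path).read()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    intervals = []
    for item in raw:
        if isinstance(item, dict):
            iv = Interval(float(item["start"]), float(item["end"]),
                          str(item.get("label", "")))
        else:
            start, end = float(item[0]), float(item[1])
            label = str(item[2]) if len(item) > 2 else ""
            iv = Interval(start, end, label)
        intervals.append(iv)
    intervals.sort(key=lambda iv: (iv.start_time, iv.end_time))
    if not allow_overlap:
        for a, b in zip(intervals, intervals[1:]):
            if b.start_time < a.end_time:
                raise ValueError(
                    f"intervals {a.label!r} and {b.label!r} overlap; pass "
                    f"allow_overlap=True to permit multi-coverage"
                )
    return intervals


def suggest_intervals(repset: ReplicateSet, target_count: int) -> list:
    """Advisory tiling: boundaries at the deepest valleys of the mean TIC.

    Places ``target_count - 1`` interior boundaries at the lowest local
    minima of the member-averaged total ion chromatogram (ties broken by
    the earliest scan), then tiles the run. The canonical workflow remains a
    manually curated interval config; this is an aid for drafting one.
    """
    ref = repset.members[0]
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if target_count > ref.n_scans:
        raise ValueError(
            f"target_count {target_count} exceeds scan count {ref.n_scans}"
        )
    times = ref.scan_times
    end = times[-1] + (times[-1] - times[-2])  # one spacing past the last scan
    if target_count == 1:
        return [Interval(times[0], end, "iv001")]

    mean_tic = np.mean([m.tic() for m in repset.members], axis=0)
    interior = np.arange(1, ref.n_scans - 1)
    # a valley must dip below at least one neighbour; a perfectly flat TIC
    # therefore has none and triggers the equal-width fallback
    is_valley = (
        (mean_tic[interior] <= mean_tic[interior - 1])
        & (mean_tic[interior] <= mean_tic[interior + 1])
        & (
            (mean_tic[interior] < mean_tic[interior - 1])
            | (mean_tic[interior] < mean_tic[interior + 1])
        )
    )
    valleys = interior[is_valley]
    if valleys.size < target_count - 1:
        # flat or featureless TIC: fall back to near-equal-width tiling
        fractions = np.linspace(0.0, 1.0, target_count + 1)[1:-1]
        cuts = [times[0] + (end - times[0]) * f for f in fractions]
    else:
        order = np.lexsort((valleys, mean_tic[valleys]))  # depth, then earliest
        chosen = np.sort(valleys[order[: target_count - 1]])
        cuts = list(times[chosen])

    bounds = [times[0], *cuts, end]
    return [
        Interval(lo, hi, f"iv{k + 1:03d}")
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    ]


def build_cube(repset: ReplicateSet, interval: Interval) -> IntervalCube:
    """Slice the interval's scans out of every member (pure slicing)."""
    ref = repset.members[0]
    mask = interval.contains(ref.scan_times)
    n_inside = int(mask.sum())
    if n_inside < 2:
        raise ValueError(
            f"interval {interval.label!r} [{interval.start_time}, "
            f"{interval.end_time}) contains {n_inside} scans; need >= 2"
        )
    slabs = [m.intensities[mask, :] for m in repset.members]
    return IntervalCube(
        slabs=slabs,
        interval=interval,
        member_ids=list(range(len(repset.members))),
        mz_axis=ref.mz_axis.copy(),
        scan_times=ref.scan_times[mask],
    )
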