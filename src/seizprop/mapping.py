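"""Channel-to-region mapping and region-level observation assembly.

Each bipolar channel is assigned to the brain region nearest to its
contact-pair midpoint, unless the second-nearest region is at a comparable
distance — the ambiguity rule d2 / (d1 + 0.5 mm) < 2 leaves such channels
unassigned.  Distance to a region is the minimum Euclidean distance to its
voxel coordinates (0 inside).  No upper distance cap is applied, but
midpoints further than 5 mm from gray matter are logged as suspicious.

Per region, channel observations are combined by the median onset with
non-seizing channels entering at +inf and lower interpolation for even
counts; the region is seizing iff the median is finite, which coincides
with the channel-majority rule (even splits resolve to seizing).  Finally
the seizure is aligned so the earliest region onset is at t1 = 30 s, onsets
beyond t_lim = 90 s are reclassified non-seizing, unobserved regions are
hidden, and seizures with no seizing region are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .observations import SeizureObservation

__all__ = [
    "Parcellation",
    "RegionObservation",
    "assign_channel_to_region",
    "aggregate_region_observation",
    "finalize_seizure",
    "seizure_duration_filter",
]

logger = logging.getLogger(__name__)

AMBIGUITY_OFFSET_MM = 0.5
AMBIGUITY_RATIO = 2.0
DISTANCE_WARNING_MM = 5.0


@dataclass
class Parcellation:
    """Region labels with their voxel coordinates (mm, scanner space)."""

    region_ids: list[str]
    voxel_coords: list[np.ndarray]  # per region, (n_voxels, 3)

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.voxel_coords):
            raise ValueError("one voxel array per region required")
        self.voxel_coords = [np.atleast_2d(np.asarray(v, dtype=float)) for v in self.voxel_coords]
        for r, v in zip(self.region_ids, self.voxel_coords):
            if v.size == 0 or v.shape[1] != 3:
                raise ValueError(f"region {r} needs a nonempty (n, 3) voxel array")


@dataclass
class RegionObservation:
    """Aggregated observation of one region in one seizure."""

    region_id: str
    status: str                 # "seizing" | "non-seizing" | "hidden"
    onset_s: float              # finite iff seizing
    n_channels_assigned: int = 0
    channel_onsets: tuple = ()  # multiset of per-channel onsets (inf = non-seizing)


def assign_channel_to_region(midpoint, parc: Parcellation) -> str | None:
    """Nearest-region assignment with the ambiguity rule; None = unassigned."""
    if len(parc.region_ids) < 2:
        raise ValueError("need at least two regions to apply the ambiguity rule")
    mp = np.asarray(midpoint, dtype=float)
    dists = np.array(
        [np.sqrt(((v - mp) ** 2).sum(axis=1)).min() for v in parc.voxel_coords]
    )
    order = np.argsort(dists)
    d1, d2 = dists[order[0]], dists[order[1]]
    if d1 > DISTANCE_WARNING_MM:
        logger.warning(
            "contact midpoint %.2f mm from nearest gray matter (region %s)",
            d1, parc.region_ids[order[0]],
        )
    if d2 / (d1 + AMBIGUITY_OFFSET_MM) < AMBIGUITY_RATIO:
        return None
    return parc.region_ids[order[0]]


def _median_lower(values: Sequence[float]) -> float:
    """Median with lower interpolation: sorted element at index (k-1)//2."""
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[(len(v) - 1) // 2])


def aggregate_region_observation(
    region_id: str, channel_onsets: Sequence[float]
) -> RegionObservation:
    """Combine the assigned channels of a region into one observation.

    ``channel_onsets`` holds one entry per assigned channel: the detected
    onset in seconds, or +inf for a non-seizing channel.
    """
    if len(channel_onsets) == 0:
        raise ValueError("at least one assigned channel is required")
    med = _median_lower(channel_onsets)
    if np.isfinite(med):
        return RegionObservation(
            region_id, "seizing", med, len(channel_onsets), tuple(channel_onsets)
        )
    return RegionObservation(
        region_id, "non-seizing", np.inf, len(channel_onsets), tuple(channel_onsets)
    )


def finalize_seizure(
    observations: Sequence[RegionObservation],
    all_region_ids: Sequence[str],
    t1: float = 30.0,
    t_lim: float = 90.0,
) -> SeizureObservation | None:
    """Align, clip and complete a seizure observation; None if excluded.

    Finite onsets are shifted so the earliest equals ``t1``; shifted onsets
    exceeding ``t_lim`` become non-seizing; regions without any observation
    are hidden.  A seizure with no seizing region at all is excluded.
    """
    by_region = {o.region_id: o for o in observations}
    if len(by_region) != len(observations):
        raise ValueError("duplicate region observations")
    onsets = [o.onset_s for o in observations if o.status == "seizing"]
    if not onsets:
        return None
    shift = t1 - min(onsets)
    ids = [str(r) for r in all_region_ids]
    status = np.array(["hidden"] * len(ids), dtype=object)
    onset = np.full(len(ids), np.inf)
    for i, r in enumerate(ids):
        o = by_region.get(r)
        if o is None or o.status == "hidden":
            continue
        if o.status == "seizing":
            t = o.onset_s + shift
            if t > t_lim:
                status[i] = "non-seizing"
            else:
                status[i] = "seizing"
                onset[i] = t
        else:
            status[i] = "non-seizing"
    return SeizureObservation(ids, status, onset)


def seizure_duration_filter(duration_s: float) -> bool:
    """Keep only seizures strictly longer than 30 s."""
    return duration_s > 30.0
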