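"""Per-seizure region observations and multi-seizure cohorts.

A seizure is observed through a subset of regions (those with at least one
assigned SEEG channel).  Each observed region is either seizing, with a
detected onset time in seconds, or non-seizing; all remaining regions are
hidden.  Onset times of non-seizing and hidden regions are stored as +inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome

__all__ = ["SeizureObservation", "MultiSeizureData", "STATUS_VALUES"]

STATUS_VALUES = ("hidden", "seizing", "non-seizing")


@dataclass
class SeizureObservation:
    """Observed state and onset times of one seizure on a region set."""

    region_ids: list[str]
    status: np.ndarray      # array of {"hidden", "seizing", "non-seizing"}
    onset_s: np.ndarray     # finite iff seizing, else +inf

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=object)
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        n = len(self.region_ids)
        if self.status.shape != (n,) or self.onset_s.shape != (n,):
            raise ValueError("status and onset_s must match region_ids in length")
        bad = set(self.status) - set(STATUS_VALUES)
        if bad:
            raise ValueError(f"unknown status values: {bad}")
        seizing = self.status == "seizing"
        if not np.array_equal(seizing, np.isfinite(self.onset_s)):
            raise ValueError("onset must be finite iff status is 'seizing'")
        if np.any(self.onset_s[seizing] <= 0):
            raise ValueError("onset times must be positive")

    # -- index helpers used throughout inference and validation
    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def seizing_idx(self) -> np.ndarray:
        return np.flatnonzero(self.status == "seizing")

    @property
    def nonseizing_idx(self) -> np.ndarray:
        return np.flatnonzero(self.status == "non-seizing")

    @property
    def observed_idx(self) -> np.ndarray:
        return np.flatnonzero(self.status != "hidden")

    @property
    def hidden_idx(self) -> np.ndarray:
        return np.flatnonzero(self.status == "hidden")

    @property
    def n_obs(self) -> int:
        return int(len(self.observed_idx))

    @property
    def t_seizing(self) -> np.ndarray:
        return self.onset_s[self.seizing_idx]

    def hide_region(self, idx: int) -> "SeizureObservation":
        """Return a copy with one region's observation removed (leave-one-out)."""
        status = self.status.copy()
        onset = self.onset_s.copy()
        status[idx] = "hidden"
        onset[idx] = np.inf
        return SeizureObservation(list(self.region_ids), status, onset)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"region_id": self.region_ids, "status": self.status, "onset_s": self.onset_s}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeizureObservation":
        df = pd.read_csv(path)
        return cls(
            df["region_id"].astype(str).tolist(),
            df["status"].to_numpy(dtype=object),
            df["onset_s"].to_numpy(dtype=float),
        )


@dataclass
class MultiSeizureData:
    """Cohort of (observation, connectome) pairs sharing one parcellation size."""

    seizures: list[tuple[SeizureObservation, Connectome]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = {obs.n_regions for obs, _ in self.seizures} | {
            w.n_regions for _, w in self.seizures
        }
        if len(sizes) > 1:
            raise ValueError("all seizures must share the same number of regions")
        for obs, w in self.seizures:
            if obs.n_regions != w.n_regions:
                raise ValueError("observation and connectome sizes differ")

    @property
    def n_seizures(self) -> int:
        return len(self.seizures)

    @property
    def n_regions(self) -> int:
        return self.seizures[0][0].n_regions if self.seizures else 0

    def __iter__(self):
        return iter(self.seizures)

    def __getitem__(self, k):
        return self.seizures[k]
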