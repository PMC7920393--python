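"""Weighted directed connectomes: container, normalization, resection, I/O.

The connectome is a dense nonnegative matrix ``W`` where ``W[i, j]`` is the
connection strength from region ``j`` to region ``i`` (row = target).  The
model requires the maximal sum of ingoing projections, ``max_i sum_j w_ij``,
to be at most one; the normalization below makes it exactly one.  This bound
guarantees that the network input a region receives while other regions are
seizing always falls in [0, 1], the domain of the excitation function.

Raw tractography output enters as streamline counts ``what_ij`` together with
region volumes: counts are scaled by the target-region volume to fiber
densities, an optional anterior/posterior hippocampus correction adds the
98th percentile of the scaled weights to both directed entries of each pair
(gray-matter connections invisible to white-matter tractography), and the
result is divided by the maximal ingoing sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Connectome", "RawConnectome", "normalize_connectome", "apply_resection"]


@dataclass
class Connectome:
    """Normalized weighted directed network over labeled brain regions."""

    weights: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal entries must be zero")
        if W.size and W.sum(axis=1).max() > 1.0 + 1e-9:
            raise ValueError(
                "max ingoing-weight sum exceeds 1; normalize the connectome first"
            )
        self.weights = W
        if self.region_ids is None:
            self.region_ids = [f"r{i}" for i in range(W.shape[0])]
        else:
            self.region_ids = [str(r) for r in self.region_ids]
        if len(self.region_ids) != W.shape[0]:
            raise ValueError("region_ids length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def index_of(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def node_strength(self, observed: Sequence[int] | None = None) -> np.ndarray:
        """Per-region strength sum_j (w_ij + w_ji), optionally restricted to
        an observed subset of j."""
        W = self.weights
        S = W + W.T
        if observed is None:
            return S.sum(axis=1)
        return S[:, list(observed)].sum(axis=1)

    # -- I/O: dense CSV with a header row of region ids (directed, row=target)
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=self.region_ids, columns=self.region_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Connectome":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("connectome CSV must have matching row/column region ids")
        return cls(df.to_numpy(dtype=float), list(df.columns.astype(str)))


@dataclass
class RawConnectome:
    """Unnormalized tractography output: streamline counts and region volumes."""

    fiber_counts: np.ndarray  # counts[i, j], streamlines j -> i
    volumes: np.ndarray       # mm^3, per target region
    region_ids: list[str] | None = None
    hippocampus_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        C = np.asarray(self.fiber_counts, dtype=float)
        V = np.asarray(self.volumes, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("fiber_counts must be square")
        if C.shape[0] != V.shape[0]:
            raise ValueError("volumes length must match matrix size")
        if np.any(C < 0):
            raise ValueError("fiber counts must be nonnegative")
        if np.any(V <= 0):
            raise ValueError("region volumes must be positive")
        self.fiber_counts, self.volumes = C, V
        if self.region_ids is None:
            self.region_ids = [f"r{i}" for i in range(C.shape[0])]


def normalize_connectome(
    raw: RawConnectome, *, percentile_over_nonzero: bool = False
) -> Connectome:
    """Volume-scale, hippocampus-correct, and ingoing-sum-normalize.

    Steps: ``w~_ij = what_ij / V_i``; for every (anterior, posterior)
    hippocampus pair both directed entries between the two regions are
    incremented by the 98th percentile of the scaled weights (all entries by
    default, nonzero entries if ``percentile_over_nonzero``); finally
    ``w_ij = w~_ij / max_i sum_j w~_ij`` so the maximal ingoing sum is 1.
    """
    ids = list(raw.region_ids or [])
    W = raw.fiber_counts / raw.volumes[:, None]
    np.fill_diagonal(W, 0.0)
    if raw.hippocampus_pairs:
        vals = W[W > 0] if percentile_over_nonzero else W.ravel()
        if vals.size == 0:
            raise ValueError("cannot take percentile of an all-zero connectome")
        p98 = np.percentile(vals, 98)  # linear interpolation
        for ant, post in raw.hippocampus_pairs:
            a, p = ids.index(str(ant)), ids.index(str(post))
            W[a, p] += p98
            W[p, a] += p98
    max_in = W.sum(axis=1).max()
    if max_in <= 0:
        raise ValueError("all-zero connectome cannot be normalized")
    return Connectome(W / max_in, ids)


def apply_resection(connectome: Connectome, resected: Sequence[str]) -> Connectome:
    """Remove a region set from the network (virtual surgery).

    Returns the submatrix on the surviving regions.  Ingoing sums can only
    decrease, so the normalization bound (<= 1) is preserved.
    """
    resected = set(map(str, resected))
    unknown = resected - set(connectome.region_ids)
    if unknown:
        raise KeyError(f"unknown region ids in resection set: {sorted(unknown)}")
    keep = [i for i, r in enumerate(connectome.region_ids) if r not in resected]
    sub = connectome.weights[np.ix_(keep, keep)]
    return Connectome(sub, [connectome.region_ids[i] for i in keep])
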