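"""Neighbor message passing: principal-neighborhood-style aggregation.

Each agent aggregates the observation vectors of its neighbors with four
aggregators (mean, max, min, population std), each modulated by three
degree scalers: identity, logarithmic amplification
``log(1 + deg) / log(1 + deg_avg)`` and its reciprocal (attenuation),
where ``deg`` is the neighbor count and ``deg_avg`` a running average
maintained by the trainer. With no neighbors the agent's own features
stand in for every aggregator (std = 0), so the feature layout is
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AGGREGATORS = ("mean", "max", "min", "std")
SCALERS = ("identity", "amplification", "attenuation")


@dataclass
class AggregatedFeatures:
    """Flattened neighbor aggregates in a fixed documented order:
    for each aggregator (mean, max, min, std), for each scaler
    (identity, amplification, attenuation), the feature vector."""

    vector: np.ndarray
    neighbor_count: int

    @staticmethod
    def width(n_features: int) -> int:
        return n_features * len(AGGREGATORS) * len(SCALERS)


def neighbors(positions: np.ndarray, alive: np.ndarray, i: int,
              radius: float) -> np.ndarray:
    """Indices of alive agents within Euclidean ``radius`` of agent i."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos - pos[i], axis=1)
    idx = np.flatnonzero((d <= radius) & np.asarray(alive, bool))
    return idx[idx != i]


def degree_scalers(deg: int, deg_avg: float) -> tuple[float, float, float]:
    """(identity, amplification, attenuation) for a neighbor count."""
    denom = np.log1p(max(deg_avg, 1e-9))
    if denom <= 0:
        return 1.0, 1.0, 1.0
    amp = np.log1p(deg) / denom
    if amp <= 0:
        # deg = 0: the aggregate falls back to the agent's own features,
        # scalers degenerate to identity
        return 1.0, 1.0, 1.0
    return 1.0, float(amp), float(1.0 / amp)


def aggregate(own: np.ndarray, neighbor_vectors: np.ndarray | list,
              deg_avg: float = 1.0) -> AggregatedFeatures:
    """Aggregate neighbor feature vectors (see module docstring)."""
    own = np.asarray(own, dtype=float)
    nv = np.asarray(neighbor_vectors, dtype=float)
    if nv.size == 0:
        nv = own[None, :]
        deg = 0
    else:
        if nv.ndim != 2 or nv.shape[1] != own.shape[0]:
            raise ValueError("neighbor vectors must match own feature length")
        deg = len(nv)
        # canonical ordering makes the aggregates bitwise permutation
        # invariant (floating-point sums are order dependent)
        nv = nv[np.lexsort(nv.T[::-1])]
    mean = nv.mean(axis=0)
    mx = nv.max(axis=0)
    mn = nv.min(axis=0)
    std = nv.std(axis=0)            # population std: 0 for one neighbor
    if deg == 0:
        std = np.zeros_like(own)
    scalers = degree_scalers(deg, deg_avg)
    parts = []
    for agg in (mean, mx, mn, std):
        for s in scalers:
            parts.append(agg * s)
    return AggregatedFeatures(vector=np.concatenate(parts),
                              neighbor_count=deg)
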