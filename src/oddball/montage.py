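"""Sensor montage: 2-D layouts, neighbourhood relations and region-of-interest groups.

The analyses in this package only need sensor *identities*, 2-D positions
(for interpolation and topography plots) and an adjacency relation (for
channel interpolation and cluster-based permutation tests).  The default
layout is a sunflower arrangement of sensors on the unit disc with
Delaunay-derived adjacency -- a desk-scale stand-in for a dense geodesic
net.  The +y direction is anterior (toward the front of the head).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["Montage", "disc_montage", "default_rois"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Montage:
    """A set of named sensors with 2-D positions and a symmetric adjacency."""

    names: tuple
    positions: np.ndarray  # (n_sensors, 2)
    adjacency: np.ndarray  # (n_sensors, n_sensors) bool

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        adj = np.asarray(self.adjacency, dtype=bool)
        n = len(self.names)
        if pos.shape != (n, 2):
            raise ValueError(f"positions must be ({n}, 2), got {pos.shape}")
        if adj.shape != (n, n):
            raise ValueError(f"adjacency must be ({n}, {n}), got {adj.shape}")
        if np.any(adj != adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency must be irreflexive (zero diagonal)")
        if n >= 2 and not np.all(adj.sum(axis=0) >= 1):
            raise ValueError("every sensor needs at least one neighbour")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_sensors(self) -> int:
        return len(self.names)

    def neighbors(self, idx: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[idx])


def disc_montage(n_sensors: int = 64) -> Montage:
    """Deterministic sunflower layout on the unit disc with Delaunay adjacency.

    Sensors are placed at radius sqrt(i/n) and angle i*golden-angle, which
    spreads them evenly over the disc.  Adjacency edges are the Delaunay
    triangulation edges, so each sensor is connected to its natural
    geometric neighbours.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors for a triangulated layout")
    i = np.arange(n_sensors)
    r = np.sqrt((i + 0.5) / n_sensors)
    theta = i * _GOLDEN_ANGLE
    pos = np.column_stack([r * np.sin(theta), r * np.cos(theta)])

    tri = Delaunay(pos)
    adj = np.zeros((n_sensors, n_sensors), dtype=bool)
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                adj[simplex[a], simplex[b]] = True
                adj[simplex[b], simplex[a]] = True
    names = tuple(f"E{k + 1:03d}" for k in i)
    return Montage(names=names, positions=pos, adjacency=adj)


def default_rois(montage: Montage) -> dict:
    """Anterior / fronto-central / centro-posterior sensor groups.

    Splits sensors into thirds by their anterior-posterior (y) coordinate:
    the anterior third hosts the first-sound evoked response (P1), the
    middle third the mismatch and P3a responses, and the posterior third
    the P3b.  Exact sensor identities never matter downstream -- every
    analysis takes the sensor list as a parameter.
    """
    y = montage.positions[:, 1]
    hi, lo = np.quantile(y, [2.0 / 3.0, 1.0 / 3.0])
    return {
        "P1": np.flatnonzero(y >= hi),
        "MMN_P3a": np.flatnonzero((y < hi) & (y >= lo)),
        "P3b": np.flatnonzero(y < lo),
    }
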