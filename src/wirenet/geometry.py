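"""Spatial embeddings of network units and their pairwise Euclidean distances.

Only the hidden recurrent layer carries geometry; dense input/output
projections have no spatial positions and hence no wiring cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["SpatialLayout", "place_on_circle", "pairwise_distances", "normalize_distances"]


@dataclass(frozen=True)
class SpatialLayout:
    """Fixed unit positions in 2D or 3D (arbitrary length units)."""

    coords: np.ndarray  # (n_units, dim)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(f"coords must be (n_units, 2|3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_units(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def distance_matrix(self) -> np.ndarray:
        return pairwise_distances(self)

    def to_csv(self, path) -> None:
        cols = ["x", "y", "z"][: self.dim]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "id", np.arange(self.n_units))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpatialLayout":
        df = pd.read_csv(path).sort_values("id")
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        return cls(df[cols].to_numpy(dtype=np.float64))


def place_on_circle(
    n_units: int,
    radius: float = 1.0,
    seed: int | None = None,
    mode: str = "random",
) -> SpatialLayout:
    """Place units on a circle of given radius centred at the origin.

    ``random`` draws angles uniformly on [0, 2pi) from a generator seeded
    with ``seed``; ``equally_spaced`` is deterministic with unit 0 at angle
    0, proceeding counter-clockwise.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if mode == "random":
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_units)
    elif mode == "equally_spaced":
        theta = 2.0 * np.pi * np.arange(n_units) / n_units
    else:
        raise ValueError(f"unknown mode {mode!r}")
    coords = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return SpatialLayout(coords)


def pairwise_distances(layout: SpatialLayout) -> np.ndarray:
    """Full symmetric Euclidean distance matrix D with D[i, i] = 0."""
    if layout.n_units == 1:
        return np.zeros((1, 1))
    return squareform(pdist(layout.coords, metric="euclidean"))


def normalize_distances(distances) -> np.ndarray:
    """Divide a sample of edge lengths by its maximum, mapping it into [0, 1]."""
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty distance sample")
    m = d.max()
    if m <= 0:
        raise ValueError("all-zero distance sample cannot be normalized")
    return d / m
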