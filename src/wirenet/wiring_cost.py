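"""Wiring cost of a spatially embedded sparse network.

The cost of a connection is the Euclidean distance it spans times the
magnitude of its weight; the network cost is the sum over all active
connections (a volume proxy), or a scale-invariant normalized ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SpatialLayout

__all__ = [
    "SparseNet",
    "wiring_cost_volume",
    "wiring_cost_normalized",
    "cost_gradient",
    "normalized_cost_gradient",
]


@dataclass
class SparseNet:
    """Binary connectivity mask + real weights over a spatial layout.

    ``mask[i, j] = 1`` means the directed connection i -> j is present;
    ``weights`` must be exactly zero wherever the mask is zero. Positive
    weights are excitatory, negative inhibitory.
    """

    mask: np.ndarray     # (n, n) in {0, 1}
    weights: np.ndarray  # (n, n) real
    layout: SpatialLayout

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = self.layout.n_units
        if self.mask.shape != (n, n) or self.weights.shape != (n, n):
            raise ValueError(
                f"mask/weights must be ({n}, {n}); got {self.mask.shape}, {self.weights.shape}"
            )
        if not np.array_equal(np.unique(self.mask), np.unique(self.mask).clip(0, 1)):
            raise ValueError("mask entries must be 0 or 1")
        if np.any((self.mask == 0) & (self.weights != 0)):
            raise ValueError("weights must be exactly 0 on masked-out entries")

    @property
    def n_units(self) -> int:
        return self.layout.n_units

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())

    def distance_matrix(self) -> np.ndarray:
        return self.layout.distance_matrix()

    def copy(self) -> "SparseNet":
        return SparseNet(self.mask.copy(), self.weights.copy(), self.layout)

    # -- serialization (sparse triplets i, j, w) ---------------------------

    def to_csv(self, path) -> None:
        i, j = np.nonzero(self.mask)
        pd.DataFrame({"i": i, "j": j, "w": self.weights[i, j]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layout: SpatialLayout) -> "SparseNet":
        df = pd.read_csv(path)
        n = layout.n_units
        mask = np.zeros((n, n))
        weights = np.zeros((n, n))
        mask[df["i"], df["j"]] = 1.0
        weights[df["i"], df["j"]] = df["w"]
        return cls(mask, weights, layout)


def wiring_cost_volume(net: SparseNet) -> float:
    """Volume-proxy wiring cost: sum over connections of A_ij * D_ij * |w_ij|."""
    D = net.distance_matrix()
    return float(np.sum(net.mask * D * np.abs(net.weights)))


def wiring_cost_normalized(net: SparseNet) -> float:
    """Scale-invariant wiring cost.

    Mean of |w| * D over the m active connections, divided by the root of
    (mean squared active weight) x (mean squared distance over all
    n(n-1) ordered unit pairs). Invariant under global positive rescaling
    of either the weights or the coordinates.
    """
    n = net.n_units
    if n < 2:
        raise ValueError("normalized cost needs at least two units")
    m = net.n_active
    if m == 0 or not np.any(net.weights):
        raise ValueError("normalized cost needs at least one active non-zero weight")
    D = net.distance_matrix()
    active = net.mask > 0
    mean_wd = np.mean(np.abs(net.weights[active]) * D[active])
    mean_w2 = np.mean(net.weights[active] ** 2)
    off = ~np.eye(n, dtype=bool)
    mean_d2 = np.mean(D[off] ** 2)
    return float(mean_wd / np.sqrt(mean_w2 * mean_d2))


def cost_gradient(net: SparseNet) -> np.ndarray:
    """Gradient of the volume cost w.r.t. the weights.

    Entry (i, j) is A_ij * D_ij * sign(w_ij); the subgradient at w = 0 is
    taken as 0, and masked-out entries are 0.
    """
    D = net.distance_matrix()
    return net.mask * D * np.sign(net.weights)


def normalized_cost_gradient(net: SparseNet) -> np.ndarray:
    """Analytic gradient of the normalized cost w.r.t. the weights."""
    n = net.n_units
    D = net.distance_matrix()
    active = net.mask > 0
    m = int(active.sum())
    mean_w2 = np.mean(net.weights[active] ** 2)
    off = ~np.eye(n, dtype=bool)
    mean_d2 = np.mean(D[off] ** 2)
    c = wiring_cost_normalized(net)
    grad = np.zeros_like(net.weights)
    grad[active] = (D[active] * np.sign(net.weights[active]) / m) / np.sqrt(
        mean_w2 * mean_d2
    ) - c * net.weights[active] / (m * mean_w2)
    return grad
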