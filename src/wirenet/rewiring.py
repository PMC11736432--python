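"""Dynamic sparse rewiring: SET, DeepR, and DSR with distance-biased regrowth.

All three strategies keep the number of active connections exactly
constant: every pruned connection is replaced by one grown at a currently
inactive position. With distance bias enabled, regrowth sites are sampled
with probability inversely proportional to the Euclidean distance the new
connection would span, encouraging short wiring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wiring_cost import SparseNet

__all__ = [
    "RewireConfig",
    "set_rewire",
    "deepr_update",
    "dsr_prune_and_grow",
    "sample_regrowth_sites",
    "SaturationError",
]


class SaturationError(RuntimeError):
    """No (or not enough) inactive positions available for regrowth."""


@dataclass
class RewireConfig:
    strategy: str = "set"          # {set, deepr, dsr}
    zeta: float = 0.3              # SET prune fraction per sign class
    alpha: float = 0.05            # DeepR learning rate
    xi: float = 1e-4               # DeepR L1 coefficient
    temperature: float = 1e-5      # DeepR random-walk noise scale
    epsilon_init: float = 1e-12    # DeepR activation weight for regrown edges
    H: float = 0.001               # DSR global prune threshold
    delta: float = 0.1             # DSR tolerance on the prune count
    K: int = 100                   # DSR target prune count per iteration
    distance_bias: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("set", "deepr", "dsr"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.zeta < 1:
            raise ValueError("zeta must be in (0, 1)")
        if self.H <= 0:
            raise ValueError("H must be > 0")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")


def sample_regrowth_sites(
    net: SparseNet,
    k: int,
    distance_bias: bool,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Sample k distinct inactive positions of the mask, without replacement.

    With distance bias, position (i, j) is drawn with probability
    proportional to 1 / D_ij among candidates; zero-distance pairs (self
    connections, coincident units) are excluded from biased sampling.
    Without bias, sampling is uniform over all inactive positions.
    """
    if k == 0:
        return []
    inactive = net.mask == 0
    if distance_bias:
        D = net.distance_matrix()
        cand = np.argwhere(inactive & (D > 0))
        if len(cand) < k:
            raise SaturationError(f"need {k} regrowth sites, only {len(cand)} available")
        w = 1.0 / D[cand[:, 0], cand[:, 1]]
        p = w / w.sum()
        idx = rng.choice(len(cand), size=k, replace=False, p=p)
    else:
        cand = np.argwhere(inactive)
        if len(cand) < k:
            raise SaturationError(f"need {k} regrowth sites, only {len(cand)} available")
        idx = rng.choice(len(cand), size=k, replace=False)
    return [tuple(pair) for pair in cand[idx]]


def _smallest_magnitude(values: np.ndarray, rows: np.ndarray, cols: np.ndarray, k: int):
    """Indices of the k smallest-|w| entries; ties broken by (i, j) order."""
    order = np.lexsort((cols, rows, np.abs(values)))
    return order[:k]


def set_rewire(
    net: SparseNet,
    zeta: float,
    rng: np.random.Generator,
    distance_bias: bool = False,
) -> SparseNet:
    """Sparse evolutionary training step.

    Prunes the fraction zeta of smallest-magnitude non-negative and of
    smallest-magnitude negative active connections, then grows the same
    total number of connections at inactive positions, initialized to 0.
    """
    if not 0 < zeta < 1:
        raise ValueError("zeta must be in (0, 1)")
    net = net.copy()
    i, j = np.nonzero(net.mask)
    if len(i) == 0:
        raise ValueError("net has no active connections")
    w = net.weights[i, j]

    n_pruned = 0
    for sign_sel in (w >= 0, w < 0):
        ii, jj, ww = i[sign_sel], j[sign_sel], w[sign_sel]
        k = int(np.floor(zeta * len(ww)))
        if k == 0:
            continue
        drop = _smallest_magnitude(ww, ii, jj, k)
        net.mask[ii[drop], jj[drop]] = 0.0
        net.weights[ii[drop], jj[drop]] = 0.0
        n_pruned += k

    for (gi, gj) in sample_regrowth_sites(net, n_pruned, distance_bias, rng):
        net.mask[gi, gj] = 1.0
        net.weights[gi, gj] = 0.0
    return net


def deepr_update(
    net: SparseNet,
    signs: np.ndarray,
    grads: np.ndarray,
    config: RewireConfig,
    rng: np.random.Generator,
) -> tuple[SparseNet, np.ndarray]:
    """Deep rewiring update of all active connections.

    Each active weight takes a gradient step plus an L1 pull toward zero
    along its fixed sign and a Gaussian random walk:
    ``w' = w - alpha * grad - alpha * xi * s + sqrt(2 * alpha * T) * nu``.
    A connection whose updated weight crosses zero against its sign is
    deactivated, and for each deactivation one inactive position is
    activated with weight s' * epsilon (s' a fresh random sign).

    Returns the updated net and sign matrix; the active count is conserved.
    """
    net = net.copy()
    signs = np.asarray(signs, dtype=np.float64).copy()
    active = net.mask > 0
    if np.any(active & (np.abs(signs) != 1)):
        raise RuntimeError("every active connection needs a sign in {-1, +1}")
    nonzero = active & (net.weights != 0)
    if np.any(np.sign(net.weights[nonzero]) != signs[nonzero]):
        raise RuntimeError("active weight sign disagrees with its assigned sign")

    a, xi, T = config.alpha, config.xi, config.temperature
    noise = np.sqrt(2.0 * a * T) * rng.standard_normal(size=int(active.sum()))
    w = net.weights[active]
    w_new = w - a * grads[active] - a * xi * signs[active] + noise

    flipped = signs[active] * w_new <= 0
    w_new[flipped] = 0.0
    net.weights[active] = w_new
    act_idx = np.argwhere(active)
    dead = act_idx[flipped]
    net.mask[dead[:, 0], dead[:, 1]] = 0.0
    signs[dead[:, 0], dead[:, 1]] = 0.0

    n_grow = len(dead)
    if n_grow:
        sites = sample_regrowth_sites(net, n_grow, config.distance_bias, rng)
        new_signs = rng.choice([-1.0, 1.0], size=n_grow)
        for (gi, gj), s in zip(sites, new_signs):
            net.mask[gi, gj] = 1.0
            signs[gi, gj] = s
            net.weights[gi, gj] = s * config.epsilon_init
    return net, signs


def dsr_prune_and_grow(
    nets: list[SparseNet],
    config: RewireConfig,
    rng: np.random.Generator,
) -> tuple[list[SparseNet], float]:
    """Dynamic sparse reparameterization across a list of layers.

    Prunes every active weight with |w| < H globally; adapts H for the
    next iteration (halved if the pruned count exceeded (1 + delta) * K,
    doubled if it fell below (1 - delta) * K); then grows, allocating to
    layer l the share G_l = R_l / sum(R) of the total pruned count (R_l =
    surviving parameters), with largest-remainder rounding. Regrown
    weights start at 0. The global active count is conserved.
    """
    nets = [net.copy() for net in nets]
    H = config.H

    pruned_counts = []
    for net in nets:
        prune = (net.mask > 0) & (np.abs(net.weights) < H)
        pruned_counts.append(int(prune.sum()))
        net.mask[prune] = 0.0
        net.weights[prune] = 0.0
    total_pruned = sum(pruned_counts)
    survivors = np.array([net.n_active for net in nets], dtype=np.float64)

    if total_pruned > (1 + config.delta) * config.K:
        H_new = H / 2.0
    elif total_pruned < (1 - config.delta) * config.K:
        H_new = H * 2.0
    else:
        H_new = H

    if total_pruned == 0:
        return nets, H_new

    # largest-remainder allocation of the regrowth budget across layers
    if survivors.sum() > 0:
        raw = survivors / survivors.sum() * total_pruned
    else:
        raw = np.full(len(nets), total_pruned / len(nets))
    grow = np.floor(raw).astype(int)
    remainder = raw - grow
    for idx in np.argsort(-remainder)[: total_pruned - grow.sum()]:
        grow[idx] += 1

    # cap at each layer's free slots; redistribute overflow
    capacity = np.array([int((net.mask == 0).sum()) for net in nets])
    if capacity.sum() < total_pruned:
        raise SaturationError("not enough inactive positions across layers")
    overflow = int(np.maximum(grow - capacity, 0).sum())
    grow = np.minimum(grow, capacity)
    while overflow > 0:
        room = capacity - grow
        for idx in np.argsort(-room):
            if overflow == 0:
                break
            if room[idx] > 0:
                take = min(room[idx], overflow)
                grow[idx] += take
                overflow -= take

    for net, g in zip(nets, grow):
        for (gi, gj) in sample_regrowth_sites(net, int(g), config.distance_bias, rng):
            net.mask[gi, gj] = 1.0
            net.weights[gi, gj] = 0.0
    return nets, H_new
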