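"""Biological connectomes: parsing, bio-instantiated models, and
geometric comparison of trained wiring with the organism's.

A connectome is a neuron-level map: neuron ids with 3D coordinates and a
role (sensory / inter / motor), plus directed synaptic edges. A
bio-instantiated model copies the map verbatim: hidden-layer size equals
the neuron count, the recurrent mask equals the edge set, and unit
positions equal the neuron coordinates. After cost-controlled training,
the distribution of connection lengths is compared with the organism's
via the two-sample Kolmogorov-Smirnov distance, against a baseline in
which neuron positions are randomly rearranged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd

from .geometry import SpatialLayout, pairwise_distances
from .models import SparseRecurrentModel
from .netanalysis import connection_distance_sample, ks_distance, randomize_positions
from .wiring_cost import SparseNet

__all__ = [
    "Connectome",
    "read_connectome",
    "largest_connected_component",
    "build_bio_model",
    "geometry_match_report",
    "GeometryMatchReport",
    "synthetic_connectome",
]

ROLES = ("sensory", "inter", "motor", "unknown")


@dataclass
class Connectome:
    """Neurons (id, x, y, z, role) and directed edges (pre, post, n_synapses)."""

    neurons: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self):
        ids = set(self.neurons["id"])
        if len(ids) != len(self.neurons):
            raise ValueError("duplicate neuron ids")
        bad_role = set(self.neurons["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown roles: {sorted(bad_role)}")
        for col in ("pre", "post"):
            dangling = set(self.edges[col]) - ids
            if dangling:
                raise ValueError(f"edge references unknown neuron id(s): {sorted(dangling)}")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_edges(self) -> int:
        """Number of distinct directed connection pairs."""
        return len(self.edges)

    def index_of(self) -> dict:
        return {nid: k for k, nid in enumerate(self.neurons["id"])}

    def layout(self) -> SpatialLayout:
        return SpatialLayout(self.neurons[["x", "y", "z"]].to_numpy(dtype=np.float64))

    def mask(self) -> np.ndarray:
        idx = self.index_of()
        m = np.zeros((self.n_neurons, self.n_neurons))
        m[
            self.edges["pre"].map(idx).to_numpy(),
            self.edges["post"].map(idx).to_numpy(),
        ] = 1.0
        return m

    def to_graph(self, directed: bool = False) -> nx.Graph:
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(self.neurons["id"])
        g.add_edges_from(zip(self.edges["pre"], self.edges["post"]))
        return g

    def connection_distances(self, normalize: bool = False) -> np.ndarray:
        D = pairwise_distances(self.layout())
        idx = self.index_of()
        d = D[
            self.edges["pre"].map(idx).to_numpy(),
            self.edges["post"].map(idx).to_numpy(),
        ]
        if normalize:
            from .geometry import normalize_distances

            d = normalize_distances(d)
        return d

    # Graph summary statistics used to validate parsed maps.

    def clustering(self) -> float:
        return float(nx.average_clustering(self.to_graph(directed=False)))

    def mean_network_distance(self) -> float:
        """Mean shortest-path length of the undirected graph."""
        return float(nx.average_shortest_path_length(self.to_graph(directed=False)))


def read_connectome(neurons_path, edges_path) -> Connectome:
    """Load a connectome from neurons.csv (id, x, y, z[, role]) and
    edges.csv (pre, post[, n_synapses]).

    Duplicate neuron rows are dropped; repeated (pre, post) rows collapse
    to one connection pair with summed synapse multiplicity.
    """
    neurons = pd.read_csv(neurons_path)
    edges = pd.read_csv(edges_path)
    required = {"id", "x", "y", "z"}
    if missing := required - set(neurons.columns):
        raise ValueError(f"neurons file missing columns: {sorted(missing)}")
    if missing := {"pre", "post"} - set(edges.columns):
        raise ValueError(f"edges file missing columns: {sorted(missing)}")
    if "role" not in neurons.columns:
        neurons["role"] = "unknown"
    neurons = neurons.drop_duplicates(subset="id").reset_index(drop=True)
    neurons["role"] = neurons["role"].fillna("unknown")

    no_coords = neurons.loc[
        neurons[["x", "y", "z"]].isna().any(axis=1), "id"
    ].tolist()
    if no_coords:
        raise ValueError(f"neurons missing coordinates: {no_coords}")

    ids = set(neurons["id"])
    for row, (pre, post) in enumerate(zip(edges["pre"], edges["post"])):
        if pre not in ids:
            raise ValueError(f"edges row {row}: unknown neuron id {pre!r}")
        if post not in ids:
            raise ValueError(f"edges row {row}: unknown neuron id {post!r}")

    if "n_synapses" not in edges.columns:
        edges["n_synapses"] = 1
    edges = (
        edges.groupby(["pre", "post"], as_index=False, sort=False)["n_synapses"].sum()
    )
    return Connectome(neurons=neurons, edges=edges)


def largest_connected_component(connectome: Connectome) -> Connectome:
    """Induced sub-connectome on the largest component (undirected sense)."""
    if connectome.n_neurons == 0:
        raise ValueError("empty connectome")
    g = connectome.to_graph(directed=False)
    keep = max(nx.connected_components(g), key=len)
    neurons = connectome.neurons[connectome.neurons["id"].isin(keep)].reset_index(drop=True)
    edges = connectome.edges[
        connectome.edges["pre"].isin(keep) & connectome.edges["post"].isin(keep)
    ].reset_index(drop=True)
    return Connectome(neurons=neurons, edges=edges)


def build_bio_model(
    connectome: Connectome,
    task_shape: tuple[int, int],
    io_mapping: str = "dense",
    cell_type: str = "gru",
    seed: int = 0,
    **cell_kwargs,
) -> tuple[SparseRecurrentModel, SpatialLayout]:
    """Bio-instantiated recurrent model: hidden size, mask, and unit
    positions copied exactly from the connectome.

    ``dense`` feeds inputs to every hidden unit and reads output from all
    of them; ``sensory_motor`` projects inputs only into sensory-neuron
    units and reads output only from motor-neuron units.
    """
    input_size, output_size = task_shape
    layout = connectome.layout()
    mask = connectome.mask()
    input_units = output_units = None
    if io_mapping == "sensory_motor":
        roles = connectome.neurons["role"].to_numpy()
        if not {"sensory", "motor"} <= set(roles):
            raise ValueError("sensory_motor mapping requires sensory and motor roles")
        input_units = (roles == "sensory").astype(float)
        output_units = (roles == "motor").astype(float)
    elif io_mapping != "dense":
        raise ValueError(f"unknown io_mapping {io_mapping!r}")
    model = SparseRecurrentModel(
        cell_type,
        input_size,
        connectome.n_neurons,
        output_size,
        mask,
        layout,
        seed=seed,
        input_units=input_units,
        output_units=output_units,
        **cell_kwargs,
    )
    return model, layout


@dataclass
class GeometryMatchReport:
    ks_trained: float        # trained net vs organism
    ks_randomized: float     # position-randomized baseline vs organism
    trained_sample: np.ndarray
    reference_sample: np.ndarray
    randomized_sample: np.ndarray

    def ecdf_frame(self) -> pd.DataFrame:
        rows = []
        for name, sample in (
            ("trained", self.trained_sample),
            ("reference", self.reference_sample),
            ("randomized", self.randomized_sample),
        ):
            s = np.sort(sample)
            rows.append(
                pd.DataFrame(
                    {"condition": name, "distance": s, "ecdf": np.arange(1, len(s) + 1) / len(s)}
                )
            )
        return pd.concat(rows, ignore_index=True)


def geometry_match_report(
    trained: SparseNet,
    reference: Connectome,
    seed: int = 0,
) -> GeometryMatchReport:
    """Compare connection-length distributions of a trained net and the
    organism it was instantiated from (distances max-normalized)."""
    ref_sample = reference.connection_distances(normalize=True)
    trained_sample = connection_distance_sample(trained, normalize=True)
    randomized = randomize_positions(trained, seed=seed)
    rand_sample = connection_distance_sample(randomized, normalize=True)
    return GeometryMatchReport(
        ks_trained=ks_distance(trained_sample, ref_sample),
        ks_randomized=ks_distance(rand_sample, ref_sample),
        trained_sample=trained_sample,
        reference_sample=ref_sample,
        randomized_sample=rand_sample,
    )


def synthetic_connectome(
    n: int,
    m: int,
    decay_scale: float = 0.2,
    seed: int = 0,
) -> Connectome:
    """Random connectome with distance-dependent connectivity (synthetic
    stand-in with the spatial statistics the geometric comparison assumes).

    n neurons at uniform positions in the unit cube; m distinct directed
    edges sampled with probability proportional to exp(-D_ij / decay_scale).
    Roles: first ceil(0.3 n) sensory, last ceil(0.4 n) motor, rest inter.
    """
    if m > n * (n - 1):
        raise ValueError(f"m = {m} exceeds n(n-1) = {n * (n - 1)}")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n, 3))
    D = pairwise_distances(SpatialLayout(coords))
    pairs = np.argwhere(~np.eye(n, dtype=bool))
    logits = -D[pairs[:, 0], pairs[:, 1]] / decay_scale
    p = np.exp(logits - logits.max())
    p /= p.sum()
    chosen = rng.choice(len(pairs), size=m, replace=False, p=p)

    n_sensory = int(np.ceil(0.3 * n))
    n_motor = int(np.ceil(0.4 * n))
    roles = np.array(["inter"] * n, dtype=object)
    roles[:n_sensory] = "sensory"
    roles[n - n_motor :] = "motor"

    neurons = pd.DataFrame(
        {
            "id": [f"n{k}" for k in range(n)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "role": roles,
        }
    )
    edges = pd.DataFrame(
        {
            "pre": [f"n{i}" for i in pairs[chosen, 0]],
            "post": [f"n{j}" for j in pairs[chosen, 1]],
            "n_synapses": 1,
        }
    )
    return Connectome(neurons=neurons, edges=edges)
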