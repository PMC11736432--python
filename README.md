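# wirenet

Wiring-cost-controlled training and topology analysis of spatially
embedded sparse recurrent neural networks.

Biological nervous systems pay a physical price for every connection:
axons occupy volume and consume energy in proportion to the distance
they span. Brain wiring therefore reflects a trade-off between task
performance and wiring economy — a trade-off absent from conventional
artificial networks, whose connections have no geometry at all.
`wirenet` gives the hidden units of a sparse recurrent network fixed
spatial positions and trains weights *and* topology under the joint
objective

```
L = E(X, y; θ) + η · C_wiring,        C_wiring = Σ_ij A_ij · D_ij · |w_ij|
```

where `A` is the binary connectivity mask of the hidden layer, `D` the
Euclidean distance matrix of the unit positions, `w` the recurrent
weights, and `η` the cost-penalty coefficient. Topology evolves by
dynamic sparse rewiring — SET (magnitude pruning + regrowth), DeepR
(sign-constrained stochastic rewiring), or DSR (adaptive-threshold
pruning with layer-wise reallocation) — with new connections sampled
with probability ∝ 1/D, and the total connection count held exactly
constant throughout.

The package is for computational-neuroscience and network-science
practitioners who want to study how wiring economy shapes network
structure: it covers the training framework (RNN, CT-RNN, Neural ODE,
GRU cells), graph analysis of the trained masks (modularity, clustering,
Louvain modules), lesion-based module-specialization statistics, and
geometric comparison of trained wiring with biological connectomes via
the Kolmogorov–Smirnov distance between connection-length
distributions.

## Worked example

Train a 64-unit sparse GRU (10% recurrent density, units on the unit
circle) on a generated 7-class sequence task, with and without cost
pressure, and compare the trained topology:

```python
import wirenet as wn
from wirenet.models import make_sparse_model
from wirenet.trainer import TrainConfig, train
from wirenet.rewiring import RewireConfig
from wirenet.netanalysis import mask_to_graph, louvain_partition, \
    modularity, clustering_coefficient

ds = wn.generate_classification_task(seed=11, n_per_class=100)

for eta in (0.0, 1e-2):
    model = make_sparse_model("gru", 7, 64, 7, density=0.1, seed=0)
    cfg = TrainConfig(eta=eta, seed=0, strategy=RewireConfig(strategy="set"))
    best, history = train(model, ds, cfg)
    g = mask_to_graph(best.mask)
    q = modularity(g, louvain_partition(g, seed=0))
    _, c = clustering_coefficient(g)
    X, y = ds.subset("test")
    print(f"eta={eta:<6g} acc={best.accuracy(X, y):.3f} "
          f"Q={q:.3f} C={c:.3f} cost={history.wiring_cost.iloc[-1]:.1f}")
```

Output:

```
eta=0      acc=0.957 Q=0.226 C=0.204 cost=131.0
eta=0.01   acc=1.000 Q=0.318 C=0.280 cost=1.8
```

Reading: at `η = 10⁻²` the network keeps (here: slightly improves) its
test accuracy while its wiring cost collapses by two orders of
magnitude, and the hidden graph reorganizes from random-like (Q ≈ 0.23,
C ≈ 0.20, the expectation for a random graph at this density) into a
spatially clustered, modular topology (Q ≈ 0.32, C ≈ 0.28) — the same
trade-off pattern observed in real brain networks.

A thin CLI wraps the same pipeline:

```
wirenet train --model gru --strategy set --eta 1e-3 --seed 7 --out run/
wirenet bio-compare --connectome maps/ciona/ --eta 1e-3 --out report/
```

`bio-compare` expects `neurons.csv` (id, x, y, z, role) and `edges.csv`
(pre, post, n_synapses) and reports the K–S distance between the trained
network's connection-length distribution and the organism's, against a
position-randomized baseline.

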