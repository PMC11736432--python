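"""Desk-scale reference experiments.

Scaled-down counterparts of the three headline analyses — the wiring-cost
penalty sweep, the module-lesion specialization comparison, and the
connectome geometry match — plus the density-bound check for the
131-unit configuration. Problem sizes (64-unit sweep models, a 131-unit
/ 1,500-connection lesion configuration, an 80-neuron synthetic
connectome, a 7-class / 7-feature / 32-step task with 100 sequences per
class) are chosen so a full replication runs on a laptop CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bio_connectome import build_bio_model, geometry_match_report, synthetic_connectome
from .geometry import place_on_circle
from .lesion import lesion_report
from .models import SparseRecurrentModel, make_sparse_model
from .netanalysis import louvain_partition, mask_to_graph
from .rewiring import RewireConfig
from .synthetic_tasks import SequenceDataset, generate_classification_task
from .trainer import TrainConfig, eta_sweep, train

__all__ = [
    "default_dataset",
    "sweep_experiment",
    "best_nonzero_eta",
    "lesion_experiment",
    "connectome_experiment",
    "density_experiment",
    "make_131_unit_model",
]

SWEEP_ETAS = (0.0, 1e-4, 1e-3, 1e-2)
LESION_ETA = 1e-3
CONNECTOME_ETA = 1e-2
CONNECTOME_XI = 5e-3  # DeepR L1: high enough that the eta=0 baseline
# reaches its rewiring equilibrium (decorrelates from the initial mask)
# within the 30-epoch desk budget


def default_dataset(seed: int, n_per_class: int = 100) -> SequenceDataset:
    """The 7-class, 7-feature, 32-step sequence task used throughout."""
    return generate_classification_task(
        n_classes=7, seq_len=32, n_features=7, n_per_class=n_per_class, seed=seed
    )


def make_131_unit_model(seed: int, n_connections: int = 1500) -> SparseRecurrentModel:
    """GRU with 131 hidden units on a circle and a fixed connection budget."""
    rng = np.random.default_rng(seed)
    mask = np.zeros(131 * 131)
    mask[rng.choice(131 * 131, n_connections, replace=False)] = 1.0
    return SparseRecurrentModel(
        "gru", 7, 131, 7, mask.reshape(131, 131), place_on_circle(131, seed=seed), seed=seed
    )


def sweep_experiment(
    dataset_seed: int,
    run_seeds: list[int],
    etas=SWEEP_ETAS,
    hidden: int = 64,
    density: float = 0.1,
):
    """Penalty sweep of the 64-unit sparse GRU (SET rewiring)."""
    dataset = default_dataset(dataset_seed)
    factory = lambda seed: make_sparse_model(
        "gru", 7, hidden, 7, density=density, seed=seed
    )
    config = TrainConfig(strategy=RewireConfig(strategy="set"))
    return eta_sweep(factory, dataset, list(etas), run_seeds, config)


def best_nonzero_eta(df: pd.DataFrame) -> float:
    """Highest mean test accuracy among non-zero penalties; ties resolved
    toward the larger (more economical) penalty."""
    nz = df[df.eta > 0].groupby("eta")["test_accuracy"].mean()
    best_acc = nz.max()
    return float(nz[nz >= best_acc - 1e-12].index.max())


def lesion_experiment(
    dataset_seed: int,
    run_seeds: list[int],
    eta_cost: float = LESION_ETA,
) -> pd.DataFrame:
    """Module-lesion specialization for cost-trained vs cost-free runs.

    Trains the 131-unit / 1,500-connection GRU, partitions the trained
    hidden graph with Louvain, lesions each module, and reports the
    average task and module variances. Lesions are evaluated on the full
    pooled dataset for per-class resolution.
    """
    dataset = default_dataset(dataset_seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for eta in (0.0, eta_cost):
            for seed in run_seeds:
                config = TrainConfig(
                    eta=eta, seed=seed, strategy=RewireConfig(strategy="set")
                )
                best, _ = train(make_131_unit_model(seed), dataset, config)
                part = louvain_partition(mask_to_graph(best.mask), seed=seed, restarts=5)
                rep = lesion_report(best, part, dataset.X, dataset.y)
                rows.append(
                    {
                        "eta": eta,
                        "seed": seed,
                        "avg_task_variance": rep.avg_task_variance,
                        "avg_module_variance": rep.avg_module_variance,
                        "n_modules": len(set(part.values())),
                    }
                )
    return pd.DataFrame(rows)


def connectome_experiment(
    dataset_seed: int,
    run_seeds: list[int],
    eta: float = CONNECTOME_ETA,
    n: int = 80,
    m: int = 640,
    decay_scale: float = 0.1,
) -> pd.DataFrame:
    """Geometry match of bio-instantiated GRUs to a spatially organized
    synthetic connectome, with DeepR rewiring, at eta = 0 vs a moderate
    penalty. The reference uses a short decay scale, mirroring the strong
    short-range bias of real neural maps. Reports the K-S distance of the
    trained and position-randomized connection-length distributions to
    the reference's."""
    conn = synthetic_connectome(n=n, m=m, decay_scale=decay_scale, seed=dataset_seed)
    dataset = default_dataset(dataset_seed)
    X_test, y_test = dataset.subset("test")
    rows = []
    for eta_run in (0.0, eta):
        for seed in run_seeds:
            model, _ = build_bio_model(conn, (7, 7), io_mapping="dense", seed=seed)
            config = TrainConfig(
                eta=eta_run,
                seed=seed,
                strategy=RewireConfig(strategy="deepr", xi=CONNECTOME_XI),
            )
            best, _ = train(model, dataset, config)
            rep = geometry_match_report(best.to_sparse_net(), conn, seed=seed)
            rows.append(
                {
                    "eta": eta_run,
                    "seed": seed,
                    "test_accuracy": best.accuracy(X_test, y_test),
                    "ks_trained": rep.ks_trained,
                    "ks_randomized": rep.ks_randomized,
                }
            )
    return pd.DataFrame(rows)


def density_experiment(dataset_seed: int, seed: int, epochs: int = 12) -> pd.DataFrame:
    """Track recurrent connection density of the 131-unit configuration
    (10% budget) across rewiring epochs."""
    dataset = default_dataset(dataset_seed, n_per_class=20)
    model = make_131_unit_model(seed, n_connections=int(round(0.1 * 131 * 131)))
    config = TrainConfig(
        epochs=epochs, seed=seed, strategy=RewireConfig(strategy="set")
    )
    _, history = train(model, dataset, config)
    history["density"] = history["n_active"] / (131 * 131)
    return history
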