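"""Seeded generators of sequence-classification datasets.

Emulates the statistical shape of small wearable-sensor / gesture-phase
style benchmarks: multivariate time series with a handful of classes,
class-dependent temporal structure, additive noise, features scaled to
[0, 1], and train/validation/test splits of 0.75 : 0.15 : 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SequenceDataset", "generate_classification_task", "windowize"]


@dataclass
class SequenceDataset:
    """Sequences (N, T, F) with integer labels and index-based splits."""

    X: np.ndarray
    y: np.ndarray
    splits: dict[str, np.ndarray]

    def __post_init__(self):
        if self.X.ndim != 3:
            raise ValueError("X must be (N, T, F)")
        if len(self.y) != len(self.X):
            raise ValueError("labels must match sequences")

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    @property
    def n_features(self) -> int:
        return self.X.shape[2]

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.splits[split]
        return self.X[idx], self.y[idx]


def _stratified_splits(
    y: np.ndarray,
    ratios: tuple[float, float, float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return {
        "train": np.concatenate(train),
        "val": np.concatenate(val),
        "test": np.concatenate(test),
    }


def generate_classification_task(
    n_classes: int = 7,
    seq_len: int = 32,
    n_features: int = 7,
    n_per_class: int = 30,
    noise_sd: float = 0.05,
    drive_jitter: float = 0.35,
    seed: int = 0,
    split_ratios: tuple[float, float, float] = (0.75, 0.15, 0.1),
) -> SequenceDataset:
    """Class-conditional latent linear dynamics plus two noise sources.

    Each class k owns a stable random linear recurrence
    ``z_{t+1} = rho * R_k z_t + u`` (R_k a random rotation-like matrix,
    u a class-specific drive, z_0 = 0). Each sequence perturbs the drive
    once, ``u = u_k + drive_jitter * eps`` (execution variability: the
    whole trajectory shifts coherently, as repeated performances of the
    same activity differ), and adds i.i.d. Gaussian frame noise of sd
    ``noise_sd`` (sensor noise). Features are min-max scaled to [0, 1]
    over the whole dataset. With noise_sd = 0 and drive_jitter = 0 all
    sequences within a class are identical.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if seq_len < 1 or n_features < 1 or n_per_class < 1:
        raise ValueError("degenerate dataset shape")
    rng = np.random.default_rng(seed)
    rho = 0.85

    recurrences = np.empty((n_classes, n_features, n_features))
    for k in range(n_classes):
        A = rng.standard_normal((n_features, n_features))
        # scale to spectral radius rho for a stable recurrence
        A *= rho / max(np.abs(np.linalg.eigvals(A)).max(), 1e-12)
        recurrences[k] = A

    # class drives along a random orthonormal frame: equal pairwise
    # separation (drive_scale * sqrt(2)) regardless of seed
    drive_scale = 2.3
    g = rng.standard_normal((n_features, max(n_classes, n_features)))
    q, _ = np.linalg.qr(g[:, :n_features])
    dirs = q.T
    if n_classes > n_features:  # extra classes: random unit directions
        extra = rng.standard_normal((n_classes - n_features, n_features))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        dirs = np.vstack([dirs, extra])
    drives = drive_scale * dirs[:n_classes]

    N = n_classes * n_per_class
    y = np.repeat(np.arange(n_classes), n_per_class)
    X = np.empty((N, seq_len, n_features))
    for s in range(N):
        k = y[s]
        u = drives[k] + drive_jitter * rng.standard_normal(n_features)
        z = np.zeros(n_features)
        for t in range(seq_len):
            z = recurrences[k] @ z + u
            X[s, t] = z
    X += noise_sd * rng.standard_normal((N, seq_len, n_features))

    lo, hi = X.min(), X.max()
    X = (X - lo) / (hi - lo) if hi > lo else np.zeros_like(X)

    splits = _stratified_splits(y, split_ratios, rng)
    return SequenceDataset(X, y, splits)


def windowize(
    features: np.ndarray,
    frame_labels: np.ndarray,
    window: int,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a long labelled sequence (L, F) into overlapping windows.

    Returns windows (n, window, F) and one label per window, inherited
    from the window's final frame.
    """
    features = np.asarray(features)
    frame_labels = np.asarray(frame_labels)
    L = features.shape[0]
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = np.arange(0, L - window + 1, stride)
    X = np.stack([features[s : s + window] for s in starts])
    y = frame_labels[starts + window - 1]
    return X, y
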