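"""Multimodal autoencoder fusing the nine PPMI matrices into drug features.

Architecture (deepNF-style, one encoder branch per network with a shared
bottleneck):

    per-network encoder  x_i (n_drugs) -> h1_i (per_network_hidden), sigmoid
    concatenation        [h1_1 .. h1_K]
    joint layer          -> joint_hidden, sigmoid, dropout
    embedding layer      -> embedding_dim, sigmoid          <- fused features
    mirrored decoder     -> joint_hidden -> K x per_network_hidden
    per-network head     -> n_drugs, sigmoid reconstruction

Inputs are min-max scaled to [0, 1] per network so the sigmoid
reconstruction heads and binary cross-entropy loss are well matched.
Training is plain minibatch Adam; everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, bce, dsigmoid, glorot, sigmoid
from .containers import DrugVocabulary, FusedFeatures, PPMIMatrix

__all__ = [
    "MAEConfig",
    "TrainingHistory",
    "scale_inputs",
    "MultimodalAutoencoder",
    "build_mae",
    "train_mae",
    "extract_features",
    "save_mae",
    "load_mae",
]


@dataclass(frozen=True)
class MAEConfig:
    per_network_hidden: int = 256
    joint_hidden: int = 512
    embedding_dim: int = 128
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_network_hidden", "joint_hidden", "embedding_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch total loss and per-network reconstruction losses."""

    total: list[float] = field(default_factory=list)
    per_network: list[list[float]] = field(default_factory=list)


def scale_inputs(ppmis) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """Min-max scale each matrix to [0, 1]; returns matrices and (min, max) pairs.

    A constant matrix scales to all zeros (there is nothing to reconstruct).
    """
    mats = [p.matrix if isinstance(p, PPMIMatrix) else np.asarray(p, float) for p in ppmis]
    if not mats:
        raise ValueError("no matrices to scale")
    scaled, params = [], []
    for m in mats:
        lo, hi = float(m.min()), float(m.max())
        if hi > lo:
            scaled.append((m - lo) / (hi - lo))
        else:
            scaled.append(np.zeros_like(m))
        params.append((lo, hi))
    return scaled, params


class MultimodalAutoencoder:
    """Seeded NumPy implementation of the fusion autoencoder."""

    def __init__(self, cfg: MAEConfig, n_networks: int, n_drugs: int):
        self.cfg = cfg
        self.n_networks = n_networks
        self.n_drugs = n_drugs
        rng = np.random.default_rng(cfg.seed)
        h1, h2, d = cfg.per_network_hidden, cfg.joint_hidden, cfg.embedding_dim
        p: dict[str, np.ndarray] = {}
        for i in range(n_networks):
            p[f"We{i}"] = glorot(rng, n_drugs, h1)
            p[f"be{i}"] = np.zeros(h1)
            p[f"Wo{i}"] = glorot(rng, h1, n_drugs)
            p[f"bo{i}"] = np.zeros(n_drugs)
        p["Wj"] = glorot(rng, n_networks * h1, h2)
        p["bj"] = np.zeros(h2)
        p["Wz"] = glorot(rng, h2, d)
        p["bz"] = np.zeros(d)
        p["Wd1"] = glorot(rng, d, h2)
        p["bd1"] = np.zeros(h2)
        p["Wd2"] = glorot(rng, h2, n_networks * h1)
        p["bd2"] = np.zeros(n_networks * h1)
        self.params = p
        self._train_rng = np.random.default_rng(rng.integers(2**31))

    # -- forward -----------------------------------------------------------

    def forward(self, xs: list[np.ndarray], dropout: bool = False):
        """Forward pass; returns (reconstructions, embedding, cache)."""
        p = self.params
        K, h1 = self.n_networks, self.cfg.per_network_hidden
        a1 = [sigmoid(xs[i] @ p[f"We{i}"] + p[f"be{i}"]) for i in range(K)]
        concat = np.concatenate(a1, axis=1)
        a2 = sigmoid(concat @ p["Wj"] + p["bj"])
        mask = None
        if dropout and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (self._train_rng.random(a2.shape) < keep) / keep
            a2 = a2 * mask
        z = sigmoid(a2 @ p["Wz"] + p["bz"])
        d2 = sigmoid(z @ p["Wd1"] + p["bd1"])
        d1 = sigmoid(d2 @ p["Wd2"] + p["bd2"])
        chunks = [d1[:, i * h1:(i + 1) * h1] for i in range(K)]
        recon = [sigmoid(chunks[i] @ p[f"Wo{i}"] + p[f"bo{i}"]) for i in range(K)]
        cache = (xs, a1, concat, a2, mask, z, d2, d1, chunks, recon)
        return recon, z, cache

    # -- backward ----------------------------------------------------------

    def _backward(self, cache) -> dict[str, np.ndarray]:
        """Gradients of summed per-network mean-BCE w.r.t. all parameters."""
        p = self.params
        K, h1 = self.n_networks, self.cfg.per_network_hidden
        xs, a1, concat, a2, mask, z, d2, d1, chunks, recon = cache
        B = xs[0].shape[0]
        g: dict[str, np.ndarray] = {}
        # d(meanBCE)/d(logits) = (pred - target) / n_entries, per network
        d_chunks = []
        for i in range(K):
            delta = (recon[i] - xs[i]) / (B * self.n_drugs)
            g[f"Wo{i}"] = chunks[i].T @ delta
            g[f"bo{i}"] = delta.sum(axis=0)
            d_chunks.append((delta @ p[f"Wo{i}"].T) * dsigmoid(chunks[i]))
        d_d1 = np.concatenate(d_chunks, axis=1)
        g["Wd2"] = d2.T @ d_d1
        g["bd2"] = d_d1.sum(axis=0)
        d_d2 = (d_d1 @ p["Wd2"].T) * dsigmoid(d2)
        g["Wd1"] = z.T @ d_d2
        g["bd1"] = d_d2.sum(axis=0)
        d_z = (d_d2 @ p["Wd1"].T) * dsigmoid(z)
        g["Wz"] = a2.T @ d_z
        g["bz"] = d_z.sum(axis=0)
        d_a2 = d_z @ p["Wz"].T
        if mask is not None:
            d_a2 = d_a2 * mask
        # a2 pre-dropout sigmoid derivative: recover pre-mask activation
        a2_pre = a2 if mask is None else np.where(mask > 0, a2 / np.maximum(mask, 1e-12), 0.0)
        d_a2 = d_a2 * dsigmoid(a2_pre)
        g["Wj"] = concat.T @ d_a2
        g["bj"] = d_a2.sum(axis=0)
        d_concat = d_a2 @ p["Wj"].T
        for i in range(K):
            d_a1 = d_concat[:, i * h1:(i + 1) * h1] * dsigmoid(a1[i])
            g[f"We{i}"] = xs[i].T @ d_a1
            g[f"be{i}"] = d_a1.sum(axis=0)
        return g

    def loss(self, xs: list[np.ndarray]) -> tuple[float, list[float]]:
        recon, _, _ = self.forward(xs, dropout=False)
        per_net = [bce(xs[i], recon[i]) for i in range(self.n_networks)]
        return float(np.sum(per_net)), per_net

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def build_mae(cfg: MAEConfig, n_networks: int, n_drugs: int) -> MultimodalAutoencoder:
    """Construct a seeded, untrained fusion autoencoder."""
    return MultimodalAutoencoder(cfg, n_networks, n_drugs)


def train_mae(model: MultimodalAutoencoder, scaled: list[np.ndarray],
              cfg: MAEConfig | None = None) -> TrainingHistory:
    """Train by minibatch Adam on summed per-network BCE; returns history.

    ``cfg`` defaults to the model's own configuration. Zero epochs return
    the model unchanged with an empty history.
    """
    cfg = cfg or model.cfg
    n = scaled[0].shape[0]
    if any(m.shape[0] != n for m in scaled):
        raise ValueError("all scaled matrices must have n_drugs rows")
    if len(scaled) != model.n_networks:
        raise ValueError("number of matrices does not match the model")
    opt = Adam(model.params, lr=cfg.learning_rate)
    history = TrainingHistory()
    rng = np.random.default_rng(cfg.seed + 1)
    batch = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xs = [m[idx] for m in scaled]
            _, _, cache = model.forward(xs, dropout=True)
            opt.step(model._backward(cache))
        total, per_net = model.loss(scaled)
        if not np.isfinite(total):
            raise FloatingPointError("fusion autoencoder loss became non-finite")
        history.total.append(total)
        history.per_network.append(per_net)
    return history


def extract_features(model: MultimodalAutoencoder, scaled: list[np.ndarray],
                     vocabulary: DrugVocabulary) -> FusedFeatures:
    """Deterministic bottleneck activations (dropout off) as drug features."""
    _, z, _ = model.forward(scaled, dropout=False)
    return FusedFeatures(z, vocabulary)


def save_mae(model: MultimodalAutoencoder, directory,
             scaling_params=None) -> None:
    """Checkpoint the model into one directory: weights + JSON manifest.

    The manifest records the full configuration (including the seed) and
    the per-network min-max scaling parameters so that feature extraction
    is reproducible from the checkpoint alone.
    """
    import dataclasses
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "weights.npz", **model.params)
    manifest = {
        "kind": "fusion_autoencoder",
        "config": dataclasses.asdict(model.cfg),
        "n_networks": model.n_networks,
        "n_drugs": model.n_drugs,
        "scaling": [list(p) for p in scaling_params] if scaling_params else None,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_mae(directory) -> tuple[MultimodalAutoencoder, list | None]:
    """Restore a checkpointed model; returns (model, scaling_params)."""
    import json
    from pathlib import Path

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("kind") != "fusion_autoencoder":
        raise ValueError(f"{d} is not a fusion-autoencoder checkpoint")
    cfg = MAEConfig(**manifest["config"])
    model = MultimodalAutoencoder(cfg, manifest["n_networks"], manifest["n_drugs"])
    with np.load(d / "weights.npz") as data:
        for k in model.params:
            model.params[k] = data[k]
    scaling = manifest["scaling"]
    return model, [tuple(p) for p in scaling] if scaling else None
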