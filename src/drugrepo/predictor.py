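"""Wasserstein variational autoencoder scoring disease-drug associations.

The model consumes one disease at a time as a row vector x over the drug
vocabulary (1 = known association). The encoder maps x through two paths —
a feature pooling x @ F against the fused drug features F, and a learned
dense layer — whose concatenation feeds a hidden layer (dropout) producing
a Gaussian posterior (mu, sigma). The decoder maps the latent sample to a
feature-space vector h and scores every drug as sigmoid(h @ F^T + bias),
so the fused drug features condition both encoding and decoding.

Training minimises, per disease row,

    total = wasserstein + alpha * KL(q(z|x) || N(0, I)) + 0.1 * BCE(x, xhat)

where the Wasserstein term treats x and xhat as distributions over drugs
and measures entropic optimal-transport cost under a ground metric given
by squared Euclidean distances between fused feature rows ("sinkhorn"
mode). The alternative "diagonal" mode fixes the coupling to the identity,
which collapses the term to the mean squared per-drug difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, glorot, sigmoid
from .containers import AssociationMatrix, DrugVocabulary, FusedFeatures
from .ot import SinkhornKernel, sinkhorn_plan

__all__ = [
    "LatentGaussian",
    "LossWeights",
    "WVAEConfig",
    "PredictionTable",
    "mse_loss",
    "feature_cost",
    "wasserstein_loss",
    "kl_regularization",
    "auxiliary_loss",
    "total_loss",
    "WassersteinVAE",
    "build_wvae",
    "train_wvae",
    "save_wvae",
    "load_wvae",
    "predict",
]


@dataclass(frozen=True)
class LatentGaussian:
    """Diagonal Gaussian posterior parameters (per latent dimension)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, float)
        sigma = np.asarray(self.sigma, float)
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have the same shape")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
            raise ValueError("latent parameters must be finite")
        if np.min(sigma) <= 0:
            raise ValueError("sigma must be strictly positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite loss and optimal-transport settings.

    ``alpha`` scales the KL regulariser, ``aux_weight`` the binary
    cross-entropy auxiliary term (0.1 by default). ``ot_mode`` selects
    between the entropic-transport Wasserstein term ("sinkhorn") and the
    identity-coupling reading ("diagonal").
    """

    alpha: float = 0.1
    aux_weight: float = 0.1
    sinkhorn_epsilon: float = 0.1
    ot_mode: str = "sinkhorn"
    sinkhorn_max_iter: int = 200
    sinkhorn_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.aux_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.ot_mode not in ("sinkhorn", "diagonal"):
            raise ValueError(f"unknown ot_mode: {self.ot_mode!r}")
        if self.ot_mode == "sinkhorn" and self.sinkhorn_epsilon <= 0:
            raise ValueError("sinkhorn_epsilon must be positive")


@dataclass(frozen=True)
class WVAEConfig:
    latent_dim: int = 32
    hidden_dim: int = 256
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 300
    pretrain_epochs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.hidden_dim < 1:
            raise ValueError("layer widths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class PredictionTable:
    """Ranked per-disease drug scores; ranks are 1-based within a disease."""

    rows: list[tuple]  # (disease_id, drug_id, score, rank, known)

    def top(self, k: int, novel_only: bool = False) -> "PredictionTable":
        rows = [r for r in self.rows if not (novel_only and r[4])]
        return PredictionTable(rows[:k])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["disease_id", "drug_id", "score", "rank", "known"])


# ---------------------------------------------------------------------------
# loss components


def mse_loss(D: np.ndarray, D_hat: np.ndarray) -> float:
    """Halved mean squared reconstruction error."""
    d = np.asarray(D, float)
    dh = np.asarray(D_hat, float)
    if d.shape != dh.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {dh.shape}")
    return float(np.mean((d - dh) ** 2) / 2.0)


def feature_cost(F) -> np.ndarray:
    """Squared Euclidean distances between fused feature rows (ground metric)."""
    m = F.matrix if isinstance(F, FusedFeatures) else np.asarray(F, float)
    sq = np.sum(m * m, axis=1)
    c = sq[:, None] + sq[None, :] - 2.0 * (m @ m.T)
    np.maximum(c, 0.0, out=c)
    np.fill_diagonal(c, 0.0)
    return c


def _as_distribution(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, float)
    if np.min(x) < 0:
        raise ValueError(f"{what} must be non-negative")
    s = x.sum()
    if s <= 0:
        warnings.warn(f"all-zero {what}; falling back to uniform", RuntimeWarning)
        return np.full(x.size, 1.0 / x.size)
    return x / s


def wasserstein_loss(x: np.ndarray, x_hat: np.ndarray, F,
                     weights: LossWeights | None = None) -> float:
    """Transport-based discrepancy between a disease row and its reconstruction."""
    weights = weights or LossWeights()
    x = np.asarray(x, float)
    x_hat = np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have the same length")
    if weights.ot_mode == "diagonal":
        return float(np.mean((x - x_hat) ** 2))
    a = _as_distribution(x, "source row")
    b = _as_distribution(x_hat, "reconstructed row")
    plan = sinkhorn_plan(a, b, feature_cost(F), epsilon=weights.sinkhorn_epsilon,
                         max_iter=weights.sinkhorn_max_iter, tol=weights.sinkhorn_tol)
    return plan.cost


def kl_regularization(z: LatentGaussian) -> float:
    """KL divergence of the posterior from the standard normal (>= 0)."""
    mu, sigma = z.mu, z.sigma
    return float(np.sum(-0.5 * (1.0 + 2.0 * np.log(sigma) - mu ** 2 - sigma ** 2)))


def auxiliary_loss(x: np.ndarray, x_hat: np.ndarray, eps: float = 1e-7) -> float:
    """Summed binary cross-entropy between known labels and scores."""
    x = np.asarray(x, float)
    p = np.clip(np.asarray(x_hat, float), eps, 1.0 - eps)
    return float(-np.sum(x * np.log(p) + (1.0 - x) * np.log(1.0 - p)))


def total_loss(x: np.ndarray, x_hat: np.ndarray, z: LatentGaussian, F,
               weights: LossWeights | None = None) -> float:
    """Composite loss: wasserstein + alpha * KL + aux_weight * BCE."""
    weights = weights or LossWeights()
    return (wasserstein_loss(x, x_hat, F, weights)
            + weights.alpha * kl_regularization(z)
            + weights.aux_weight * auxiliary_loss(x, x_hat))


# ---------------------------------------------------------------------------
# model


@dataclass
class WVAEHistory:
    total: list[float] = field(default_factory=list)
    wasserstein: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    auxiliary: list[float] = field(default_factory=list)


class WassersteinVAE:
    """NumPy implementation of the disease-row variational autoencoder."""

    def __init__(self, n_drugs: int, F: FusedFeatures, cfg: WVAEConfig | None = None,
                 standardize_features: bool = True):
        if F.matrix.shape[0] != n_drugs:
            raise ValueError("feature rows must align with the drug vocabulary")
        self.cfg = cfg or WVAEConfig()
        self.n_drugs = n_drugs
        if standardize_features:
            # z-score each feature dimension: the fusion bottleneck uses
            # sigmoid units whose informative variation can sit on a large
            # per-dimension offset; standardising restores discriminative
            # geometry for both the decoder and the transport ground cost
            mu = F.matrix.mean(axis=0)
            sd = F.matrix.std(axis=0)
            self.F = (F.matrix - mu) / np.maximum(sd, 1e-8)
        else:
            self.F = F.matrix
        self.d = F.dim
        L, H = self.cfg.latent_dim, self.cfg.hidden_dim
        rng = np.random.default_rng(self.cfg.seed)
        d = self.d
        self.params = {
            "Wx": glorot(rng, n_drugs, d),
            "bx": np.zeros(d),
            "Wh": glorot(rng, 2 * d, H),
            "bh": np.zeros(H),
            "Wmu": glorot(rng, H, L),
            "bmu": np.zeros(L),
            "Wls": glorot(rng, H, L),
            "bls": np.zeros(L),
            "Wd": glorot(rng, L, d),
            "bd": np.zeros(d),
            "bout": np.zeros(n_drugs),
        }
        self._train_rng = np.random.default_rng(rng.integers(2**31))
        self._cost = None  # feature ground-cost cache
        self._kernel: SinkhornKernel | None = None

    def cost_matrix(self) -> np.ndarray:
        if self._cost is None:
            self._cost = feature_cost(self.F)
        return self._cost

    def _sinkhorn_kernel(self, epsilon: float) -> SinkhornKernel:
        """Gibbs kernel on the mean-normalised ground cost (cached).

        The raw squared-distance scale grows with the feature dimension;
        normalising by the mean cost makes ``epsilon`` a dimensionless
        regularisation strength and keeps the kernel well conditioned.
        """
        if self._kernel is None or self._kernel.epsilon != epsilon:
            c = self.cost_matrix()
            scale = c.mean()
            self._kernel = SinkhornKernel(c / scale if scale > 0 else c, epsilon)
        return self._kernel

    def encode(self, X: np.ndarray, dropout: bool = False):
        p = self.params
        pooled = X @ self.F
        learned = X @ p["Wx"] + p["bx"]
        c = np.concatenate([pooled, learned], axis=1)
        h_pre = np.tanh(c @ p["Wh"] + p["bh"])
        mask = None
        h = h_pre
        if dropout and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (self._train_rng.random(h.shape) < keep) / keep
            h = h_pre * mask
        mu = h @ p["Wmu"] + p["bmu"]
        ls = np.clip(h @ p["Wls"] + p["bls"], -8.0, 8.0)
        return c, h_pre, mask, h, mu, ls

    def decode(self, z: np.ndarray):
        p = self.params
        hd = np.tanh(z @ p["Wd"] + p["bd"])
        logits = hd @ self.F.T + p["bout"]
        return hd, logits, sigmoid(logits)

    def posterior(self, x: np.ndarray) -> LatentGaussian:
        _, _, _, _, mu, ls = self.encode(np.atleast_2d(x), dropout=False)
        return LatentGaussian(mu[0], np.exp(ls[0]))

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic scores (dropout off, z = posterior mean)."""
        X = np.atleast_2d(np.asarray(X, float))
        _, _, _, _, mu, _ = self.encode(X, dropout=False)
        _, _, xhat = self.decode(mu)
        return xhat

    # -- training ----------------------------------------------------------

    def _epoch(self, X: np.ndarray, weights: LossWeights, opt: Adam,
               diagonal_only: bool) -> tuple[float, float, float, float]:
        """One full-batch gradient step; returns loss components (means/row)."""
        p = self.params
        B, n = X.shape
        c, h_pre, mask, h, mu, ls = self.encode(X, dropout=True)
        sigma = np.exp(ls)
        noise = self._train_rng.standard_normal(mu.shape)
        z = mu + sigma * noise
        hd, logits, xhat = self.decode(z)

        use_sinkhorn = weights.ot_mode == "sinkhorn" and not diagonal_only
        if use_sinkhorn:
            s_a = X.sum(axis=1, keepdims=True)
            if np.any(s_a <= 0):
                warnings.warn("all-zero disease rows; using uniform source marginals",
                              RuntimeWarning)
            A = np.where(s_a > 0, X / np.maximum(s_a, 1e-300), 1.0 / n)
            s_b = xhat.sum(axis=1, keepdims=True)
            Bdist = xhat / s_b
            kernel = self._sinkhorn_kernel(weights.sinkhorn_epsilon)
            costs, grad_b = kernel.solve(A, Bdist, max_iter=weights.sinkhorn_max_iter,
                                         tol=1e-6)
            wass = float(np.mean(costs))
            # chain rule through the normalisation b = xhat / s (grad_b is
            # already centred, so the Jacobian reduces to division by s)
            d_xhat_w = grad_b / s_b
        else:
            wass = float(np.mean((X - xhat) ** 2))
            d_xhat_w = 2.0 * (xhat - X) / n

        kl_rows = np.sum(-0.5 * (1.0 + 2.0 * ls - mu ** 2 - sigma ** 2), axis=1)
        kl = float(np.mean(kl_rows))
        xclip = np.clip(xhat, 1e-7, 1.0 - 1e-7)
        aux_rows = -np.sum(X * np.log(xclip) + (1 - X) * np.log(1 - xclip), axis=1)
        aux = float(np.mean(aux_rows))
        total = wass + weights.alpha * kl + weights.aux_weight * aux

        # backward (objective = mean over rows)
        d_logits = (d_xhat_w * xhat * (1 - xhat) + weights.aux_weight * (xhat - X)) / B
        g = {}
        g["bout"] = d_logits.sum(axis=0)
        d_hd = (d_logits @ self.F) * (1.0 - hd ** 2)
        g["Wd"] = z.T @ d_hd
        g["bd"] = d_hd.sum(axis=0)
        d_z = d_hd @ p["Wd"].T
        d_mu = d_z + weights.alpha * mu / B
        d_ls = d_z * noise * sigma + weights.alpha * (sigma ** 2 - 1.0) / B
        d_h = d_mu @ p["Wmu"].T + d_ls @ p["Wls"].T
        g["Wmu"] = h.T @ d_mu
        g["bmu"] = d_mu.sum(axis=0)
        g["Wls"] = h.T @ d_ls
        g["bls"] = d_ls.sum(axis=0)
        if mask is not None:
            d_h = d_h * mask
        d_c_pre = d_h * (1.0 - h_pre ** 2)
        g["Wh"] = c.T @ d_c_pre
        g["bh"] = d_c_pre.sum(axis=0)
        d_c = d_c_pre @ p["Wh"].T
        d_learned = d_c[:, self.d:]
        g["Wx"] = X.T @ d_learned
        g["bx"] = d_learned.sum(axis=0)
        opt.step(g)
        return total, wass, kl, aux


def build_wvae(n_drugs: int, F: FusedFeatures, cfg: WVAEConfig | None = None) -> WassersteinVAE:
    return WassersteinVAE(n_drugs, F, cfg)


def train_wvae(model: WassersteinVAE, X: AssociationMatrix | np.ndarray,
               weights: LossWeights | None = None,
               epochs: int | None = None) -> WVAEHistory:
    """Full-batch Adam training on mean per-row composite loss.

    An optional warm-up (``cfg.pretrain_epochs``) first fits the plain
    mean-squared reconstruction (identity coupling) before switching on the
    transport term, mirroring a feature-reconstruction pretraining pass.
    """
    weights = weights or LossWeights()
    Xm = X.matrix if isinstance(X, AssociationMatrix) else np.asarray(X, float)
    epochs = model.cfg.epochs if epochs is None else epochs
    opt = Adam(model.params, lr=model.cfg.learning_rate)
    history = WVAEHistory()
    for _ in range(model.cfg.pretrain_epochs):
        model._epoch(Xm, weights, opt, diagonal_only=True)
    for _ in range(epochs):
        total, wass, kl, aux = model._epoch(Xm, weights, opt, diagonal_only=False)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"training loss became non-finite (wass={wass}, kl={kl}, aux={aux})")
        history.total.append(total)
        history.wasserstein.append(wass)
        history.kl.append(kl)
        history.auxiliary.append(aux)
    return history


def save_wvae(model: WassersteinVAE, directory,
              weights: LossWeights | None = None) -> None:
    """Checkpoint the predictor: parameters, features and a JSON manifest.

    The manifest stores the model configuration, the loss weights used in
    training (if given) and a hash of the feature matrix so a checkpoint
    can be matched to the fusion output it was trained against.
    """
    import dataclasses
    import hashlib
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "weights.npz", F=model.F, **model.params)
    manifest = {
        "kind": "association_wvae",
        "config": dataclasses.asdict(model.cfg),
        "loss_weights": dataclasses.asdict(weights) if weights else None,
        "n_drugs": model.n_drugs,
        "feature_sha256": hashlib.sha256(
            np.ascontiguousarray(model.F).tobytes()).hexdigest(),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_wvae(directory, vocabulary: DrugVocabulary) -> WassersteinVAE:
    """Restore a checkpointed predictor (features come from the checkpoint)."""
    import json
    from pathlib import Path

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("kind") != "association_wvae":
        raise ValueError(f"{d} is not a predictor checkpoint")
    cfg = WVAEConfig(**manifest["config"])
    with np.load(d / "weights.npz") as data:
        F = FusedFeatures(data["F"], vocabulary)
        # features were standardised before saving; do not standardise twice
        model = WassersteinVAE(manifest["n_drugs"], F, cfg,
                               standardize_features=False)
        for k in model.params:
            model.params[k] = data[k]
    return model


def predict(model: WassersteinVAE, x_query: np.ndarray,
            vocabulary: DrugVocabulary, disease_id: str = "query",
            mask_known: bool = True) -> PredictionTable:
    """Deterministic scores for one disease row, ranked descending.

    With ``mask_known`` the drugs already positive in the query are flagged
    so novel candidates can be listed first; ties break by vocabulary order.
    """
    x = np.asarray(x_query, float)
    scores = model.reconstruct(x)[0]
    order = np.lexsort((np.arange(len(scores)), -scores))
    rows = []
    for rank, j in enumerate(order, start=1):
        known = bool(x[j] > 0) if mask_known else False
        rows.append((disease_id, vocabulary.ids[j], float(scores[j]), rank, known))
    return PredictionTable(rows)
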