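"""Latent variable model: autoencoder over one-hot 50-mers + HLB regressor.

The model embeds each one-hot encoded pseudo-residue window into a
16-dimensional latent vector z through a fully connected encoder
(256/128/64 hidden units, ReLU).  Two parallel branches read z: a decoder
(64/128/256, ReLU, sigmoid output) reconstructing the window, and a small
regressor (two 16-unit layers) predicting the window's mean HLB.  The
training loss is a weighted sum

    L = BCE(window, reconstruction) + lambda * (hlb_pred - hlb_true)^2

where BCE is element-wise binary cross-entropy summed over the width x 4
independent sigmoid outputs and averaged over the batch.  Jointly
optimizing reconstruction and regression forces the latent space to carry
both the sequential arrangement of blocks and the segmental
hydrophobicity of a window.  Optimization uses Adam (lr 0.001) with a
plateau scheduler that halves the learning rate when the validation loss
stops improving.

The network is small enough that a self-contained numpy implementation
(explicit backprop, seeded initialization) keeps training bit-reproducible
across runs on a single CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import WindowSet, encode_windows

__all__ = [
    "ModelConfig",
    "LatentEmbedding",
    "TrainingHistory",
    "LatentModel",
    "reconstruction_loss",
    "combined_loss",
    "train",
    "save_model",
    "load_model",
    "write_embeddings_tsv",
]

logger = logging.getLogger(__name__)

_EPS = 1e-7  # sigmoid clipping floor inside the cross-entropy


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the latent model.

    Defaults follow the reference architecture: encoder/decoder hidden
    widths 256/128/64, 16-d latent, 16/16 regressor, Adam at 1e-3 with a
    halve-on-plateau schedule (factor 0.5, patience 5 epochs on the
    validation total loss).
    """

    window_width: int = 50
    n_classes: int = 4
    encoder_widths: tuple[int, ...] = (256, 128, 64)
    latent_dim: int = 16
    regressor_hidden: tuple[int, ...] = (16, 16)
    learning_rate: float = 1e-3
    loss_weight: float = 1.0          # lambda on the HLB term
    max_epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    validation_fraction: float = 0.1
    lr_factor: float = 0.5
    lr_patience: int = 5

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.loss_weight < 0:
            raise ValueError("loss_weight must be >= 0")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")

    @property
    def input_dim(self) -> int:
        return self.window_width * self.n_classes


@dataclass
class LatentEmbedding:
    """Latent vectors and predicted HLB for a window set."""

    z: np.ndarray               # (n, latent_dim)
    predicted_hlb: np.ndarray   # (n,)
    windows: WindowSet | None = None

    def __len__(self) -> int:
        return self.z.shape[0]


@dataclass
class TrainingHistory:
    """Per-epoch loss traces (total = reconstruction + lambda * regression)."""

    train_total: list[float] = field(default_factory=list)
    train_recon: list[float] = field(default_factory=list)
    train_reg: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    val_recon: list[float] = field(default_factory=list)
    val_reg: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Loss functions (also exposed standalone for testing / inspection)

def reconstruction_loss(target: np.ndarray, probs: np.ndarray) -> float:
    """Element-wise binary cross-entropy summed over a window's outputs.

    ``target`` is the 0/1 indicator matrix, ``probs`` the sigmoid outputs;
    both may be flat (width*4,) or (width, 4).  Probabilities are clipped
    at 1e-7 so a perfect reconstruction gives a loss at the clipping floor.
    """
    t = np.asarray(target, dtype=float).ravel()
    p = np.clip(np.asarray(probs, dtype=float).ravel(), _EPS, 1.0 - _EPS)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).sum())


def combined_loss(
    probs: np.ndarray,
    target: np.ndarray,
    hlb_pred: float,
    hlb_true: float,
    loss_weight: float = 1.0,
) -> float:
    """Total single-window loss: cross-entropy + lambda * squared HLB error."""
    return reconstruction_loss(target, probs) + loss_weight * (hlb_pred - hlb_true) ** 2


# ---------------------------------------------------------------------------
# Network internals

def _init_mlp(widths: Sequence[int], rng: np.random.Generator) -> list[dict]:
    """He-initialized dense layers for the given width chain."""
    layers = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        layers.append({
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        })
    return layers


def _forward_mlp(layers: list[dict], x: np.ndarray, final_activation: str):
    """Forward pass; returns output and the per-layer cache for backprop.

    Hidden layers use ReLU; the final layer uses ``final_activation`` in
    {'linear', 'sigmoid'}.
    """
    cache = []
    h = x
    for li, layer in enumerate(layers):
        a = h @ layer["W"] + layer["b"]
        last = li == len(layers) - 1
        if not last:
            out = np.maximum(a, 0.0)
        elif final_activation == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-a))
        else:
            out = a
        cache.append((h, a, out))
        h = out
    return h, cache


def _backward_mlp(layers, cache, grad_out, final_activation: str, grads: list[dict]):
    """Backprop through an MLP; grad_out is dL/d(output).

    For the sigmoid final layer the caller passes dL/d(pre-activation)
    directly (BCE + sigmoid collapse), flagged by final_activation='logit'.
    """
    g = grad_out
    for li in range(len(layers) - 1, -1, -1):
        h, a, out = cache[li]
        last = li == len(layers) - 1
        if last and final_activation == "logit":
            ga = g
        elif last and final_activation == "linear":
            ga = g
        else:
            ga = g * (a > 0.0)
        grads[li]["W"] += h.T @ ga
        grads[li]["b"] += ga.sum(axis=0)
        g = ga @ layers[li]["W"].T
    return g


class _Adam:
    """Adam optimizer over a flat list of parameter dicts."""

    def __init__(self, param_layers: list[dict], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = param_layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.items()} for l in param_layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.items()} for l in param_layers]

    def step(self, grads: list[dict]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, g, m, v in zip(self.layers, grads, self.m, self.v):
            for k in layer:
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g[k]
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g[k] ** 2
                layer[k] -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


class LatentModel:
    """Encoder + decoder + HLB regressor over one-hot windows."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.input_dim
        enc = [d, *config.encoder_widths, config.latent_dim]
        dec = [config.latent_dim, *reversed(config.encoder_widths), d]
        reg = [config.latent_dim, *config.regressor_hidden, 1]
        self.encoder = _init_mlp(enc, rng)
        self.decoder = _init_mlp(dec, rng)
        self.regressor = _init_mlp(reg, rng)
        self.history: TrainingHistory | None = None

    # -- inference ---------------------------------------------------------

    def _as_matrix(self, windows) -> np.ndarray:
        if isinstance(windows, np.ndarray):
            x = windows
        else:
            x = encode_windows(windows)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"window width mismatch: got {x.shape[1] if x.ndim == 2 else '?'} "
                f"features, model expects {self.config.input_dim}"
            )
        return x

    def encode(self, windows) -> LatentEmbedding:
        """Embed windows; deterministic (inference has no stochastic parts)."""
        x = self._as_matrix(windows)
        z, _ = _forward_mlp(self.encoder, x, "linear")
        hlb, _ = _forward_mlp(self.regressor, z, "linear")
        ws = windows if isinstance(windows, WindowSet) else None
        return LatentEmbedding(z=z, predicted_hlb=hlb.ravel(), windows=ws)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Per-position class probability matrices, shape (n, width, 4).

        Outputs are independent sigmoids, so rows are not normalized; the
        reconstructed sequence reads out by per-position argmax.
        """
        z = np.atleast_2d(z)
        p, _ = _forward_mlp(self.decoder, z, "sigmoid")
        return p.reshape(len(z), self.config.window_width, self.config.n_classes)

    def predict_hlb(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        out, _ = _forward_mlp(self.regressor, z, "linear")
        return out.ravel()

    # -- training ----------------------------------------------------------

    def _batch_losses(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        z, _ = _forward_mlp(self.encoder, x, "linear")
        p, _ = _forward_mlp(self.decoder, z, "sigmoid")
        h, _ = _forward_mlp(self.regressor, z, "linear")
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        recon = float(-(x * np.log(pc) + (1 - x) * np.log(1 - pc)).sum(axis=1).mean())
        reg = float(((h.ravel() - y) ** 2).mean())
        return recon, reg

    def _train_step(self, x: np.ndarray, y: np.ndarray, opt: _Adam, lam: float):
        B = len(x)
        z, enc_cache = _forward_mlp(self.encoder, x, "linear")
        p, dec_cache = _forward_mlp(self.decoder, z, "sigmoid")
        h, reg_cache = _forward_mlp(self.regressor, z, "linear")

        zero = lambda layers: [{k: np.zeros_like(v) for k, v in l.items()} for l in layers]
        g_enc, g_dec, g_reg = zero(self.encoder), zero(self.decoder), zero(self.regressor)

        # BCE + sigmoid: dL/d(logit) = (p - t) / B
        gz_dec = _backward_mlp(self.decoder, dec_cache, (p - x) / B, "logit", g_dec)
        gz_reg = _backward_mlp(
            self.regressor, reg_cache,
            lam * 2.0 * (h - y[:, None]) / B, "linear", g_reg,
        )
        _backward_mlp(self.encoder, enc_cache, gz_dec + gz_reg, "linear", g_enc)
        opt.step(g_enc + g_dec + g_reg)


def train(
    windows,
    labels: Sequence[float],
    cfg: ModelConfig | None = None,
    groups: Sequence[str] | None = None,
) -> tuple[LatentModel, TrainingHistory]:
    """Train a latent model on windows and their mean-HLB labels.

    The train/validation split (default 90/10) is seeded and, when
    ``groups`` (e.g. source family per window) is given, stratified by
    group so every family appears in both partitions.
    """
    cfg = cfg or ModelConfig()
    model = LatentModel(cfg)
    x = model._as_matrix(windows)
    y = np.asarray(labels, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 windows to train")
    if len(x) != len(y):
        raise ValueError("labels must match windows")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite HLB labels")

    rng = np.random.default_rng(cfg.seed)
    n = len(x)
    if groups is not None:
        groups = np.asarray(groups)
        val_idx: list[int] = []
        for g in np.unique(groups):
            gi = np.flatnonzero(groups == g)
            gi = gi[rng.permutation(len(gi))]
            k = max(1, int(round(cfg.validation_fraction * len(gi))))
            val_idx.extend(gi[:k])
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
    else:
        perm = rng.permutation(n)
        k = max(1, int(round(cfg.validation_fraction * n)))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[perm[:k]] = True
    x_tr, y_tr = x[~val_mask], y[~val_mask]
    x_va, y_va = x[val_mask], y[val_mask]
    if len(x_tr) == 0:
        raise ValueError("empty training split")

    opt = _Adam(model.encoder + model.decoder + model.regressor, cfg.learning_rate)
    hist = TrainingHistory()
    lam = cfg.loss_weight
    best_val = np.inf
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(x_tr), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model._train_step(x_tr[idx], y_tr[idx], opt, lam)

        tr_recon, tr_reg = model._batch_losses(x_tr, y_tr)
        va_recon, va_reg = model._batch_losses(x_va, y_va)
        hist.train_recon.append(tr_recon)
        hist.train_reg.append(tr_reg)
        hist.train_total.append(tr_recon + lam * tr_reg)
        hist.val_recon.append(va_recon)
        hist.val_reg.append(va_reg)
        val_total = va_recon + lam * va_reg
        hist.val_total.append(val_total)
        hist.learning_rate.append(opt.lr)

        # halve the learning rate when validation loss plateaus
        if val_total < best_val - 1e-6:
            best_val = val_total
            stale = 0
        else:
            stale += 1
            if stale > cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                stale = 0
                logger.info("epoch %d: lr reduced to %g", epoch, opt.lr)

    model.history = hist
    return model, hist


# ---------------------------------------------------------------------------
# Checkpointing: one .npz archive holding config (JSON), weights, history.

def save_model(path: str | Path, model: LatentModel) -> None:
    arrays: dict[str, np.ndarray] = {}
    for name, layers in (
        ("enc", model.encoder), ("dec", model.decoder), ("reg", model.regressor)
    ):
        for i, layer in enumerate(layers):
            arrays[f"{name}_{i}_W"] = layer["W"]
            arrays[f"{name}_{i}_b"] = layer["b"]
    cfg = asdict(model.config)
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8
    )
    if model.history is not None:
        arrays["history_json"] = np.frombuffer(
            json.dumps(asdict(model.history)).encode(), dtype=np.uint8
        )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> LatentModel:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    for key in ("encoder_widths", "regressor_hidden"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = LatentModel(ModelConfig(**cfg_dict))
    for name, layers in (
        ("enc", model.encoder), ("dec", model.decoder), ("reg", model.regressor)
    ):
        for i, layer in enumerate(layers):
            layer["W"] = data[f"{name}_{i}_W"]
            layer["b"] = data[f"{name}_{i}_b"]
    if "history_json" in data:
        model.history = TrainingHistory(
            **json.loads(bytes(data["history_json"]).decode())
        )
    return model


def write_embeddings_tsv(path: str | Path, emb: LatentEmbedding) -> None:
    """Export embeddings as TSV: parent_id, start, z1..zK, predicted_hlb."""
    k = emb.z.shape[1]
    with open(path, "w") as fh:
        cols = ["parent_id", "start"] + [f"z{i+1}" for i in range(k)] + ["predicted_hlb"]
        fh.write("\t".join(cols) + "\n")
        for i in range(len(emb)):
            if emb.windows is not None:
                w = emb.windows.windows[i]
                pid, start = w.parent_id, w.start
            else:
                pid, start = str(i), 0
            zvals = "\t".join(f"{v:.6g}" for v in emb.z[i])
            fh.write(f"{pid}\t{start}\t{zvals}\t{emb.predicted_hlb[i]:.6g}\n")
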