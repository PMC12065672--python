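"""Per-participant 1D convolutional classifiers for hourly biosignal windows.

The classifier consumes a 12-step window of selected hourly features and emits
the probability of substance use in the window's final hour. Its backbone is a
single 1D convolution (32 filters of size 3, ReLU) followed by max pooling
(size 2) and flattening — for 12-step inputs the per-channel feature map
shrinks from 10 to 5 and flattens to a 160-unit vector. The supervised head is
dropout (50%) plus a sigmoid unit; training minimizes the Brier score (mean
squared error between predicted probability and the binary label) with Adam,
a reduce-on-plateau learning-rate schedule, and early stopping on a
chronological 20% validation split.

The self-supervised variant first pretrains the backbone on a label-free
pretext task — multi-output regression of biometric features (by default,
forecasting the next hour's feature vector from the current window) under MSE
— then transfers the convolutional weights, attaches a dense(32, ReLU) →
dropout(50%) → sigmoid head, and fine-tunes: 100 epochs with the backbone
frozen, then 100 epochs unfrozen.

The network, backpropagation and Adam optimizer are implemented directly in
NumPy and verified against finite-difference gradients in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CnnSpec",
    "TrainConfig",
    "SslConfig",
    "Cnn1D",
    "TrainedClassifier",
    "build_classifier",
    "train_supervised",
    "pretrain_ssl",
    "finetune_transferred",
    "predict_probabilities",
    "brier_score",
]


class ModelError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CnnSpec:
    input_steps: int = 12
    conv_filters: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.5
    head_hidden_units: int = 32  # used by the SSL fine-tuning head only

    def __post_init__(self):
        if self.input_steps < self.kernel_size:
            raise ModelError("input_steps must be >= kernel_size")

    @property
    def conv_length(self) -> int:
        return self.input_steps - self.kernel_size + 1

    @property
    def pooled_length(self) -> int:
        return self.conv_length // self.pool_size

    @property
    def flatten_width(self) -> int:
        return self.pooled_length * self.conv_filters


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 32
    validation_fraction: float = 0.2
    early_stop_patience: int = 10
    lr_factor: float = 0.5
    lr_patience: int = 5
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.validation_fraction < 1.0):
            raise ModelError("validation_fraction must be in (0, 1)")
        if self.early_stop_patience < 1:
            raise ModelError("early_stop_patience must be >= 1")


@dataclass(frozen=True)
class SslConfig:
    pretrain_epochs: int = 100
    frozen_epochs: int = 100
    unfrozen_epochs: int = 100
    #: "forecast": regress the next hour's feature vector from each window;
    #: "reconstruct": regress the window's own per-feature means.
    pretext: str = "forecast"

    def __post_init__(self):
        if min(self.pretrain_epochs, self.frozen_epochs, self.unfrozen_epochs) < 1:
            raise ModelError("all SSL epoch counts must be >= 1")
        if self.pretext not in ("forecast", "reconstruct"):
            raise ModelError("pretext must be 'forecast' or 'reconstruct'")


def brier_score(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared error between predicted probability and binary outcome."""
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    return float(np.mean((probs - labels) ** 2))


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Cnn1D:
    """Conv → ReLU → max-pool → flatten backbone with a pluggable head.

    Heads: ``"classifier"`` (dropout → sigmoid unit, supervised),
    ``"regressor"`` (linear multi-output, SSL pretext),
    ``"finetune"`` (dense ReLU → dropout → sigmoid, SSL transfer).
    """

    BACKBONE_KEYS = ("conv_W", "conv_b")

    def __init__(self, spec: CnnSpec, n_features: int, head: str = "classifier",
                 n_targets: int = 1, seed: int = 0):
        if n_features < 1:
            raise ModelError("n_features must be >= 1")
        if head not in ("classifier", "regressor", "finetune"):
            raise ModelError(f"unknown head {head!r}")
        self.spec = spec
        self.n_features = n_features
        self.head = head
        self.n_targets = n_targets
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        k, c, w = spec.kernel_size, spec.conv_filters, spec.flatten_width
        self.params: dict[str, np.ndarray] = {
            "conv_W": _glorot(rng, (k * n_features, c)),
            "conv_b": np.zeros(c),
        }
        if head == "classifier":
            self.params["out_W"] = _glorot(rng, (w, 1))
            self.params["out_b"] = np.zeros(1)
        elif head == "regressor":
            self.params["out_W"] = _glorot(rng, (w, n_targets))
            self.params["out_b"] = np.zeros(n_targets)
        else:
            h = spec.head_hidden_units
            self.params["hid_W"] = _glorot(rng, (w, h))
            self.params["hid_b"] = np.zeros(h)
            self.params["out_W"] = _glorot(rng, (h, 1))
            self.params["out_b"] = np.zeros(1)

    # -- forward / backward ------------------------------------------------

    def _patches(self, X: np.ndarray) -> np.ndarray:
        k = self.spec.kernel_size
        # (B, L, F, k) -> (B, L, k, F) -> (B, L, k*F)
        v = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)
        v = np.moveaxis(v, 3, 2)
        return v.reshape(X.shape[0], self.spec.conv_length, k * self.n_features)

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.spec.input_steps or X.shape[2] != self.n_features:
            raise ModelError(
                f"expected input of shape (B, {self.spec.input_steps}, {self.n_features}), "
                f"got {X.shape}"
            )
        B = X.shape[0]
        p, c = self.spec.pool_size, self.spec.conv_filters
        patches = self._patches(X)
        z1 = patches @ self.params["conv_W"] + self.params["conv_b"]
        a1 = np.maximum(z1, 0.0)
        pl = self.spec.pooled_length
        a1r = a1[:, : pl * p, :].reshape(B, pl, p, c)
        pool_idx = a1r.argmax(axis=2)
        pooled = np.take_along_axis(a1r, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(B, self.spec.flatten_width)
        cache = {"patches": patches, "z1": z1, "pool_idx": pool_idx, "flat": flat,
                 "shapes": {"conv": z1.shape[1:], "pooled": pooled.shape[1:],
                            "flatten": flat.shape[1]}}

        def _dropout(a: np.ndarray, key: str) -> np.ndarray:
            rate = self.spec.dropout_rate
            if not train or rate <= 0.0:
                return a
            assert rng is not None
            mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
            cache[key] = mask
            return a * mask

        if self.head == "classifier":
            flat_d = _dropout(flat, "drop_mask")
            cache["flat_d"] = flat_d
            out = _sigmoid(flat_d @ self.params["out_W"] + self.params["out_b"])
        elif self.head == "regressor":
            out = flat @ self.params["out_W"] + self.params["out_b"]
        else:
            zh = flat @ self.params["hid_W"] + self.params["hid_b"]
            ah = np.maximum(zh, 0.0)
            ah_d = _dropout(ah, "drop_mask")
            cache.update(zh=zh, ah_d=ah_d)
            out = _sigmoid(ah_d @ self.params["out_W"] + self.params["out_b"])
        cache["out"] = out
        return out, cache

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray,
                       rng: np.random.Generator) -> tuple[float, dict[str, np.ndarray]]:
        """Brier/MSE loss and gradients for one (mini-)batch (training mode)."""
        out, cache = self.forward(X, train=True, rng=rng)
        B = X.shape[0]
        Y = np.asarray(Y, dtype=float).reshape(out.shape)
        grads: dict[str, np.ndarray] = {}
        if self.head == "regressor":
            loss = float(np.mean((out - Y) ** 2))
            dz = 2.0 * (out - Y) / out.size
            grads["out_W"] = cache["flat"].T @ dz
            grads["out_b"] = dz.sum(axis=0)
            dflat = dz @ self.params["out_W"].T
        elif self.head == "classifier":
            loss = float(np.mean((out - Y) ** 2))
            dz = 2.0 * (out - Y) * out * (1.0 - out) / B
            grads["out_W"] = cache["flat_d"].T @ dz
            grads["out_b"] = dz.sum(axis=0)
            dflat = dz @ self.params["out_W"].T
            if "drop_mask" in cache:
                dflat = dflat * cache["drop_mask"]
        else:
            loss = float(np.mean((out - Y) ** 2))
            dz = 2.0 * (out - Y) * out * (1.0 - out) / B
            grads["out_W"] = cache["ah_d"].T @ dz
            grads["out_b"] = dz.sum(axis=0)
            dah = dz @ self.params["out_W"].T
            if "drop_mask" in cache:
                dah = dah * cache["drop_mask"]
            dzh = dah * (cache["zh"] > 0)
            grads["hid_W"] = cache["flat"].T @ dzh
            grads["hid_b"] = dzh.sum(axis=0)
            dflat = dzh @ self.params["hid_W"].T

        p, c = self.spec.pool_size, self.spec.conv_filters
        pl = self.spec.pooled_length
        dpool = dflat.reshape(B, pl, c)
        da1r = np.zeros((B, pl, p, c))
        np.put_along_axis(da1r, cache["pool_idx"][:, :, None, :], dpool[:, :, None, :], axis=2)
        da1 = np.zeros_like(cache["z1"])
        da1[:, : pl * p, :] = da1r.reshape(B, pl * p, c)
        dz1 = da1 * (cache["z1"] > 0)
        grads["conv_W"] = np.einsum("blf,blc->fc", cache["patches"], dz1)
        grads["conv_b"] = dz1.sum(axis=(0, 1))
        return loss, grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout inactive)."""
        out, _ = self.forward(np.asarray(X, dtype=float), train=False)
        return out

    def layer_shapes(self) -> dict[str, object]:
        """Shapes observed on an actual forward pass of a dummy window."""
        _, cache = self.forward(np.zeros((1, self.spec.input_steps, self.n_features)))
        return cache["shapes"]

    def get_weights(self, keys=None) -> dict[str, np.ndarray]:
        keys = keys if keys is not None else self.params.keys()
        return {k: self.params[k].copy() for k in keys}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            if self.params[k].shape != v.shape:
                raise ModelError(f"shape mismatch for {k}: {self.params[k].shape} vs {v.shape}")
            self.params[k] = v.copy()


def build_classifier(spec: CnnSpec, n_features: int, seed: int = 0) -> Cnn1D:
    """Untrained supervised classifier per the published architecture."""
    return Cnn1D(spec, n_features, head="classifier", seed=seed)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, trainable: set[str]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in trainable:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _fit(model: Cnn1D, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig,
         max_epochs: int, trainable: set[str], rng: np.random.Generator,
         val: tuple[np.ndarray, np.ndarray] | None = None) -> list[dict]:
    """Mini-batch Adam with a chronological validation split, early stopping
    (best-weight restore) and reduce-on-plateau learning rate.

    When ``val`` is given, all of ``X`` is fitted and ``val`` is the holdout;
    otherwise the chronologically last ``validation_fraction`` of ``X`` is
    held out."""
    if val is not None:
        X_tr, Y_tr = X, Y
        X_va, Y_va = val
    else:
        n = len(X)
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        n_val = min(n_val, n - 1)
        X_tr, Y_tr = X[: n - n_val], Y[: n - n_val]
        X_va, Y_va = X[n - n_val :], Y[n - n_val :]
    opt = _Adam(model.params)
    lr = cfg.initial_lr
    best_val = np.inf
    best_weights = model.get_weights()
    wait = lr_wait = 0
    history: list[dict] = []
    for epoch in range(max_epochs):
        perm = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        for lo in range(0, len(X_tr), cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            loss, grads = model.loss_and_grads(X_tr[idx], Y_tr[idx], rng)
            opt.step(model.params, grads, lr, trainable)
            epoch_loss += loss * len(idx)
        epoch_loss /= len(X_tr)
        val_pred = model.predict(X_va)
        val_loss = float(np.mean((val_pred - Y_va.reshape(val_pred.shape)) ** 2))
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_loss": val_loss, "lr": lr})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            wait = lr_wait = 0
        else:
            wait += 1
            lr_wait += 1
            if lr_wait >= cfg.lr_patience:
                lr = max(cfg.min_lr, lr * cfg.lr_factor)
                lr_wait = 0
            if wait >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    return history


@dataclass
class TrainedClassifier:
    model: Cnn1D
    history: list[dict] = field(default_factory=list)
    provenance: str = "supervised"  # or "ssl"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_probabilities(self, X)


def _check_binary(labels: np.ndarray) -> None:
    if len(np.unique(np.asarray(labels))) < 2:
        raise TrainingError("training labels contain a single class")


def _val_pair(val_windows) -> tuple[np.ndarray, np.ndarray] | None:
    if val_windows is None:
        return None
    return (
        np.asarray(val_windows.windows, dtype=float),
        np.asarray(val_windows.labels, dtype=float)[:, None],
    )


def train_supervised(windows, cfg: TrainConfig, spec: CnnSpec | None = None,
                     val_windows=None) -> TrainedClassifier:
    """Train the supervised classifier on a labeled training window set.

    ``val_windows``, when given, is the chronological tail of the training
    period held out (never oversampled) for early stopping; otherwise the
    last 20% of ``windows`` is held out internally."""
    spec = spec or CnnSpec()
    X = np.asarray(windows.windows, dtype=float)
    y = np.asarray(windows.labels, dtype=float)
    _check_binary(y)
    model = Cnn1D(spec, X.shape[2], head="classifier", seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 1]))
    history = _fit(model, X, y[:, None], cfg, cfg.max_epochs,
                   set(model.params.keys()), rng, val=_val_pair(val_windows))
    return TrainedClassifier(model, history, "supervised")


def _pretext_pairs(windows, pretext: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(windows.windows, dtype=float)
    if pretext == "reconstruct":
        return X, X.mean(axis=1)
    # forecast: target is the feature vector one hour after the window's end;
    # with stride-1 windows that is the next window's final step
    end = np.asarray(windows.end_hour)
    has_next = np.flatnonzero(np.diff(end) == 1)
    return X[has_next], X[has_next + 1][:, -1, :]


def pretrain_ssl(spec: CnnSpec, windows, ssl_cfg: SslConfig,
                 cfg: TrainConfig) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Label-free pretraining of the backbone on the biometric pretext task.

    Use the *non-oversampled* training windows: oversampling is label-driven
    and would leak label information into the pretext stage. Returns the
    backbone weights and the pretext training history.
    """
    X, T = _pretext_pairs(windows, ssl_cfg.pretext)
    if len(X) < 2:
        raise TrainingError("fewer than 2 usable (window, target) pretext pairs")
    model = Cnn1D(spec, X.shape[2], head="regressor", n_targets=T.shape[1], seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 2]))
    history = _fit(model, X, T, cfg, ssl_cfg.pretrain_epochs,
                   set(model.params.keys()), rng)
    return model.get_weights(Cnn1D.BACKBONE_KEYS), history


def finetune_transferred(backbone: dict[str, np.ndarray], windows, cfg: TrainConfig,
                         ssl_cfg: SslConfig, spec: CnnSpec | None = None,
                         val_windows=None) -> TrainedClassifier:
    """Transfer the pretrained backbone and fine-tune for classification.

    Phase 1 trains only the new dense(32, ReLU) → dropout → sigmoid head with
    the backbone frozen; phase 2 unfreezes everything. Both phases use Brier
    loss, batch 32, a chronological 20% validation split and early stopping.
    """
    spec = spec or CnnSpec()
    X = np.asarray(windows.windows, dtype=float)
    y = np.asarray(windows.labels, dtype=float)
    _check_binary(y)
    model = Cnn1D(spec, X.shape[2], head="finetune", seed=cfg.seed)
    model.set_weights(backbone)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 3]))
    head_keys = set(model.params.keys()) - set(Cnn1D.BACKBONE_KEYS)
    val = _val_pair(val_windows)
    hist1 = _fit(model, X, y[:, None], cfg, ssl_cfg.frozen_epochs, head_keys, rng, val=val)
    hist2 = _fit(model, X, y[:, None], cfg, ssl_cfg.unfrozen_epochs,
                 set(model.params.keys()), rng, val=val)
    for h in hist2:
        h["phase"] = "unfrozen"
    return TrainedClassifier(model, hist1 + hist2, "ssl")


def predict_probabilities(clf: TrainedClassifier, windows) -> np.ndarray:
    """Per-window use probability in [0, 1]; deterministic at inference."""
    X = windows.windows if hasattr(windows, "windows") else np.asarray(windows, dtype=float)
    out = clf.model.predict(X)
    return np.clip(out.ravel(), 0.0, 1.0)
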