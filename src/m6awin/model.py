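"""The sequence classifier: two conv blocks, a bidirectional LSTM, and a
fully connected head with sigmoid output.

Architecture: conv(4->n1, width f1) -> batch-norm -> ReLU -> [maxpool] ->
dropout -> conv(n1->n2, width f2) -> batch-norm -> ReLU -> [maxpool] ->
dropout -> BLSTM over positions -> concatenated final forward/backward
hidden states -> FC -> sigmoid scalar.  Trained with Adam on binary
cross-entropy, early-stopped on validation loss.

Implemented on the in-package autograd engine (no GPU framework
dependency); sizes here are desk-scale by design.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .autograd import Tensor, concat, paused_gc
from .encode import encode_batch, pad_width
from .io import WindowRecord, save_checkpoint, load_checkpoint


@dataclass
class ModelConfig:
    filter_sizes: tuple[int, int] = (10, 5)
    filter_counts: tuple[int, int] = (256, 128)
    blstm_units: int = 32
    blstm_reduction: str = "final"  # "final" | "mean" | "flatten"
    fc_units: int = 64
    dropout_rate: float = 0.5
    maxpool: int | None = None
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 5
    window_size: int = 101
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.filter_sizes, list):
            self.filter_sizes = tuple(self.filter_sizes)
        if isinstance(self.filter_counts, list):
            self.filter_counts = tuple(self.filter_counts)
        if min(self.filter_counts) <= 0 or min(self.filter_sizes) <= 0:
            raise ValueError("filter sizes and counts must be positive")
        if self.blstm_units <= 0 or self.fc_units <= 0:
            raise ValueError("layer sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.blstm_reduction not in ("final", "mean", "flatten"):
            raise ValueError("blstm_reduction must be final, mean, or flatten")


@dataclass
class TrainingRecord:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0


class _BatchNorm1d:
    """Per-channel batch normalization over (batch, position)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1))
        self.running_var = np.ones((1, channels, 1))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = (x - mu).pow(2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class _LSTMDirection:
    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(hidden)
        self.Wx = Tensor(
            rng.uniform(-scale, scale, (input_size, 4 * hidden)), requires_grad=True
        )
        self.Wh = Tensor(
            rng.uniform(-scale, scale, (hidden, 4 * hidden)), requires_grad=True
        )
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.hidden = hidden

    def run(
        self, x: Tensor, time_order, masks, collect: bool = False
    ) -> tuple[Tensor, dict[int, Tensor] | None]:
        """Run over `time_order` with per-step (N,1) masks.

        Returns (final h, per-position outputs if `collect`).  Masking
        freezes the state outside each sample's valid span, so the final
        h is the state at the last (first, for the reversed direction)
        valid position.
        """
        n = x.shape[0]
        hsize = self.hidden
        h = Tensor(np.zeros((n, hsize)))
        c = Tensor(np.zeros((n, hsize)))
        outputs: dict[int, Tensor] | None = {} if collect else None
        for t in time_order:
            xt = x[:, :, t]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:hsize].sigmoid()
            f = gates[:, hsize : 2 * hsize].sigmoid()
            g = gates[:, 2 * hsize : 3 * hsize].tanh()
            o = gates[:, 3 * hsize : 4 * hsize].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = masks[t]  # (N,1) float; 1 inside the valid span
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
            if collect:
                outputs[t] = h * m
        return h, outputs


class SequenceClassifier:
    """See module docstring for the architecture."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f1, f2 = config.filter_sizes
        n1, n2 = config.filter_counts

        def he(shape, fan_in):
            return Tensor(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), shape), requires_grad=True
            )

        self.conv1_w = he((n1, 4, f1), 4 * f1)
        self.conv1_b = Tensor(np.zeros(n1), requires_grad=True)
        self.bn1 = _BatchNorm1d(n1)
        self.conv2_w = he((n2, n1, f2), n1 * f2)
        self.conv2_b = Tensor(np.zeros(n2), requires_grad=True)
        self.bn2 = _BatchNorm1d(n2)
        self.lstm_f = _LSTMDirection(n2, config.blstm_units, rng)
        self.lstm_b = _LSTMDirection(n2, config.blstm_units, rng)
        fc_in = (
            self._flatten_width()
            if config.blstm_reduction == "flatten"
            else 2 * config.blstm_units
        )
        self.fc_w = he((fc_in, config.fc_units), fc_in)
        self.fc_b = Tensor(np.zeros(config.fc_units), requires_grad=True)
        self.out_w = he((config.fc_units, 1), config.fc_units)
        self.out_b = Tensor(np.zeros(1), requires_grad=True)

    # -- parameter registry --------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        return {
            "conv1.w": self.conv1_w, "conv1.b": self.conv1_b,
            "bn1.gamma": self.bn1.gamma, "bn1.beta": self.bn1.beta,
            "conv2.w": self.conv2_w, "conv2.b": self.conv2_b,
            "bn2.gamma": self.bn2.gamma, "bn2.beta": self.bn2.beta,
            "lstm_f.Wx": self.lstm_f.Wx, "lstm_f.Wh": self.lstm_f.Wh,
            "lstm_f.b": self.lstm_f.b,
            "lstm_b.Wx": self.lstm_b.Wx, "lstm_b.Wh": self.lstm_b.Wh,
            "lstm_b.b": self.lstm_b.b,
            "fc.w": self.fc_w, "fc.b": self.fc_b,
            "out.w": self.out_w, "out.b": self.out_b,
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.parameters().items()}
        state["bn1.running_mean"] = self.bn1.running_mean.copy()
        state["bn1.running_var"] = self.bn1.running_var.copy()
        state["bn2.running_mean"] = self.bn2.running_mean.copy()
        state["bn2.running_var"] = self.bn2.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: checkpoint "
                        f"{value.shape} vs model {params[key].data.shape}"
                    )
                params[key].data = value.astype(np.float64).copy()
            elif key == "bn1.running_mean":
                self.bn1.running_mean = value.copy()
            elif key == "bn1.running_var":
                self.bn1.running_var = value.copy()
            elif key == "bn2.running_mean":
                self.bn2.running_mean = value.copy()
            elif key == "bn2.running_var":
                self.bn2.running_var = value.copy()
            else:
                raise ValueError(f"unknown state entry {key!r}")

    # -- length bookkeeping --------------------------------------------
    def _feature_lengths(self, lengths: np.ndarray) -> np.ndarray:
        f1, f2 = self.config.filter_sizes
        pad = pad_width(f1)
        pool = self.config.maxpool
        out = lengths + 2 * pad - f1 + 1
        if pool:
            out = out // pool
        out = out - f2 + 1
        if pool:
            out = out // pool
        return np.maximum(out, 1)

    # -- forward passes ------------------------------------------------
    def _conv_block1(self, x: Tensor, training: bool) -> Tensor:
        h = x.conv1d(self.conv1_w, self.conv1_b)
        return self.bn1(h, training).relu()

    def forward(
        self,
        x: Tensor,
        lengths: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Return pre-sigmoid logits of shape (N,)."""
        cfg = self.config

        def dropout(h: Tensor) -> Tensor:
            if not training or cfg.dropout_rate == 0:
                return h
            keep = 1.0 - cfg.dropout_rate
            mask = (dropout_rng.random(h.shape) < keep) / keep
            return h * mask

        h = self._conv_block1(x, training)
        if cfg.maxpool:
            h = h.maxpool1d(cfg.maxpool)
        h = dropout(h)
        h = h.conv1d(self.conv2_w, self.conv2_b)
        h = self.bn2(h, training).relu()
        if cfg.maxpool:
            h = h.maxpool1d(cfg.maxpool)
        h = dropout(h)

        t_total = h.shape[2]
        feat_len = self._feature_lengths(lengths)
        masks = {
            t: (t < feat_len).astype(np.float64)[:, None] for t in range(t_total)
        }
        collect = cfg.blstm_reduction != "final"
        h_fwd, fwd_out = self.lstm_f.run(h, range(t_total), masks, collect)
        h_bwd, bwd_out = self.lstm_b.run(
            h, range(t_total - 1, -1, -1), masks, collect
        )
        if cfg.blstm_reduction == "final":
            h = concat([h_fwd, h_bwd], axis=1)
        elif cfg.blstm_reduction == "mean":
            # masked average of per-position BLSTM outputs
            acc_f = fwd_out[0]
            acc_b = bwd_out[0]
            for t in range(1, t_total):
                acc_f = acc_f + fwd_out[t]
                acc_b = acc_b + bwd_out[t]
            inv_len = (1.0 / feat_len)[:, None]
            h = concat([acc_f * inv_len, acc_b * inv_len], axis=1)
        else:  # flatten
            per_pos = [
                concat([fwd_out[t], bwd_out[t]], axis=1) for t in range(t_total)
            ]
            h = concat(per_pos, axis=1)
            expected = self._flatten_width()
            if h.shape[1] < expected:
                h = concat(
                    [h, Tensor(np.zeros((h.shape[0], expected - h.shape[1])))],
                    axis=1,
                )
        h = (h @ self.fc_w + self.fc_b).relu()
        logits = h @ self.out_w + self.out_b
        return logits.reshape(-1)

    def _flatten_width(self) -> int:
        full = self._feature_lengths(np.array([self.config.window_size]))
        return int(full[0]) * 2 * self.config.blstm_units

    def logits(self, sequences: list[str]) -> np.ndarray:
        """Deterministic eval-mode logits, batched for memory."""
        out = []
        bs = self.config.batch_size
        with paused_gc():
            for i in range(0, len(sequences), bs):
                chunk = sequences[i : i + bs]
                x, lengths = encode_batch(chunk, self.config.filter_sizes[0])
                out.append(self.forward(Tensor(x), lengths, training=False).data)
        return np.concatenate(out) if out else np.empty(0)

    def predict_proba(self, sequences: list[str]) -> np.ndarray:
        """Scores in (0, 1); batch-size invariant."""
        z = self.logits(sequences)
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def first_layer_activations(self, sequences: list[str]) -> np.ndarray:
        """Post-ReLU first-block feature maps, shape (N, n1, T1)."""
        x, _ = encode_batch(sequences, self.config.filter_sizes[0])
        return self._conv_block1(Tensor(x), training=False).data

    def logit_and_input_gradient(self, sequence: str) -> tuple[float, np.ndarray]:
        """Positive-class logit and its gradient w.r.t. the one-hot input.

        The returned gradient has the padded shape (4, 2*pad + L); the
        caller strips the pad columns.
        """
        x, lengths = encode_batch([sequence], self.config.filter_sizes[0])
        with paused_gc():
            xt = Tensor(x, requires_grad=True)
            logit = self.forward(xt, lengths, training=False)
            logit.backward(np.ones(1))
        return float(logit.data[0]), xt.grad[0]


def build_model(config: ModelConfig) -> SequenceClassifier:
    return SequenceClassifier(config)


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _windows_to_xy(windows: list[WindowRecord]) -> tuple[list[str], np.ndarray]:
    seqs = [w.sequence for w in windows]
    labels = np.array([1.0 if w.label == "positive" else 0.0 for w in windows])
    return seqs, labels


def train(
    model: SequenceClassifier,
    train_windows: list[WindowRecord],
    val_windows: list[WindowRecord],
    config: ModelConfig | None = None,
) -> TrainingRecord:
    """Adam on BCE with early stopping on validation loss.

    Stops after `patience` consecutive epochs without validation-loss
    improvement (or at max_epochs) and restores the weights of the best
    validation epoch.  Reproducible given the config seed.
    """
    config = config or model.config
    train_seqs, train_y = _windows_to_xy(train_windows)
    val_seqs, val_y = _windows_to_xy(val_windows)
    if len(set(train_y)) < 2:
        raise ValueError("training set contains a single class; BCE degenerate")
    if not val_seqs:
        raise ValueError("validation set is empty")

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), lr=config.learning_rate)
    record = TrainingRecord(seed=config.seed)
    best_loss = np.inf
    best_state = model.state_dict()
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_seqs))
        epoch_losses = []
        with paused_gc():
            for lo in range(0, len(order), config.batch_size):
                idx = order[lo : lo + config.batch_size]
                x, lengths = encode_batch(
                    [train_seqs[i] for i in idx], config.filter_sizes[0]
                )
                logits = model.forward(
                    Tensor(x), lengths, training=True, dropout_rng=rng
                )
                loss = logits.bce_with_logits(train_y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
        record.train_loss.append(float(np.mean(epoch_losses)))

        val_logits = model.logits(val_seqs)
        val_loss = float(
            np.mean(
                np.maximum(val_logits, 0)
                - val_logits * val_y
                + np.log1p(np.exp(-np.abs(val_logits)))
            )
        )
        record.val_loss.append(val_loss)
        if len(set(val_y)) == 2:
            record.val_auroc.append(float(roc_auc_score(val_y, val_logits)))
        else:
            record.val_auroc.append(float("nan"))

        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_state = model.state_dict()
            record.best_epoch = epoch
            stale = 0
        else:
            stale += 1
        record.stopped_epoch = epoch
        if stale >= config.patience:
            break

    model.load_state_dict(best_state)
    return record


def grid_search_cv(
    windows: list[WindowRecord],
    grid: list[dict],
    k: int = 5,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, list[dict]]:
    """Stratified k-fold grid search; best setting = highest mean AUROC.

    Each grid entry is a dict of ModelConfig field overrides.  Returns
    the winning config and the full per-setting table (mean/sd AUROC).
    """
    if not grid:
        raise ValueError("empty grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    base = asdict(base_config or ModelConfig())
    seqs, labels = _windows_to_xy(windows)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=base["seed"])
    table = []
    best = None
    for setting in grid:
        cfg = ModelConfig(**{**base, **setting})
        fold_scores = []
        for train_idx, val_idx in skf.split(seqs, labels):
            if len(set(labels[val_idx])) < 2 or len(set(labels[train_idx])) < 2:
                raise ValueError(
                    "a fold contains a single class; re-stratify or add data"
                )
            fold_model = build_model(cfg)
            train(
                fold_model,
                [_make_window(seqs[i], labels[i], i) for i in train_idx],
                [_make_window(seqs[i], labels[i], i) for i in val_idx],
                cfg,
            )
            scores = fold_model.logits([seqs[i] for i in val_idx])
            fold_scores.append(float(roc_auc_score(labels[val_idx], scores)))
        row = {
            **setting,
            "mean_auroc": float(np.mean(fold_scores)),
            "sd_auroc": float(np.std(fold_scores)),
        }
        table.append(row)
        if best is None or row["mean_auroc"] > best[1]:
            best = (cfg, row["mean_auroc"])
    return best[0], table


def _make_window(seq: str, label: float, index: int) -> WindowRecord:
    positive = label > 0.5
    return WindowRecord(
        window_id=f"cv_{index}",
        transcript_id="cv",
        start=0,
        end=len(seq),
        sequence=seq,
        label="positive" if positive else "negative",
        site_offsets=[0] if positive else [],
    )


# -- checkpoint plumbing ------------------------------------------------

def save_model(model: SequenceClassifier, path, metrics: dict | None = None) -> None:
    save_checkpoint(model.state_dict(), asdict(model.config), metrics or {}, path)


def load_model(path, expect_window_size: int | None = None) -> SequenceClassifier:
    state, config, _ = load_checkpoint(path, expect_window_size=expect_window_size)
    model = SequenceClassifier(ModelConfig(**config))
    model.load_state_dict(state)
    return model
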