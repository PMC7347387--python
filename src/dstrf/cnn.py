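"""Convolutional encoding model: architecture, training, prediction.

The network maps a 40-lag x 32-band stimulus window to one response sample.
Feature extraction: three 3x3 convolutional layers with 8 kernels each,
then 1x1 convolutions with 4 and 1 kernels to compress channels.  Feature
summation: a 32-unit dense hidden layer and a single linear output.  All
hidden layers are ReLU, bias-free, L2-regularized and use dropout; only the
output node carries a bias.  The bias-free constraint is structural: it is
what makes the network's per-stimulus linearization exact (see
:mod:`dstrf.jacobian`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .stimulus import DataSplit, WindowedStimulus

__all__ = ["CnnSpec", "TrainingConfig", "CnnModel", "train_cnn"]


@dataclass(frozen=True)
class CnnSpec:
    """Architecture hyperparameters of the convolutional encoding model."""

    input_shape: tuple[int, int] = (40, 32)
    conv_channels: tuple[int, ...] = (8, 8, 8)
    conv_kernel: int = 3
    reduce_channels: tuple[int, ...] = (4, 1)
    dense_hidden: int = 32
    dropout_conv: float = 0.3
    dropout_dense: float = 0.4
    l2: float = 0.001


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0
    mse_weight: float = 1.0
    corr_weight: float = 1.0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training config values must be positive")


def _build_layers(spec: CnnSpec, rng: np.random.Generator) -> list[nn.Layer]:
    h, w = spec.input_shape
    layers: list[nn.Layer] = []
    cin = 1
    first = True
    for cout in spec.conv_channels:
        layers.append(nn.Conv2d(cin, cout, spec.conv_kernel, rng, skip_input_grad=first))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout_conv))
        cin, first = cout, False
    for cout in spec.reduce_channels:
        layers.append(nn.Conv2d(cin, cout, 1, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout_conv))
        cin = cout
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * w * cin, spec.dense_hidden, rng, use_bias=False))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(spec.dropout_dense))
    layers.append(nn.Dense(spec.dense_hidden, 1, rng, use_bias=True))
    return layers


def ridge_guided_weights(
    spec: CnnSpec,
    W: np.ndarray,
    bias: float,
    rng: np.random.Generator,
    side_scale: float = 0.5,
    mix_scale: float = 0.05,
) -> list[np.ndarray]:
    """Initialization that makes the network start at a given linear STRF.

    A bias-free ReLU network represents a linear map exactly through a
    mirrored pair of units (``relu(w.x) - relu(-w.x) = w.x``), and the
    nonnegative spectrogram passes unchanged through an identity channel
    of the rectified convolutional stack.  Channel 0 of every feature
    layer carries the raw input; the first dense layer holds ``+W`` and
    ``-W`` in its first two units; the output layer combines them with
    weights +1/-1 and the STRF bias.  All remaining channels and units
    get He-scaled noise (``side_scale``) whose contribution to the output
    is down-weighted (``mix_scale``), so the net initially predicts like
    the ridge STRF while gradient descent is free to grow nonlinear
    corrections.

    Intended for short-recording regimes where training from scratch
    cannot converge; returns a weight list for
    :meth:`CnnModel.set_weights` / :func:`train_cnn`.
    """
    h, w = spec.input_shape
    if W.shape != (h, w):
        raise ValueError("STRF shape must match the network input shape")
    weights: list[np.ndarray] = []
    kk = spec.conv_kernel * spec.conv_kernel
    center = (spec.conv_kernel // 2) * spec.conv_kernel + spec.conv_kernel // 2
    cin = 1
    for cout in spec.conv_channels:
        fan = kk * cin
        m = nn.he_normal(rng, (fan, cout), fan) * side_scale
        m[:, 0] = 0.0
        m[center * cin + 0, 0] = 1.0  # identity passthrough on channel 0
        weights.append(m)
        cin = cout
    for cout in spec.reduce_channels:
        if cout > 1:
            m = nn.he_normal(rng, (cin, cout), cin) * side_scale
            m[:, 0] = 0.0
            m[0, 0] = 1.0
        else:
            # channel bottleneck: dominant passthrough plus a small mix of
            # the side features so their gradients stay alive
            m = nn.he_normal(rng, (cin, cout), cin) * mix_scale
            m[0, 0] = 1.0
        weights.append(m)
        cin = cout
    dense_in = h * w * cin
    d1 = nn.he_normal(rng, (dense_in, spec.dense_hidden), dense_in) * side_scale
    d1[:, 0] = W.ravel()
    d1[:, 1] = -W.ravel()
    weights.append(d1)
    d2 = nn.he_normal(rng, (spec.dense_hidden, 1), spec.dense_hidden) * mix_scale
    d2[0, 0], d2[1, 0] = 1.0, -1.0
    weights.append(d2)
    weights.append(np.array([bias], dtype=np.float32))
    return [np.asarray(v, dtype=np.float32) for v in weights]


class CnnModel:
    """A (possibly trained) convolutional encoding model."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.net = nn.Sequential(_build_layers(spec, rng))
        self._mlp_cache = None

    # -- inference ---------------------------------------------------------

    def _as_batch(self, windows) -> np.ndarray:
        x = windows.windows if isinstance(windows, WindowedStimulus) else np.asarray(windows)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"window shape {x.shape[1:]} does not match model input {self.spec.input_shape}")
        return x[..., None]  # add channel axis

    def predict(self, windows, dtype=np.float64, batch_size: int = 2048) -> np.ndarray:
        """Deterministic (dropout-free) predictions, one per window."""
        x = self._as_batch(windows).astype(dtype)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.net.forward(x[i:i + batch_size], train=False).ravel())
        return np.concatenate(outs)

    @property
    def output_bias(self) -> float:
        return float(self.net.layers[-1].bias[0])

    def input_gradients(self, windows, dtype=np.float64, batch_size: int = 512) -> np.ndarray:
        """d output / d input for each window (the exact linearization).

        Computed by a backward pass through the convolutional layers with
        dropout disabled; independent of the masked weight-product route in
        :mod:`dstrf.jacobian`.
        """
        x = self._as_batch(windows).astype(dtype)
        first_conv = next(l for l in self.net.layers if isinstance(l, nn.Conv2d))
        saved = first_conv.skip_input_grad
        first_conv.skip_input_grad = False
        try:
            grads = []
            for i in range(0, x.shape[0], batch_size):
                xb = x[i:i + batch_size]
                self.net.forward(xb, train=True, rng=None)
                g = self.net.backward(np.ones((xb.shape[0], 1), dtype=dtype))
                grads.append(g[..., 0])
        finally:
            first_conv.skip_input_grad = saved
        return np.concatenate(grads)

    def activation_patterns(self, windows, dtype=np.float32, batch_size: int = 1024) -> np.ndarray:
        """Boolean active/inactive state of every hidden ReLU unit per window."""
        x = self._as_batch(windows).astype(dtype)
        relus = [l for l in self.net.layers if isinstance(l, nn.ReLU)]
        rows = []
        for i in range(0, x.shape[0], batch_size):
            xb = x[i:i + batch_size]
            self.net.forward(xb, train=False)
            rows.append(np.concatenate(
                [r.last_active.reshape(xb.shape[0], -1) for r in relus], axis=1))
        return np.concatenate(rows)

    def n_hidden_units(self) -> int:
        h, w = self.spec.input_shape
        n = sum(h * w * c for c in self.spec.conv_channels)
        n += sum(h * w * c for c in self.spec.reduce_channels)
        return n + self.spec.dense_hidden

    def get_weights(self):
        return self.net.get_weights()

    def set_weights(self, weights) -> None:
        self.net.set_weights(weights)
        self._mlp_cache = None


def train_cnn(
    split: DataSplit,
    spec: CnnSpec | None = None,
    config: TrainingConfig | None = None,
    init_weights: list[np.ndarray] | None = None,
) -> tuple[CnnModel, dict]:
    """Fit the CNN with Adam, dropout, L2 and early stopping.

    Training minimizes the combined MSE-minus-correlation loss on shuffled
    minibatches; after each epoch the same loss is evaluated in one pass
    over the validation set.  Training stops when the validation loss has
    not improved for ``patience`` consecutive epochs (or at ``max_epochs``),
    and the parameters from the best validation epoch are restored (the
    starting parameters count as a candidate, so training can never return
    something worse on validation than its own initialization).  All
    randomness (initialization, shuffling, dropout masks) derives from
    ``config.seed``; ``init_weights`` (e.g. from
    :func:`ridge_guided_weights`) overrides the random He initialization.
    """
    spec = spec or CnnSpec()
    config = config or TrainingConfig()

    ws_tr, y_tr = split.train_data()
    ws_va, y_va = split.validation_data()
    x_tr = ws_tr.windows.astype(np.float32)[..., None]
    x_va = ws_va.windows.astype(np.float32)[..., None]
    y_tr = np.asarray(y_tr, dtype=np.float64)
    y_va = np.asarray(y_va, dtype=np.float64)
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("training and validation splits must be nonempty")

    ss = np.random.SeedSequence(config.seed)
    init_ss, shuffle_ss, dropout_ss = ss.spawn(3)
    model = CnnModel(spec, seed=config.seed)
    # Rebuild with the spawned init stream so init/shuffle/dropout are
    # independent.  A bias-free all-ReLU net on nonnegative inputs can draw
    # an initialization whose narrow channel bottleneck is inactive for
    # every stimulus; such a net outputs a constant, receives no gradient,
    # and never recovers, so degenerate draws are rejected and redrawn.
    probe = x_tr[: min(256, x_tr.shape[0])]
    if init_weights is not None:
        model.net.set_weights(init_weights)
    else:
        for sub in init_ss.spawn(12):
            model.net = nn.Sequential(_build_layers(spec, np.random.default_rng(sub)))
            if float(model.net.forward(probe, train=False).std()) > 1e-7:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate initialization")
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)

    opt = nn.Adam(model.net.params_and_grads, lr=config.learning_rate, l2=spec.l2)

    n = x_tr.shape[0]
    best_val = nn.combined_loss(
        y_va, model.predict(ws_va, dtype=np.float32),
        config.mse_weight, config.corr_weight)
    best_weights = model.net.get_weights()
    best_epoch = -1
    history = {"train_loss": [], "val_loss": [], "init_val_loss": float(best_val)}
    stale = 0

    for epoch in range(config.max_epochs):
        perm = shuffle_rng.permutation(n)
        batch_losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            if idx.size < 2:
                continue
            xb = x_tr[idx]
            yhat = model.net.forward(xb, train=True, rng=dropout_rng).ravel()
            loss, g = nn.combined_loss_grad(
                y_tr[idx], yhat, config.mse_weight, config.corr_weight)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs")
            model.net.backward(g.astype(np.float32)[:, None])
            opt.step()
            batch_losses.append(loss)
        val_pred = model.predict(ws_va, dtype=np.float32)
        val_loss = nn.combined_loss(y_va, val_pred, config.mse_weight, config.corr_weight)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.net.get_weights()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    model.net.set_weights(best_weights)
    model._mlp_cache = None
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return model, history
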