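"""Exact locally-linear receptive fields (DSTRFs) of the CNN model.

A bias-free ReLU network is piecewise linear: for each stimulus window it
applies one exact linear lag x frequency weighting — the dynamic STRF —
equal to the gradient of the output with respect to the input.  Two
independent routes compute it:

``weight_product``
    Convert every convolutional layer to its equivalent locally connected
    (sparse fully-connected) matrix, record which ReLU units are active for
    the given window, zero the rows feeding inactive units, and multiply
    the adjusted weight matrices through.
``gradient``
    A backward pass through the original convolutional network with
    dropout disabled.

Both must agree to float tolerance, and the local identity
``yhat(x) = <DSTRF(x), x> + output_bias`` holds exactly within a linear
region.

Coefficient significance uses a jackknife over contiguous segments of the
training data: a coefficient is kept only when at least ``min_agree`` of
the ``n`` leave-one-segment-out models agree on a strict sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from . import nn
from .cnn import CnnModel, CnnSpec, TrainingConfig, train_cnn
from .stimulus import DataSplit, WindowedStimulus

__all__ = [
    "EquivalentMlp",
    "DstrfSeries",
    "JackknifeEnsemble",
    "conv_to_locally_connected",
    "cnn_to_mlp",
    "compute_dstrf",
    "compute_dstrf_series",
    "jackknife_mean_se",
    "significance_mask",
    "apply_mask",
    "train_jackknife_ensemble",
    "ensemble_dstrf",
    "count_state_switches",
]

logger = logging.getLogger(__name__)


def conv_to_locally_connected(
    kernels: np.ndarray,
    input_shape: tuple[int, int],
    padding: str = "same",
    stride: int = 1,
) -> sp.csr_matrix:
    """Sparse matrix form of a stride-1 'same'-padded 2-D convolution.

    ``kernels`` has shape (kh, kw, C, L).  The returned (H*W*C, H*W*L)
    matrix satisfies ``flat_out = flat_in @ M`` for every input, with both
    tensors flattened row-major as (row, column, channel).
    """
    if stride != 1:
        raise ValueError("only stride 1 is supported")
    if padding != "same":
        raise ValueError("only 'same' zero padding is supported")
    kernels = np.asarray(kernels, dtype=np.float64)
    kh, kw, c_in, c_out = kernels.shape
    if kh % 2 != 1 or kw % 2 != 1:
        raise ValueError("kernel sides must be odd for 'same' padding")
    h, w = input_shape
    ph, pw = kh // 2, kw // 2

    rows, cols, data = [], [], []
    ci = np.arange(c_in)
    lo = np.arange(c_out)
    for di in range(kh):
        for dj in range(kw):
            i = np.arange(max(0, ph - di), min(h, h + ph - di))
            j = np.arange(max(0, pw - dj), min(w, w + pw - dj))
            if i.size == 0 or j.size == 0:
                continue
            out_pos = (i[:, None] * w + j[None, :]).ravel()          # (npos,)
            in_pos = ((i[:, None] + di - ph) * w + (j[None, :] + dj - pw)).ravel()
            r = (in_pos[:, None, None] * c_in + ci[None, :, None]
                 + np.zeros_like(lo)[None, None, :])
            col = (out_pos[:, None, None] * c_out + lo[None, None, :]
                   + np.zeros_like(ci)[None, :, None])
            d = np.broadcast_to(kernels[di, dj][None], (out_pos.size, c_in, c_out))
            rows.append(r.ravel())
            cols.append(col.ravel())
            data.append(d.ravel())
    m = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w * c_in, h * w * c_out),
    )
    return m.tocsr()


@dataclass
class EquivalentMlp:
    """Fully-connected equivalent of the CNN (hidden layers bias-free).

    ``layer_weights[k]`` maps the flattened input of layer ``k`` to its
    flattened pre-activation output; ReLU applies between consecutive
    weights and the final weight adds ``output_bias``.
    """

    layer_weights: list  # scipy sparse or dense (in, out) matrices
    output_bias: float
    input_shape: tuple[int, int] = (40, 32)

    def forward(self, x: np.ndarray, return_activations: bool = False):
        h = np.asarray(x, dtype=np.float64).ravel()
        masks = []
        self._last_boundary = 0
        for wmat in self.layer_weights[:-1]:
            z = wmat.T @ h
            mask = z > 0
            self._last_boundary += int(np.count_nonzero(z == 0.0))
            masks.append(mask)
            h = np.where(mask, z, 0.0)
        out = float(np.asarray(self.layer_weights[-1].T @ h).ravel()[0]
                    + self.output_bias)
        if return_activations:
            return out, masks
        return out

    def dstrf(self, x: np.ndarray) -> np.ndarray:
        """Masked weight-matrix product for the region containing ``x``."""
        _, masks = self.forward(x, return_activations=True)
        # units exactly at zero pre-activation are treated as inactive
        n_boundary = getattr(self, "_last_boundary", 0)
        last = self.layer_weights[-1]
        v = np.asarray(last.todense() if sp.issparse(last) else last,
                       dtype=np.float64).ravel()
        for wmat, mask in zip(reversed(self.layer_weights[:-1]), reversed(masks)):
            v = wmat @ (np.where(mask, v, 0.0))
        if n_boundary:
            logger.debug("%d units exactly at the ReLU boundary", n_boundary)
        return np.asarray(v).ravel().reshape(self.input_shape)


def cnn_to_mlp(model: CnnModel) -> EquivalentMlp:
    """Convert the trained CNN to its locally-connected MLP equivalent."""
    h, w = model.spec.input_shape
    weights = []
    shape = (h, w)
    c_in = 1
    for layer in model.net.layers:
        if isinstance(layer, nn.Conv2d):
            weights.append(conv_to_locally_connected(layer.kernels, shape))
            c_in = layer.cout
        elif isinstance(layer, nn.Dense):
            wm = layer.weights.astype(np.float64)
            weights.append(wm)
        elif isinstance(layer, (nn.ReLU, nn.Dropout, nn.Flatten)):
            continue
        else:
            raise ValueError(f"unsupported layer type {type(layer).__name__}")
    bias_layer = model.net.layers[-1]
    if not isinstance(bias_layer, nn.Dense) or bias_layer.bias is None:
        raise ValueError("expected a biased dense output layer")
    return EquivalentMlp(layer_weights=weights, output_bias=model.output_bias,
                         input_shape=model.spec.input_shape)


@dataclass
class DstrfSeries:
    """Time-indexed stack of lag x frequency linearized receptive fields."""

    values: np.ndarray  # (time, lag, frequency)
    model_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("DSTRF series must be time x lag x frequency")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    def matrix(self) -> np.ndarray:
        """Flattened-slices-by-time matrix (lag*frequency, time)."""
        return self.values.reshape(self.n_slices, -1).T


def _get_mlp(model: CnnModel) -> EquivalentMlp:
    if getattr(model, "_mlp_cache", None) is None:
        model._mlp_cache = cnn_to_mlp(model)
    return model._mlp_cache


def compute_dstrf(model: CnnModel, window: np.ndarray,
                  method: str = "gradient") -> np.ndarray:
    """Exact linearization of the CNN at one stimulus window."""
    window = np.asarray(window, dtype=np.float64)
    if not np.all(np.isfinite(window)):
        raise ValueError("window must be finite")
    if method == "gradient":
        return model.input_gradients(window[None])[0]
    if method == "weight_product":
        return _get_mlp(model).dstrf(window)
    raise ValueError("method must be 'gradient' or 'weight_product'")


def compute_dstrf_series(model: CnnModel, windows: WindowedStimulus | np.ndarray,
                         method: str = "gradient", batch_size: int = 256,
                         model_id: str = "", stimulus_id: str = "") -> DstrfSeries:
    """One DSTRF per window, order preserved."""
    x = windows.windows if isinstance(windows, WindowedStimulus) else np.asarray(windows)
    if method == "gradient":
        values = model.input_gradients(x, batch_size=batch_size)
    elif method == "weight_product":
        mlp = _get_mlp(model)
        values = np.stack([mlp.dstrf(w) for w in x])
    else:
        raise ValueError("method must be 'gradient' or 'weight_product'")
    return DstrfSeries(values=values, model_id=model_id, stimulus_id=stimulus_id)


def jackknife_mean_se(estimates: np.ndarray, axis: int = 0):
    """Jackknife mean and standard error over leave-one-out estimates.

    ``se = sqrt((n - 1) / n * sum((theta_i - mean)^2))``.
    """
    estimates = np.asarray(estimates, dtype=np.float64)
    n = estimates.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 estimates")
    mean = estimates.mean(axis=axis)
    dev = estimates - np.expand_dims(mean, axis)
    se = np.sqrt((n - 1) / n * (dev ** 2).sum(axis=axis))
    return mean, se


def significance_mask(ensemble_dstrfs: np.ndarray, min_agree: int | None = None) -> np.ndarray:
    """Sign-agreement mask over ensemble DSTRF estimates.

    ``ensemble_dstrfs`` has the ensemble axis first.  A coefficient is
    significant when at least ``min_agree`` models give it the same strict
    sign (default ``ceil(0.95 * n)``, i.e. 19 of 20).
    """
    est = np.asarray(ensemble_dstrfs)
    n = est.shape[0]
    if min_agree is None:
        min_agree = int(np.ceil(0.95 * n))
    if min_agree > n:
        raise ValueError("min_agree cannot exceed the ensemble size")
    n_pos = (est > 0).sum(axis=0)
    n_neg = (est < 0).sum(axis=0)
    return (n_pos >= min_agree) | (n_neg >= min_agree)


def apply_mask(series: np.ndarray | DstrfSeries, mask: np.ndarray):
    """Zero the insignificant coefficients; keep the rest unchanged."""
    if isinstance(series, DstrfSeries):
        return replace(series, values=apply_mask(series.values, mask))
    series = np.asarray(series)
    if mask.shape != series.shape:
        raise ValueError("mask shape must match series shape")
    return np.where(mask, series, 0.0)


@dataclass
class JackknifeEnsemble:
    """Leave-one-segment-out CNN ensemble for coefficient significance."""

    models: list[CnnModel]
    segments: list[tuple[int, int]]
    config: TrainingConfig
    histories: list[dict] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)


def train_jackknife_ensemble(
    split: DataSplit,
    spec: CnnSpec | None = None,
    config: TrainingConfig | None = None,
    n: int = 20,
    init_weights=None,
    member_seeds: list[int] | None = None,
) -> JackknifeEnsemble:
    """Train ``n`` CNNs, each excluding one contiguous training segment.

    Segment lengths differ by at most one frame; model ``i`` never sees
    frames from segment ``i``.  All members share ``config.seed`` — the
    same initialization and dropout stream — so the ensemble spread
    measures sensitivity to the resampled data, which is what the
    jackknife standard error and the sign-agreement mask quantify.

    ``init_weights`` may be a weight list shared by every member, or a
    callable ``(member_split, index) -> weights`` evaluated per member (so
    data-derived initializations can be computed from each member's own
    reduced training data, avoiding leakage of the held-out segment).
    ``member_seeds`` overrides the shared seed with one seed per member —
    appropriate when members train from random initialization, so the
    sign-agreement mask also discounts structure specific to any single
    initialization.
    """
    if n < 2:
        raise ValueError("need at least 2 jackknife segments")
    spec = spec or CnnSpec()
    config = config or TrainingConfig()
    t0, t1 = split.train
    bounds = np.linspace(t0, t1, n + 1).round().astype(int)
    segments = [(int(bounds[i]), int(bounds[i + 1])) for i in range(n)]

    models, histories = [], []
    for i in range(n):
        keep = [seg for j, seg in enumerate(segments) if j != i]
        sub = replace_split_train_segments(split, keep)
        iw = init_weights(sub, i) if callable(init_weights) else init_weights
        cfg = config
        if member_seeds is not None:
            cfg = TrainingConfig(
                learning_rate=config.learning_rate, batch_size=config.batch_size,
                max_epochs=config.max_epochs, patience=config.patience,
                seed=int(member_seeds[i]), mse_weight=config.mse_weight,
                corr_weight=config.corr_weight)
        model, hist = train_cnn(sub, spec, cfg, init_weights=iw)
        models.append(model)
        histories.append(hist)
    return JackknifeEnsemble(models=models, segments=segments, config=config,
                             histories=histories)


def replace_split_train_segments(split: DataSplit, segments) -> DataSplit:
    """A view of ``split`` whose training data comes from ``segments`` only."""
    return DataSplit(
        train=split.train, validation=split.validation, test=split.test,
        spectrogram=split.spectrogram, response=split.response,
        test_repeats=split.test_repeats, window_frames=split.window_frames,
        seed=split.seed, train_segments=list(segments),
    )


def ensemble_dstrf(
    ensemble: JackknifeEnsemble,
    windows: WindowedStimulus | np.ndarray,
    min_agree: int | None = None,
    method: str = "gradient",
) -> dict:
    """Jackknife-mean DSTRF series with per-slice significance masking.

    Returns the per-coefficient jackknife mean and standard error, the
    sign-agreement mask and the masked mean series (insignificant
    coefficients set to zero).
    """
    stack = np.stack([
        compute_dstrf_series(m, windows, method=method).values.astype(np.float32)
        for m in ensemble.models])
    mean, se = jackknife_mean_se(stack.astype(np.float64), axis=0)
    mask = significance_mask(stack, min_agree=min_agree)
    masked = apply_mask(mean, mask)
    return {
        "mean": DstrfSeries(values=mean, model_id="jackknife-mean"),
        "se": se,
        "mask": mask,
        "masked": DstrfSeries(values=masked, model_id="jackknife-masked"),
    }


def count_state_switches(model: CnnModel, windows: WindowedStimulus | np.ndarray,
                         batch_size: int = 512) -> float:
    """Mean number of hidden units changing state between consecutive windows."""
    x = windows.windows if isinstance(windows, WindowedStimulus) else np.asarray(windows)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 consecutive windows")
    total = 0
    prev_last = None
    for i in range(0, n, batch_size):
        pats = model.activation_patterns(x[i:i + batch_size])
        if prev_last is not None:
            total += int(np.sum(prev_last != pats[0]))
        total += int(np.sum(pats[:-1] != pats[1:]))
        prev_last = pats[-1]
    return total / (n - 1)
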