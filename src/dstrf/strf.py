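"""Linear spectrotemporal receptive field (STRF) estimation.

A causal lag x frequency weighting predicts the response at frame ``t``
from the past 400 ms of stimulus.  Weights are estimated by ridge
regression; the penalty is chosen from a grid by maximizing Pearson
correlation on the validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import DataSplit, WindowedStimulus

__all__ = ["StrfWeights", "fit_strf"]


@dataclass
class StrfWeights:
    """Ridge STRF: prediction is <W, window> + bias."""

    W: np.ndarray  # (lag, frequency)
    bias: float
    penalty: float | None = None

    def predict(self, windows: WindowedStimulus | np.ndarray) -> np.ndarray:
        x = windows.windows if isinstance(windows, WindowedStimulus) else np.asarray(windows)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.W.shape:
            raise ValueError("window shape does not match STRF shape")
        return x.reshape(x.shape[0], -1) @ self.W.ravel() + self.bias


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _block_pearson(a: np.ndarray, b: np.ndarray, n_blocks: int = 4) -> float:
    """Mean Pearson correlation over contiguous sub-blocks.

    Sub-block averaging makes penalty selection robust to slow shared
    stimulus structure that inflates a single whole-segment correlation.
    """
    idx = np.array_split(np.arange(a.size), min(n_blocks, max(1, a.size // 8)))
    return float(np.mean([_pearson(a[i], b[i]) for i in idx]))


def fit_strf(
    windows: WindowedStimulus | DataSplit,
    response: np.ndarray | None = None,
    reg_grid: np.ndarray | None = None,
    val_windows: WindowedStimulus | None = None,
    val_response: np.ndarray | None = None,
) -> StrfWeights:
    """Fit a ridge STRF, selecting the penalty on the validation split.

    Accepts either a :class:`DataSplit` (train/validation taken from it) or
    explicit train windows + response with optional validation data.  With a
    single candidate penalty no validation data is required.  The penalty
    grid is expressed relative to the mean eigenvalue of the stimulus
    covariance so it is insensitive to stimulus scaling.
    """
    if isinstance(windows, DataSplit):
        split = windows
        ws_tr, y_tr = split.train_data()
        val_windows, val_response = split.validation_data()
    else:
        ws_tr, y_tr = windows, np.asarray(response, dtype=np.float64)

    x = ws_tr.windows.reshape(ws_tr.n_windows, -1).astype(np.float64)
    y = np.asarray(y_tr, dtype=np.float64)
    n, d = x.shape
    xm = x.mean(axis=0)
    ym = y.mean()
    xc = x - xm
    g = xc.T @ xc
    b = xc.T @ (y - ym)

    scale = np.trace(g) / d if np.trace(g) > 0 else 1.0
    if reg_grid is None:
        reg_grid = scale * np.logspace(-4, 2, 7)
    reg_grid = np.atleast_1d(np.asarray(reg_grid, dtype=np.float64))
    if np.any(reg_grid < 0):
        raise ValueError("penalties must be nonnegative")
    if np.any(reg_grid == 0):
        # a singular design with zero penalty is not invertible; fall back
        reg_grid = np.where(reg_grid == 0, scale * 1e-10, reg_grid)

    evals, q = np.linalg.eigh(g)
    qtb = q.T @ b

    if reg_grid.size == 1:
        w = q @ (qtb / (evals + reg_grid[0]))
        shape = (ws_tr.window_frames, ws_tr.n_bands)
        return StrfWeights(W=w.reshape(shape), bias=float(ym - xm @ w),
                           penalty=float(reg_grid[0]))

    if val_windows is None or val_response is None:
        raise ValueError("validation data required to select among multiple penalties")
    xv = val_windows.windows.reshape(val_windows.n_windows, -1).astype(np.float64)
    yv = np.asarray(val_response, dtype=np.float64)

    best = None
    for lam in reg_grid:
        w = q @ (qtb / (evals + lam))
        pred = xv @ w  # bias does not affect correlation
        score = _block_pearson(yv, pred)
        if best is None or score > best[0]:
            best = (score, lam, w)
    _, lam, w = best
    shape = (ws_tr.window_frames, ws_tr.n_bands)
    return StrfWeights(W=w.reshape(shape), bias=float(ym - xm @ w), penalty=float(lam))
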