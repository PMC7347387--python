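"""Linear-nonlinear (LN) and short-term-plasticity (STP) cascade models.

The LN model is a rank-4 time-frequency separable cascade: four Gaussian
spectral kernels select frequency bands, each selected channel is filtered
by a 400 ms (40-tap) FIR temporal filter, the channels are summed, and a
double-exponential static nonlinearity is applied.  The STP variant inserts
a Tsodyks-Markram synaptic adaptation stage between the spectral kernels
and the temporal filters; each channel has a release probability ``u`` and
a recovery time constant ``tau`` (in frames), and the adaptation state
multiplies the channel drive.

Both variants are fitted by full-batch Adam on the combined
MSE-minus-correlation loss with analytic gradients (backpropagation through
time for the adaptation recursion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from . import nn
from .stimulus import DataSplit, WindowedStimulus

__all__ = [
    "LnParams",
    "StpParams",
    "CascadeModel",
    "double_exponential",
    "stp_adaptation",
    "fit_cascade",
]

N_CHANNELS = 4
N_TAPS = 40


def double_exponential(x, a: float, b: float, c: float, kappa: float):
    """Double-exponential sigmoid ``b + a * exp(-exp(-e^kappa * (x - c)))``.

    ``b`` is the baseline, ``b + a`` the saturation, ``c`` the inflection
    input and ``e^kappa`` the slope.  At ``x = c`` the output is
    ``b + a / e``.
    """
    k = np.exp(kappa)
    return b + a * np.exp(-np.exp(-k * (np.asarray(x, dtype=np.float64) - c)))


@numba.njit(cache=True)
def _stp_forward(x, u, tau, d0):  # pragma: no cover - jit kernel
    T, C = x.shape
    d = np.empty((T, C))
    for c in range(C):
        prev = d0
        d[0, c] = prev
        for t in range(1, T):
            prev = prev + u[c] * x[t - 1, c] * (1.0 - prev) - prev / tau[c]
            d[t, c] = prev
    return d


@numba.njit(cache=True)
def _stp_backward(x, u, tau, d, gy):  # pragma: no cover - jit kernel
    """Backprop through the adaptation recursion.

    ``gy`` is dL/dy with y = d * x.  Returns (gx, gu, gtau) where gx is the
    gradient with respect to the module input.
    """
    T, C = x.shape
    gx = np.zeros((T, C))
    gu = np.zeros(C)
    gtau = np.zeros(C)
    for c in range(C):
        lam = 0.0  # dL/dd[t]
        for t in range(T - 1, -1, -1):
            lam += gy[t, c] * x[t, c]
            gx[t, c] += gy[t, c] * d[t, c]
            if t > 0:
                prev = d[t - 1, c]
                gu[c] += lam * x[t - 1, c] * (1.0 - prev)
                gtau[c] += lam * prev / (tau[c] * tau[c])
                gx[t - 1, c] += lam * u[c] * (1.0 - prev)
                lam = lam * (1.0 - u[c] * x[t - 1, c] - 1.0 / tau[c])
    return gx, gu, gtau


def stp_adaptation(x: np.ndarray, u: np.ndarray, tau: np.ndarray,
                   d0: float = 0.0) -> np.ndarray:
    """Tsodyks-Markram adaptation applied per channel.

    The gain state updates as ``d(t) = d(t-1) + u * x(t-1) * (1 - d(t-1))
    - d(t-1) / tau`` with ``d(0) = d0``, and the output is ``y = d * x``.
    ``x`` is a (time x channels) nonnegative drive.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    u = np.broadcast_to(np.asarray(u, dtype=np.float64), (x.shape[1],)).copy()
    tau = np.broadcast_to(np.asarray(tau, dtype=np.float64), (x.shape[1],)).copy()
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    if np.any(x < 0):
        raise ValueError("adaptation input must be nonnegative")
    d = _stp_forward(x, u, tau, float(d0))
    return d * x


@dataclass
class LnParams:
    """Rank-4 separable cascade parameters."""

    centers: np.ndarray   # (4,) Gaussian centres, band index units
    widths: np.ndarray    # (4,) Gaussian widths, bands (> 0)
    amps: np.ndarray      # (4,) Gaussian amplitudes
    fir: np.ndarray       # (4, 40) temporal taps; tap 39 = current frame
    dexp: tuple[float, float, float, float]  # (a, b, c, kappa)

    def spectral_kernels(self, n_bands: int) -> np.ndarray:
        f = np.arange(n_bands, dtype=np.float64)
        return self.amps[:, None] * np.exp(
            -((f[None, :] - self.centers[:, None]) ** 2)
            / (2.0 * self.widths[:, None] ** 2))


@dataclass
class StpParams:
    """Per-channel Tsodyks-Markram parameters."""

    u: np.ndarray            # (4,) release probabilities in [0, 1]
    tau: np.ndarray          # (4,) recovery time constants, frames (> 0)
    d0: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.tau = np.asarray(self.tau, dtype=np.float64)
        if np.any((self.u < 0) | (self.u > 1)):
            raise ValueError("u must lie in [0, 1]")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")


@dataclass
class CascadeModel:
    """LN cascade, optionally with an STP stage after the spectral kernels."""

    ln: LnParams
    stp: StpParams | None = None

    def response(self, spectrogram: np.ndarray) -> np.ndarray:
        """Per-frame output over a continuous (time x frequency) spectrogram.

        The first ``N_TAPS - 1`` frames use an implicit zero history.
        """
        s = np.asarray(spectrogram, dtype=np.float64)
        g = self.ln.spectral_kernels(s.shape[1])           # (4, F)
        chans = s @ g.T                                    # (T, 4)
        if self.stp is not None:
            chans = stp_adaptation(np.maximum(chans, 0.0),
                                   self.stp.u, self.stp.tau, self.stp.d0)
        z = np.zeros(s.shape[0])
        for i in range(N_CHANNELS):
            z += np.convolve(chans[:, i], self.ln.fir[i, ::-1])[: s.shape[0]]
        a, b, c, kappa = self.ln.dexp
        return double_exponential(z, a, b, c, kappa)

    def predict(self, windows: WindowedStimulus) -> np.ndarray:
        """One prediction per window (common encoding-model contract).

        Stride-1 windows are stitched back into the continuous spectrogram
        so the cascade's temporal state is computed once over real history.
        """
        if windows.stride_frames != 1:
            raise ValueError("cascade prediction requires stride-1 windows")
        w = windows.windows
        spec = np.concatenate([w[0], w[1:, -1, :]], axis=0)
        full = self.response(spec)
        return full[windows.window_frames - 1:]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _CascadeFitState:
    """Unconstrained parameter vector and analytic-gradient loss."""

    def __init__(self, n_bands: int, variant: str, rng: np.random.Generator,
                 y_scale: float, y_mean: float):
        self.n_bands = n_bands
        self.variant = variant
        qs = np.linspace(0.15, 0.85, N_CHANNELS)
        self.p = {
            "centers": qs * (n_bands - 1) + rng.normal(0, 1.0, N_CHANNELS),
            "log_widths": np.log(2.0) + rng.normal(0, 0.1, N_CHANNELS),
            "amps": rng.normal(0, 0.05, N_CHANNELS),
            "fir": rng.normal(0, 0.05, (N_CHANNELS, N_TAPS)),
            "dexp": np.array([2.0 * y_scale, y_mean - y_scale, 0.0, 0.0]),
        }
        if variant == "STP":
            self.p["u_raw"] = np.full(N_CHANNELS, -2.0)
            self.p["log_taum1"] = np.full(N_CHANNELS, np.log(9.0))  # tau ~ 10

    def params(self) -> tuple[LnParams, StpParams | None]:
        ln = LnParams(
            centers=self.p["centers"].copy(),
            widths=np.exp(self.p["log_widths"]),
            amps=self.p["amps"].copy(),
            fir=self.p["fir"].copy(),
            dexp=tuple(self.p["dexp"]),
        )
        stp = None
        if self.variant == "STP":
            stp = StpParams(u=_sigmoid(self.p["u_raw"]),
                            tau=1.0 + np.exp(self.p["log_taum1"]), d0=0.0)
        return ln, stp

    def loss_and_grads(self, s, y, train_mask, mse_w=1.0, corr_w=1.0):
        """Forward + backward over the full spectrogram ``s`` (T x F)."""
        T, F = s.shape
        fidx = np.arange(F, dtype=np.float64)
        centers = self.p["centers"]
        widths = np.exp(self.p["log_widths"])
        amps = self.p["amps"]
        fir = self.p["fir"]
        a, b, c, kappa = self.p["dexp"]

        phi = np.exp(-((fidx[None, :] - centers[:, None]) ** 2)
                     / (2.0 * widths[:, None] ** 2))       # (4, F)
        gk = amps[:, None] * phi
        chans = s @ gk.T                                   # (T, 4)

        if self.variant == "STP":
            u = _sigmoid(self.p["u_raw"])
            tau = 1.0 + np.exp(self.p["log_taum1"])
            rect = np.maximum(chans, 0.0)
            d = _stp_forward(rect, u, tau, 0.0)
            drive = d * rect
        else:
            drive = chans

        z = np.zeros(T)
        for i in range(N_CHANNELS):
            z += np.convolve(drive[:, i], fir[i, ::-1])[:T]

        k = np.exp(kappa)
        w_in = np.exp(np.clip(-k * (z - c), -60.0, 60.0))
        e_in = np.exp(-w_in)
        yhat = b + a * e_in

        loss, gout_valid = nn.combined_loss_grad(
            y[train_mask], yhat[train_mask], mse_w, corr_w)
        gout = np.zeros(T)
        gout[train_mask] = gout_valid

        g = {}
        g["dexp"] = np.array([
            float(gout @ e_in),
            float(gout.sum()),
            float(-(gout * a * e_in * k * w_in).sum()),
            float((gout * a * e_in * w_in * (z - c) * k).sum()),
        ])
        gz = gout * a * e_in * k * w_in

        gdrive = np.zeros_like(drive)
        gfir = np.empty_like(fir)
        for i in range(N_CHANNELS):
            # z[t] = sum_j fir_rev[j] * drive[t - j], fir_rev[j] = fir[39 - j]
            fr = fir[i, ::-1]
            for j in range(N_TAPS):
                gfir[i, N_TAPS - 1 - j] = gz[j:] @ drive[: T - j, i]
                gdrive[: T - j, i] += fr[j] * gz[j:]

        g["fir"] = gfir

        if self.variant == "STP":
            grect, gu, gtau = _stp_backward(rect, u, tau, d, gdrive)
            g["u_raw"] = gu * u * (1.0 - u)
            g["log_taum1"] = gtau * (tau - 1.0)
            gchan = grect * (chans > 0)
        else:
            gchan = gdrive

        ggk = gchan.T @ s                                   # (4, F)
        g["amps"] = (ggk * phi).sum(axis=1)
        common = ggk * gk
        g["centers"] = (common * (fidx[None, :] - centers[:, None])).sum(axis=1) \
            / widths ** 2
        g["log_widths"] = (common * (fidx[None, :] - centers[:, None]) ** 2).sum(axis=1) \
            / widths ** 2
        return loss, g, yhat


def fit_cascade(
    split: DataSplit,
    variant: str = "LN",
    seed: int = 0,
    learning_rate: float = 0.01,
    max_iters: int = 2000,
    patience: int = 200,
    max_retries: int = 3,
) -> tuple[CascadeModel, dict]:
    """Fit the LN or STP cascade by full-batch Adam with early stopping.

    The loss is the combined MSE-minus-correlation objective evaluated over
    the training frames; every iteration also scores the validation frames
    and the best-validation parameters are returned.  If the loss diverges
    the fit restarts with a threefold smaller step, up to ``max_retries``.
    """
    if variant not in ("LN", "STP"):
        raise ValueError("variant must be 'LN' or 'STP'")
    s = np.asarray(split.spectrogram, dtype=np.float64)
    y = np.asarray(split.response, dtype=np.float64)
    wf = split.window_frames

    train_mask = np.zeros(s.shape[0], dtype=bool)
    for seg0, seg1 in split.train_segments:
        train_mask[seg0 + wf - 1: seg1] = True
    val_mask = np.zeros(s.shape[0], dtype=bool)
    v0, v1 = split.validation
    val_mask[v0 + wf - 1: v1] = True
    if not train_mask.any() or not val_mask.any():
        raise ValueError("train and validation splits must contain predictable frames")

    lr = learning_rate
    last_error = None
    for _ in range(max_retries):
        state = _CascadeFitState(
            s.shape[1], variant, np.random.default_rng(np.random.SeedSequence(seed)),
            y_scale=float(np.std(y[train_mask])) or 1.0,
            y_mean=float(np.mean(y[train_mask])),
        )
        keys = sorted(state.p)
        m = {k: np.zeros_like(state.p[k]) for k in keys}
        v = {k: np.zeros_like(state.p[k]) for k in keys}
        best_val = np.inf
        best_p = {k: state.p[k].copy() for k in keys}
        stale = 0
        diverged = False
        history = {"train_loss": [], "val_loss": []}
        for t in range(1, max_iters + 1):
            loss, grads, yhat = state.loss_and_grads(s, y, train_mask)
            if not np.isfinite(loss):
                diverged = True
                last_error = f"non-finite loss at iteration {t}"
                break
            val_loss = nn.combined_loss(y[val_mask], yhat[val_mask])
            history["train_loss"].append(loss)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_p = {k: state.p[k].copy() for k in keys}
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
            bc1 = 1.0 - 0.9 ** t
            bc2 = 1.0 - 0.999 ** t
            for key in keys:
                gk = grads[key]
                m[key] = 0.9 * m[key] + 0.1 * gk
                v[key] = 0.999 * v[key] + 0.001 * gk * gk
                state.p[key] = state.p[key] - lr * (m[key] / bc1) / (
                    np.sqrt(v[key] / bc2) + 1e-8)
        if not diverged:
            state.p = best_p
            ln, stp = state.params()
            history["best_val_loss"] = float(best_val)
            return CascadeModel(ln=ln, stp=stp), history
        lr /= 3.0
    raise RuntimeError(f"cascade fit diverged after {max_retries} retries: {last_error}")
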