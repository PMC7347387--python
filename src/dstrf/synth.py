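"""Synthetic stimuli and ground-truth neurons with known nonlinearities.

Every pipeline stage is testable without recorded data: the generator
produces a ripple-based auditory spectrogram and continuous response traces
from model neurons whose nonlinearity class is planted and controllable —

``linear``
    y = <W, X_t>: a pure spectrotemporal filter.
``static_nl``
    A double-exponential output nonlinearity applied to the linear drive.
``gain_adaptive``
    The linear drive divided by (1 + eta * E_t), where E_t is a leaky
    integral of recent stimulus energy — divisive gain adaptation.
``temporal_hold``
    A sustained response: y_t is the maximum template match over the past
    ``hold`` frames, so a transient feature produces a plateau whose
    underlying receptive field drifts in latency.
``multi_template``
    Template switching: the neuron applies receptive field W1 when a
    band-energy statistic of the current window exceeds a threshold and W2
    otherwise.

Clean responses are z-scored; repeat trials add i.i.d. Gaussian noise in
response-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cascades import double_exponential
from .stimulus import (AuditorySpectrogram, DataSplit, WindowedStimulus,
                       make_windows, split_dataset)

__all__ = [
    "SyntheticNeuronSpec",
    "SyntheticDataset",
    "generate_stimulus",
    "gabor_template",
    "simulate_neuron",
    "make_dataset",
]

NEURON_KINDS = ("linear", "static_nl", "gain_adaptive", "temporal_hold", "multi_template")


def generate_stimulus(
    duration_s: float,
    n_bands: int = 32,
    frame_rate: float = 100.0,
    seed: int = 0,
    n_ripples_per_min: float = 160.0,
) -> AuditorySpectrogram:
    """Spectrotemporally correlated nonnegative stimulus.

    A sum of seeded random moving ripples (localized drifting gratings in
    the time-frequency plane) over a smoothed noise floor; a stand-in with
    the gross second-order structure of a speech spectrogram.
    """
    if duration_s < 5:
        raise ValueError("stimulus must be at least 5 s long")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames)
    f = np.arange(n_bands)
    s = np.zeros((n_frames, n_bands))

    n_rip = max(1, int(round(n_ripples_per_min * duration_s / 60.0)))
    for _ in range(n_rip):
        t0 = rng.uniform(0, n_frames)
        dur = rng.uniform(15, 60)                     # 150-600 ms events
        f0 = rng.uniform(0, n_bands)
        bw = rng.uniform(3, 10)
        rate = rng.uniform(-8, 8) / frame_rate        # cycles per frame
        scale = rng.uniform(0.05, 0.4)                # cycles per band
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.lognormal(0.0, 0.5)
        env_t = np.exp(-0.5 * ((t - t0) / (dur / 2.0)) ** 2)
        env_f = np.exp(-0.5 * ((f - f0) / bw) ** 2)
        carrier = np.sin(2 * np.pi * (rate * t[:, None] + scale * f[None, :]) + phase)
        s += amp * env_t[:, None] * env_f[None, :] * np.maximum(carrier, 0.0)

    floor = rng.standard_normal((n_frames, n_bands))
    floor = ndimage.gaussian_filter(floor, sigma=(3.0, 1.5))
    s += 0.15 * np.maximum(floor, 0.0)

    # overall amplitude modulation at the ~300 ms scale, as in natural sound
    env = ndimage.gaussian_filter1d(rng.standard_normal(n_frames), sigma=30.0)
    env = 1.0 + 0.5 * env / (3.0 * (env.std() or 1.0))
    s *= np.maximum(env, 0.1)[:, None]

    cfs = np.geomspace(180.0, 7000.0, n_bands)
    return AuditorySpectrogram(values=np.maximum(s, 0.0), frame_rate=frame_rate,
                               center_freqs=cfs)


def gabor_template(
    window_frames: int = 40,
    n_bands: int = 32,
    center_lag: int = 32,
    center_band: int = 16,
    lag_sigma: float = 4.0,
    band_sigma: float = 3.0,
    orientation: float = 0.0,
    cycles: float = 0.12,
) -> np.ndarray:
    """Localized Gabor-like lag x frequency receptive-field template."""
    tt, ff = np.meshgrid(np.arange(window_frames), np.arange(n_bands), indexing="ij")
    dt, df = tt - center_lag, ff - center_band
    env = np.exp(-0.5 * ((dt / lag_sigma) ** 2 + (df / band_sigma) ** 2))
    carrier = np.cos(2 * np.pi * cycles * (dt * np.cos(orientation) + df * np.sin(orientation)))
    w = env * carrier
    return w / np.linalg.norm(w)


@dataclass
class SyntheticNeuronSpec:
    """Ground-truth neuron description.

    ``templates`` holds one (or, for ``multi_template``, two) lag x band
    receptive fields.  ``params`` are kind-specific: ``eta``/``tau_e`` for
    gain adaptation, ``hold`` (frames) for temporal hold, ``theta`` for the
    switching threshold, ``dexp`` for the static nonlinearity.
    """

    kind: str
    templates: list[np.ndarray] = field(default_factory=list)
    eta: float = 3.0
    tau_e: float = 30.0            # leaky-integrator time constant, frames
    hold: int = 5
    theta: float = 0.0             # threshold on the z-scored band statistic
    dexp: tuple[float, float, float, float] = (1.0, 0.0, 0.5, 1.0)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NEURON_KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if not self.templates:
            if self.kind == "multi_template":
                self.templates = [
                    gabor_template(center_lag=33, center_band=9, orientation=0.0),
                    gabor_template(center_lag=31, center_band=23, orientation=1.2),
                ]
            else:
                self.templates = [gabor_template()]
        if self.kind == "multi_template" and len(self.templates) != 2:
            raise ValueError("multi_template needs exactly two templates")
        if self.hold > 30:
            raise ValueError("hold must be <= 30 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_neuron(windows: WindowedStimulus, spec: SyntheticNeuronSpec) -> np.ndarray:
    """Clean (noiseless, un-normalized) response series, one per window."""
    x = windows.windows
    n = x.shape[0]
    w0 = spec.templates[0]
    if w0.shape != x.shape[1:]:
        raise ValueError("template shape does not match window shape")
    drive = x.reshape(n, -1) @ w0.ravel()

    if spec.kind == "linear":
        return drive
    if spec.kind == "static_nl":
        d = (drive - drive.mean()) / (drive.std() or 1.0)
        return double_exponential(d, *spec.dexp)
    if spec.kind == "gain_adaptive":
        energy = x[:, -1, :].mean(axis=1)  # per-frame stimulus energy
        decay = 1.0 - 1.0 / spec.tau_e
        e = np.empty(n)
        acc = 0.0
        for t in range(n):
            acc = decay * acc + energy[t] / spec.tau_e
            e[t] = acc
        # normalized upward energy fluctuation, so the divisive gain swings
        # over roughly one order of magnitude at the default eta
        e = np.maximum((e - e.mean()) / (e.std() or 1.0), 0.0)
        return drive / (1.0 + spec.eta * e)
    if spec.kind == "temporal_hold":
        # sustained response to sparse transient feature matches: the match
        # is the drive's rectified excess over its 75th percentile, and the
        # response holds the largest recent match for `hold` frames
        m = np.maximum(drive - np.quantile(drive, 0.75), 0.0)
        held = np.array([m[max(0, t - spec.hold): t + 1].max() for t in range(n)])
        return held
    # multi_template: switch on the slowly varying upper/lower band-energy
    # balance.  The gate is scale-free (a log energy ratio carries no
    # information about overall level a linear model could exploit) and
    # leaky-integrated over ~tau_e frames, so template episodes last long
    # enough to be learnable and clusterable.
    from scipy.signal import lfilter
    w1 = spec.templates[1]
    half = x.shape[2] // 2
    up = x[:, -1, half:].mean(axis=1)
    lo = x[:, -1, :half].mean(axis=1)
    a = 1.0 / spec.tau_e
    eu = lfilter([a], [1.0, -(1.0 - a)], up)
    el = lfilter([a], [1.0, -(1.0 - a)], lo)
    ratio = np.log((eu + 1e-9) / (el + 1e-9))
    stat = (ratio - ratio.mean()) / (ratio.std() or 1.0)
    drive1 = x.reshape(n, -1) @ w1.ravel()
    return np.where(stat > spec.theta, drive, drive1)


@dataclass
class SyntheticDataset:
    """Stimulus, ground-truth responses and a ready-made split."""

    spectrogram: AuditorySpectrogram
    clean: np.ndarray              # z-scored noiseless response per frame
    response: np.ndarray           # single noisy training/validation trace
    repeats: np.ndarray            # trials x test-frames noisy responses
    split: DataSplit
    spec: SyntheticNeuronSpec
    seed: int = 0


def make_dataset(
    spec: SyntheticNeuronSpec,
    duration_s: float = 180.0,
    n_repeats: int = 6,
    fractions: tuple[float, float, float] = (0.90, 0.03, 0.07),
    window_frames: int = 40,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate a complete synthetic recording session.

    The stimulus is split contiguously into train/validation/test blocks.
    The clean response is z-scored (over predictable frames); the training
    trace and each test repeat add independent Gaussian noise of
    ``spec.noise_sd`` response-SD units.  Fully reproducible from
    ``(spec, seed)``.
    """
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence([seed, 2025])
    stim_ss, noise_ss = ss.spawn(2)
    stim = generate_stimulus(duration_s, n_bands=spec.templates[0].shape[1],
                             seed=int(stim_ss.generate_state(1)[0] % (2 ** 31)))
    ws = make_windows(stim, window_frames)
    clean_valid = simulate_neuron(ws, spec)

    n = stim.n_frames
    clean = np.zeros(n)
    clean_valid = (clean_valid - clean_valid.mean()) / (clean_valid.std() or 1.0)
    clean[ws.target_frames()] = clean_valid

    rng = np.random.default_rng(noise_ss)
    response = clean + spec.noise_sd * rng.standard_normal(n)

    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_test = int(round(fractions[2] * n))
    test_range = (n - n_test, n)
    repeats_full = clean[test_range[0]: test_range[1]] + spec.noise_sd * \
        rng.standard_normal((n_repeats, n_test))

    split = split_dataset(
        stim.values, response,
        fractions=(fractions[0] / (fractions[0] + fractions[1]),
                   fractions[1] / (fractions[0] + fractions[1])),
        test_range=test_range, test_repeats=repeats_full,
        window_frames=window_frames, seed=seed,
    )
    return SyntheticDataset(
        spectrogram=stim, clean=clean, response=response,
        repeats=repeats_full, split=split, spec=spec, seed=seed,
    )
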