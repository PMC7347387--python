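"""Auditory stimulus front end.

Converts audio waveforms to an auditory spectrogram via a simplified cochlear
model (constant-Q filterbank, hair-cell compression, lateral inhibition,
envelope extraction), reduces the spectral resolution, cuts the spectrogram
into causal sliding windows for regression, and partitions stimulus/response
frames into train/validation/test splits.

Conventions
-----------
* Frames are 10 ms (100 Hz frame rate) unless stated otherwise.
* Windows are causal: the window ending at frame ``t`` predicts the response
  at frame ``t``.  Lag index 0 is the oldest frame in the window and lag
  index ``window_frames - 1`` is the current frame.
* Splits are contiguous, and windows that would straddle a split boundary
  are dropped from both sides (no zero-padded history is fabricated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "AuditorySpectrogram",
    "WindowedStimulus",
    "DataSplit",
    "load_wav",
    "compute_auditory_spectrogram",
    "reduce_bands",
    "make_windows",
    "split_dataset",
]


@dataclass
class Waveform:
    """Mono audio samples with a sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def load_wav(path) -> Waveform:
    """Read a PCM or float WAV file as a mono :class:`Waveform`."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:  # average channels
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(samples=data.astype(np.float64), rate=float(rate))


@dataclass
class AuditorySpectrogram:
    """Nonnegative time x frequency matrix at a fixed frame rate.

    ``values[t, f]`` is the activity of the band centred at
    ``center_freqs[f]`` (Hz, ascending, log-spaced) in frame ``t``.
    """

    values: np.ndarray
    frame_rate: float = 100.0
    center_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("spectrogram must be 2-D (time x frequency)")
        if self.center_freqs is not None:
            self.center_freqs = np.asarray(self.center_freqs, dtype=np.float64)
            if self.center_freqs.size != self.values.shape[1]:
                raise ValueError("center_freqs length must match band count")
            if np.any(np.diff(self.center_freqs) <= 0):
                raise ValueError("center_freqs must be ascending")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def _log_spaced_cfs(n_bands: int, fmin: float, fmax: float) -> np.ndarray:
    return np.geomspace(fmin, fmax, n_bands)


def compute_auditory_spectrogram(
    wav: Waveform,
    n_bands: int = 128,
    frame_rate: float = 100.0,
    fmin: float = 180.0,
    fmax: float | None = None,
) -> AuditorySpectrogram:
    """Auditory-nerve-like spectrogram of an audio waveform.

    The model runs four stages per band: (1) a constant-Q fourth-order
    gammatone filter, log-spaced centre frequencies; (2) a hair-cell stage
    of half-wave rectification, low-pass smoothing and cube-root
    compression; (3) a lateral-inhibition stage implemented as a first-order
    difference along the spectral axis followed by half-wave rectification;
    (4) envelope integration into ``1 / frame_rate`` frames.

    Parameters
    ----------
    wav:
        Input audio.  Must be at least one frame long.
    n_bands:
        Number of cochlear filters (native resolution 128).
    frame_rate:
        Output frames per second (default 100, i.e. 10 ms frames).
    fmin, fmax:
        Centre-frequency range.  ``fmax=None`` selects
        ``min(7000, 0.45 * wav.rate)`` so the filterbank always fits under
        the Nyquist frequency.
    """
    if fmax is None:
        fmax = min(7000.0, 0.45 * wav.rate)
    if wav.rate < 2.0 * fmax:
        raise ValueError("sampling rate must be at least twice the highest center frequency")
    samples_per_frame = wav.rate / frame_rate
    if wav.samples.size < samples_per_frame:
        raise ValueError("audio shorter than one spectrogram frame")

    cfs = _log_spaced_cfs(n_bands, fmin, fmax)
    n_frames = int(np.ceil(wav.samples.size / samples_per_frame))

    # hair-cell low-pass: smooths the rectified fine structure
    lp_b, lp_a = sps.butter(2, min(0.95, 2 * 400.0 / wav.rate), btype="low")

    banded = np.empty((n_bands, wav.samples.size))
    for i, cf in enumerate(cfs):
        b, a = sps.gammatone(cf, "iir", fs=wav.rate)
        y = sps.lfilter(b, a, wav.samples)
        y = np.maximum(y, 0.0)                    # rectify
        y = sps.lfilter(lp_b, lp_a, y)            # smooth
        banded[i] = np.cbrt(np.maximum(y, 0.0))   # compress

    # lateral inhibition: spectral first difference, half-wave rectified.
    # Band 0 keeps its own (compressed) envelope as the baseline row.
    lin = np.empty_like(banded)
    lin[0] = banded[0]
    lin[1:] = np.maximum(banded[1:] - banded[:-1], 0.0)

    # frame integration (mean over each 10 ms frame, ragged tail included)
    edges = np.round(np.arange(1, n_frames + 1) * samples_per_frame).astype(int)
    edges = np.minimum(edges, wav.samples.size)
    csum = np.concatenate([np.zeros((n_bands, 1)), np.cumsum(lin, axis=1)], axis=1)
    starts = np.concatenate([[0], edges[:-1]])
    counts = np.maximum(edges - starts, 1)
    frames = (csum[:, edges] - csum[:, starts]) / counts

    return AuditorySpectrogram(values=frames.T, frame_rate=frame_rate, center_freqs=cfs)


def reduce_bands(spec: AuditorySpectrogram, n_out: int = 32) -> AuditorySpectrogram:
    """Reduce spectral resolution by averaging contiguous band groups.

    With 128 native bands and ``n_out=32`` each output band is the mean of
    4 adjacent input bands; centre frequencies are combined geometrically
    so log spacing is preserved.
    """
    n_in = spec.n_bands
    if n_out > n_in:
        raise ValueError(f"cannot reduce {n_in} bands to {n_out}")
    groups = np.array_split(np.arange(n_in), n_out)
    values = np.stack([spec.values[:, g].mean(axis=1) for g in groups], axis=1)
    cfs = None
    if spec.center_freqs is not None:
        cfs = np.array([np.exp(np.mean(np.log(spec.center_freqs[g]))) for g in groups])
    return AuditorySpectrogram(values=values, frame_rate=spec.frame_rate, center_freqs=cfs)


@dataclass
class WindowedStimulus:
    """Causal sliding windows over a spectrogram.

    ``windows[k]`` is a ``window_frames x n_bands`` slice covering frames
    ``[k * stride, k * stride + window_frames)`` and predicts the response
    at frame ``first_valid_frame + k * stride``.
    """

    windows: np.ndarray  # (n, lag, frequency), a view where possible
    window_frames: int = 40
    stride_frames: int = 1
    first_valid_frame: int = 39

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_bands(self) -> int:
        return self.windows.shape[2]

    def target_frames(self) -> np.ndarray:
        """Absolute response-frame index predicted by each window."""
        return self.first_valid_frame + self.stride_frames * np.arange(self.n_windows)


def make_windows(
    spec: AuditorySpectrogram | np.ndarray,
    window_frames: int = 40,
    stride: int = 1,
) -> WindowedStimulus:
    """Cut a spectrogram into causal sliding lag x frequency windows."""
    values = spec.values if isinstance(spec, AuditorySpectrogram) else np.asarray(spec)
    n_frames = values.shape[0]
    if window_frames > n_frames:
        raise ValueError("window_frames exceeds available frames")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    view = sliding_window_view(values, window_frames, axis=0)  # (n, bands, lag)
    windows = np.swapaxes(view[::stride], 1, 2)
    return WindowedStimulus(
        windows=windows,
        window_frames=window_frames,
        stride_frames=stride,
        first_valid_frame=window_frames - 1,
    )


@dataclass
class DataSplit:
    """Disjoint contiguous frame ranges for training/validation/test.

    Ranges are ``(start, stop)`` half-open frame intervals into the full
    spectrogram/response.  ``test_repeats`` holds the trials x time response
    matrix recorded over the test range (used for noise correction).
    """

    train: tuple[int, int]
    validation: tuple[int, int]
    test: tuple[int, int]
    spectrogram: np.ndarray
    response: np.ndarray
    test_repeats: np.ndarray | None = None
    window_frames: int = 40
    seed: int | None = None
    train_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranges = [self.train, self.validation, self.test]
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if max(a0, b0) < min(a1, b1) and a1 > a0 and b1 > b0:
                raise ValueError("split ranges overlap")
        if not self.train_segments:
            self.train_segments = [self.train]

    def _windows_for(self, rng: tuple[int, int]):
        start, stop = rng
        if stop - start < self.window_frames:
            return None, None
        ws = make_windows(self.spectrogram[start:stop], self.window_frames)
        targets = start + ws.target_frames()
        return ws, self.response[targets]

    def train_data(self):
        """(windows, targets) over all contiguous training segments."""
        xs, ys = [], []
        for seg in self.train_segments:
            ws, y = self._windows_for(seg)
            if ws is not None:
                xs.append(ws.windows)
                ys.append(y)
        if not xs:
            raise ValueError("no usable training windows")
        wf = self.window_frames
        return (
            WindowedStimulus(np.concatenate(xs), wf, 1, wf - 1),
            np.concatenate(ys),
        )

    def validation_data(self):
        ws, y = self._windows_for(self.validation)
        if ws is None:
            raise ValueError("validation range shorter than one window")
        return ws, y

    def test_data(self):
        ws, y = self._windows_for(self.test)
        if ws is None:
            raise ValueError("test range shorter than one window")
        return ws, y

    def test_repeat_targets(self) -> np.ndarray:
        """Trials x time repeats aligned to the test-window targets."""
        if self.test_repeats is None:
            raise ValueError("split has no test repeats")
        start = self.test[0]
        ws, _ = self.test_data()
        idx = start + ws.target_frames() - start
        return self.test_repeats[:, idx]


def split_dataset(
    spec: AuditorySpectrogram | np.ndarray,
    response: np.ndarray,
    fractions: tuple[float, float] = (0.97, 0.03),
    test_range: tuple[int, int] | None = None,
    test_repeats: np.ndarray | None = None,
    window_frames: int = 40,
    seed: int | None = None,
) -> DataSplit:
    """Partition frames into contiguous train/validation/test ranges.

    ``fractions`` divides the non-test frames between training and
    validation.  The layout is deterministic — ``[train | validation]``
    followed by (or preceded by, if ``test_range`` says so) the test block —
    so identical arguments always produce identical splits.
    """
    values = spec.values if isinstance(spec, AuditorySpectrogram) else np.asarray(spec)
    response = np.asarray(response, dtype=np.float64)
    n = values.shape[0]
    if response.shape[0] != n:
        raise ValueError("response length must equal spectrogram frame count")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if test_range is None:
        test_range = (n, n)  # empty
    t0, t1 = test_range
    if not (0 <= t0 <= t1 <= n):
        raise ValueError("invalid test range")
    if test_repeats is not None:
        test_repeats = np.asarray(test_repeats, dtype=np.float64)
        if test_repeats.ndim != 2 or test_repeats.shape[1] != t1 - t0:
            raise ValueError("test repeats must be trials x len(test_range)")

    # non-test frames: assume the test block is a suffix or prefix; carve
    # train/validation contiguously out of the larger remaining block.
    if t0 == 0:
        lo, hi = t1, n
    else:
        lo, hi = 0, t0
        if t1 < n:
            raise ValueError("test range must be a prefix or suffix block")
    avail = hi - lo
    n_train = int(round(fractions[0] * avail))
    train = (lo, lo + n_train)
    validation = (lo + n_train, hi)
    if validation[1] - validation[0] == 0:
        warnings.warn("validation split is empty", stacklevel=2)
    if validation[1] - validation[0] not in (0,) and validation[1] - validation[0] < window_frames:
        warnings.warn("validation split shorter than one window", stacklevel=2)

    return DataSplit(
        train=train,
        validation=validation,
        test=(t0, t1),
        spectrogram=values,
        response=response,
        test_repeats=test_repeats,
        window_frames=window_frames,
        seed=seed,
    )
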