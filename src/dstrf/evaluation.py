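"""Noise-corrected model evaluation and comparison.

Trial-to-trial variability caps the correlation any stimulus-driven model
can reach.  With repeated presentations of the test stimulus, the plain
prediction-response correlation is rescaled by the repeat reliability to
estimate the correlation with the noiseless response: split the ``n``
trials into odd- and even-numbered halves with means ``Ro`` and ``Re``,
then

    rho_c = (rho(P, Re) + rho(P, Ro)) / (2 * sqrt(rho(Ro, Re)))

The reported accuracy is ``rho_c ** 2``.  Sites whose odd/even reliability
is not positive cannot be corrected and are flagged as invalid rather than
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RepeatSet", "ModelScore", "noise_corrected_correlation",
           "compare_models", "error_vs_data_curve"]


@dataclass
class RepeatSet:
    """Trials x time responses to repeated presentations of one stimulus."""

    trials: np.ndarray

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        if self.trials.ndim != 2 or self.trials.shape[0] < 2:
            raise ValueError("need a trials x time matrix with >= 2 trials")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def odd_even_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Means of odd- and even-numbered trials (1-based numbering)."""
        return self.trials[0::2].mean(axis=0), self.trials[1::2].mean(axis=0)


@dataclass
class ModelScore:
    """Noise-corrected score of one model on one repeat set."""

    rho_c: float
    rho_c_sq: float
    raw_corr: float          # plain Pearson r with the trial mean
    reliability: float       # rho(Ro, Re)
    valid: bool = True
    n_frames: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64) - np.mean(a)
    b = np.asarray(b, dtype=np.float64) - np.mean(b)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def noise_corrected_correlation(prediction: np.ndarray,
                                repeats: RepeatSet | np.ndarray) -> ModelScore:
    """Score a prediction against repeated test responses."""
    if not isinstance(repeats, RepeatSet):
        repeats = RepeatSet(repeats)
    p = np.asarray(prediction, dtype=np.float64)
    if p.shape[0] != repeats.trials.shape[1]:
        raise ValueError("prediction length must match repeat length")
    ro, re = repeats.odd_even_means()
    rel = _pearson(ro, re)
    raw = _pearson(p, repeats.trials.mean(axis=0))
    if rel <= 0:
        return ModelScore(rho_c=np.nan, rho_c_sq=np.nan, raw_corr=raw,
                          reliability=rel, valid=False, n_frames=p.size)
    rho_c = 0.5 * (_pearson(p, re) + _pearson(p, ro)) / np.sqrt(rel)
    return ModelScore(rho_c=float(rho_c), rho_c_sq=float(rho_c ** 2), raw_corr=raw,
                      reliability=rel, valid=True, n_frames=p.size)


def compare_models(score_a: ModelScore, score_b: ModelScore) -> float:
    """Improvement of model a over model b in noise-corrected R-squared."""
    if score_a.n_frames != score_b.n_frames:
        raise ValueError("scores were computed on different test sets")
    if not (score_a.valid and score_b.valid):
        raise ValueError("cannot compare scores from unreliable sites")
    return float(score_a.rho_c_sq - score_b.rho_c_sq)


def error_vs_data_curve(durations: np.ndarray, rho_sq: np.ndarray) -> dict:
    """Log-linear fit of prediction error against training-data amount.

    Fits ``1 - rho^2 = intercept + slope * log2(duration)`` by least
    squares (duplicated durations pool naturally).  The relative error
    reduction per doubling is ``-slope`` divided by the fitted error at the
    geometric-mean duration.
    """
    durations = np.asarray(durations, dtype=np.float64)
    rho_sq = np.asarray(rho_sq, dtype=np.float64)
    if durations.size != rho_sq.size or durations.size < 3:
        raise ValueError("need at least 3 (duration, rho^2) points")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    x = np.log2(durations)
    err = 1.0 - rho_sq
    slope, intercept = np.polyfit(x, err, 1)
    mid = intercept + slope * x.mean()
    frac = float(-slope / mid) if mid > 0 else np.nan
    return {"slope": float(slope), "intercept": float(intercept),
            "fractional_reduction_per_doubling": frac}
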