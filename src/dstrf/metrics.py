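"""Nonlinearity metrics computed from a DSTRF series.

``complexity``
    Sum of max-normalized singular values of the (lag*frequency) x time
    matrix of linearized receptive fields — the effective diversity of
    linear functions the network applies; 1 for a purely linear model.
``gain_change``
    Standard deviation over time of the per-slice DSTRF magnitude (itself
    the standard deviation of the slice's coefficients) — adaptation-like
    amplitude variation.
``temporal_hold``
    Largest shift ``n`` (frames) for which lag-shifted consecutive-slice
    correlations significantly exceed unshifted ones (one-tailed Wilcoxon
    signed-rank, p < 0.05) — persistence of a pattern whose latency tracks
    the stimulus.
``shape_change``
    Complexity of the shift-aligned series — diversity of spectrotemporal
    shapes that remains after removing temporal hold, with gain variation
    absorbed by shared singular vectors.

Receptive-field subtypes are found by k-means on correlation similarity of
the aligned slices, with the number of clusters chosen by the gap
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .jacobian import DstrfSeries, count_state_switches

__all__ = [
    "NonlinearityProfile",
    "AlignmentResult",
    "ClusterResult",
    "complexity",
    "gain_change",
    "temporal_hold",
    "align_dstrfs",
    "shape_change",
    "cluster_dstrfs",
    "profile",
]


def _values(series) -> np.ndarray:
    v = series.values if isinstance(series, DstrfSeries) else np.asarray(series)
    if v.ndim != 3:
        raise ValueError("series must be time x lag x frequency")
    return np.asarray(v, dtype=np.float64)


def complexity(series) -> float:
    """Sum of max-normalized singular values of the slice-by-time matrix."""
    v = _values(series)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 slices")
    mat = v.reshape(v.shape[0], -1).T   # (lag*freq, time)
    s = np.linalg.svd(mat, compute_uv=False)
    if s[0] == 0:
        raise ValueError("complexity undefined for an all-zero series")
    return float(s.sum() / s.max())


def gain_change(series) -> float:
    """Std over time of per-slice DSTRF magnitude (coefficient std, ddof=1)."""
    v = _values(series)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 slices")
    flat = v.reshape(v.shape[0], -1)
    mags = flat.std(axis=1, ddof=1)
    return float(mags.std(ddof=1))


def _shift_lags(slices: np.ndarray, n: int) -> np.ndarray:
    """Displace slices along the lag axis by ``n``, zero-filling.

    Positive ``n`` moves content toward older lags (lower lag index), the
    direction a stimulus-locked feature travels as time advances.
    """
    out = np.zeros_like(slices)
    if n == 0:
        out[...] = slices
    elif n > 0:
        out[:, :-n or None, :] = slices[:, n:, :]
    else:
        out[:, -n:, :] = slices[:, :n, :]
    return out


def _row_corrs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows of two (n, d) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def temporal_hold(series, max_shift: int = 30, alpha: float = 0.05) -> int:
    """Largest lag shift whose alignment gain is statistically significant.

    For each candidate shift ``n``, compares corr(DSTRF_t, DSTRF_{t+n})
    against the same correlation with DSTRF_{t+n} displaced by ``n`` lags,
    across all t, with a one-tailed Wilcoxon signed-rank test.  The hold is
    the longest run of consecutive significant shifts starting at n = 1
    (0 when n = 1 is not significant): a pattern that "persists for n
    frames" must realign at every intermediate shift too, and requiring
    the run keeps the false-positive rate at the single-test level instead
    of compounding across the 30 candidate shifts.
    """
    v = _values(series)
    t_len = v.shape[0]
    if t_len <= max_shift + 1:
        raise ValueError("series must be longer than max_shift + 1")
    flat = v.reshape(t_len, -1)
    hold = 0
    any_valid = False
    for n in range(1, max_shift + 1):
        a = flat[:-n]
        b = v[n:]
        alpha_corr = _row_corrs(a, b.reshape(b.shape[0], -1))
        # realignment: a feature sits n lag steps OLDER in the later slice,
        # so shifting that slice by -n moves it back under the earlier one
        beta_corr = _row_corrs(a, _shift_lags(b, -n).reshape(b.shape[0], -1))
        ok = np.isfinite(alpha_corr) & np.isfinite(beta_corr)
        if ok.sum() < 10:
            break
        any_valid = True
        diff = beta_corr[ok] - alpha_corr[ok]
        if np.allclose(diff, 0):
            break
        p = stats.wilcoxon(beta_corr[ok], alpha_corr[ok], alternative="greater").pvalue
        if p >= alpha:
            break
        hold = n
    if not any_valid:
        raise ValueError("all slice pairs degenerate; temporal hold undefined")
    return hold


@dataclass
class AlignmentResult:
    """Outcome of iterative lag alignment to the running mean DSTRF."""

    shifts: np.ndarray            # integer lag shift applied to each slice
    aligned: DstrfSeries
    converged: bool
    iterations: int
    mean_correlation: float       # mean slice-to-mean correlation at the end


def align_dstrfs(series, max_iter: int = 50, max_shift: int = 30) -> AlignmentResult:
    """Iteratively lag-align each slice to the running average DSTRF.

    Each iteration shifts every slice (zero-filled, at most ``max_shift``
    lags) to maximize its correlation with the current mean, then
    recomputes the mean; stops when the shifts no longer change.  If the
    iteration oscillates, the best configuration seen (by mean
    slice-to-mean correlation) is returned with ``converged=False``.
    """
    v = _values(series)
    t_len = v.shape[0]
    if t_len == 0:
        raise ValueError("series is empty")
    shifts = np.zeros(t_len, dtype=int)
    cand = np.arange(-max_shift, max_shift + 1)
    best = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = np.stack([_shift_lags(v[t:t + 1], shifts[t])[0] for t in range(t_len)])
        mean = aligned.mean(axis=0)
        # correlation of every candidate shift of every slice with the mean
        corr = np.full((t_len, cand.size), -np.inf)
        mean_flat = (mean - mean.mean()).ravel()
        for idx, s in enumerate(cand):
            shifted = _shift_lags(v, s).reshape(t_len, -1)
            c = _row_corrs(shifted, np.broadcast_to(mean.ravel(), shifted.shape))
            corr[:, idx] = np.where(np.isfinite(c), c, -np.inf)
        new_shifts = cand[np.argmax(corr, axis=1)]
        score = float(np.nanmean(np.max(corr, axis=1)))
        if best is None or score > best[0]:
            best = (score, new_shifts.copy())
        if np.array_equal(new_shifts, shifts) and it > 1:
            converged = True
            shifts = new_shifts
            break
        shifts = new_shifts
    if not converged:
        shifts = best[1]
    aligned = np.stack([_shift_lags(v[t:t + 1], shifts[t])[0] for t in range(t_len)])
    mean = aligned.mean(axis=0)
    final_corr = _row_corrs(aligned.reshape(t_len, -1),
                            np.broadcast_to(mean.ravel(), (t_len, mean.size)))
    return AlignmentResult(
        shifts=shifts,
        aligned=DstrfSeries(values=aligned, model_id="aligned"),
        converged=converged,
        iterations=it,
        mean_correlation=float(np.nanmean(final_corr)),
    )


def shape_change(series, max_iter: int = 50, max_shift: int = 30) -> float:
    """Complexity of the lag-aligned series."""
    return complexity(align_dstrfs(series, max_iter=max_iter, max_shift=max_shift).aligned)


@dataclass
class ClusterResult:
    """Receptive-field subtypes found by k-means + gap statistic."""

    k: int
    labels: np.ndarray
    cluster_means: np.ndarray              # (k, lag, frequency)
    cluster_stimulus_means: np.ndarray | None
    gap: np.ndarray
    gap_se: np.ndarray


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return xc / norm


def _within_dispersion(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((x - centers[labels]) ** 2).sum())


def cluster_dstrfs(
    aligned_series,
    windows: np.ndarray | None = None,
    k_range=range(1, 7),
    n_ref: int = 10,
    n_init: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """Cluster aligned DSTRF slices by correlation similarity.

    Slices are vectorized, centred and unit-normalized (so Euclidean
    k-means acts on correlation distance), clustered for each candidate
    ``k``, and the number of clusters is chosen by the gap statistic with a
    principal-component-aligned uniform reference (the reference is drawn
    uniformly in the bounding box of the data expressed in its principal
    axes, so it shares the data's correlation structure; an axis-aligned
    box badly overestimates k for spatially smooth receptive fields).
    The first-local-optimum rule applies: the smallest k with
    Gap(k) >= Gap(k+1) - SE(k+1).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    v = _values(aligned_series)
    t_len = v.shape[0]
    if t_len < max(k_range):
        raise ValueError("need at least max(k_range) slices")
    x = _normalize_rows(v.reshape(t_len, -1))
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def fit_kmeans(data, k, rs):
        if k == 1:
            center = data.mean(axis=0, keepdims=True)
            return np.zeros(data.shape[0], dtype=int), center
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rs)
        labels = km.fit_predict(data)
        return labels, km.cluster_centers_

    # principal-axis frame for the reference distribution
    mu = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - mu, full_matrices=False)
    z = (x - mu) @ vt.T
    lo, hi = z.min(axis=0), z.max(axis=0)
    log_w = []
    log_w_ref = []
    labels_by_k = {}
    for k in k_range:
        labels, centers = fit_kmeans(x, k, int(rng.integers(2 ** 31)))
        labels_by_k[k] = labels
        log_w.append(np.log(_within_dispersion(x, labels, centers) + 1e-300))
        refs = []
        for _ in range(n_ref):
            ref = rng.uniform(lo, hi, size=z.shape) @ vt + mu
            rl, rc = fit_kmeans(ref, k, int(rng.integers(2 ** 31)))
            refs.append(np.log(_within_dispersion(ref, rl, rc) + 1e-300))
        log_w_ref.append(refs)
    log_w = np.array(log_w)
    log_w_ref = np.array(log_w_ref)             # (len(k_range), n_ref)
    gap = log_w_ref.mean(axis=1) - log_w
    se = log_w_ref.std(axis=1, ddof=1) * np.sqrt(1.0 + 1.0 / n_ref)

    k_opt = k_range[-1]
    for i in range(len(k_range) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            k_opt = k_range[i]
            break
    labels = labels_by_k[k_opt]
    cluster_means = np.stack([v[labels == c].mean(axis=0) for c in range(k_opt)])
    stim_means = None
    if windows is not None:
        w = np.asarray(windows)
        if w.shape[0] != t_len:
            raise ValueError("windows must align with the DSTRF slices")
        stim_means = np.stack([w[labels == c].mean(axis=0) for c in range(k_opt)])
    return ClusterResult(k=k_opt, labels=labels, cluster_means=cluster_means,
                         cluster_stimulus_means=stim_means, gap=gap, gap_se=se)


@dataclass
class NonlinearityProfile:
    """Per-site scalar summary of network nonlinearity."""

    complexity: float
    gain_change: float
    temporal_hold: int
    shape_change: float
    mean_switches: float | None = None

    def as_dict(self) -> dict:
        return {
            "complexity": self.complexity,
            "gain_change": self.gain_change,
            "temporal_hold": self.temporal_hold,
            "shape_change": self.shape_change,
            "mean_switches": self.mean_switches,
        }


def profile(series, model=None, windows=None, max_shift: int = 30) -> NonlinearityProfile:
    """Bundle all nonlinearity metrics with one shared configuration."""
    alignment = align_dstrfs(series, max_shift=max_shift)
    switches = None
    if model is not None and windows is not None:
        switches = count_state_switches(model, windows)
    return NonlinearityProfile(
        complexity=complexity(series),
        gain_change=gain_change(series),
        temporal_hold=temporal_hold(series, max_shift=max_shift),
        shape_change=complexity(alignment.aligned),
        mean_switches=switches,
    )
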