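"""Nonlinearity metrics on constructed DSTRF series with known answers."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import svdvals

from dstrf.metrics import (align_dstrfs, cluster_dstrfs, complexity,
                           gain_change, shape_change, temporal_hold,
                           _shift_lags)

LAG, FREQ = 20, 12


def pattern(rng=None, lag_c=10, f_c=6):
    tt, ff = np.meshgrid(np.arange(LAG), np.arange(FREQ), indexing="ij")
    w = np.exp(-0.5 * (((tt - lag_c) / 2.0) ** 2 + ((ff - f_c) / 1.5) ** 2))
    w *= np.cos(0.9 * (tt - lag_c))
    return w / np.linalg.norm(w)


def orthogonal_patterns(k):
    """k mutually orthogonal, equal-norm lag x freq patterns."""
    rng = np.random.default_rng(0)
    m = rng.standard_normal((LAG * FREQ, k))
    q, _ = np.linalg.qr(m)
    return [q[:, i].reshape(LAG, FREQ) for i in range(k)]


class TestComplexity:
    def test_constant_series_is_one(self):
        series = np.repeat(pattern()[None], 30, axis=0)
        assert complexity(series) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 4])
    def test_orthogonal_cycle_gives_k(self, k):
        pats = orthogonal_patterns(k)
        series = np.stack([pats[t % k] for t in range(8 * k)])
        assert complexity(series) == pytest.approx(k, abs=1e-8)

    def test_matches_independent_svd(self, rng):
        series = rng.standard_normal((25, LAG, FREQ))
        s = svdvals(series.reshape(25, -1).T)
        assert complexity(series) == pytest.approx(s.sum() / s.max())

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            complexity(np.zeros((5, LAG, FREQ)))
        with pytest.raises(ValueError):
            complexity(np.zeros((1, LAG, FREQ)) + 1)


class TestGainChange:
    def test_constant_series_is_zero(self):
        series = np.repeat(pattern()[None], 10, axis=0)
        assert gain_change(series) == pytest.approx(0.0, abs=1e-12)

    def test_two_slice_closed_form(self):
        w = pattern()
        w = w - w.mean()  # zero-mean so |W| is a plain std
        series = np.stack([w, 2 * w])
        s = w.std(ddof=1)
        assert gain_change(series) == pytest.approx(s / np.sqrt(2), rel=1e-10)

    def test_matches_direct_formula(self, rng):
        series = rng.standard_normal((12, LAG, FREQ))
        mags = np.array([
            np.sqrt(((sl - sl.mean()) ** 2).sum() / (LAG * FREQ - 1))
            for sl in series])
        want = np.sqrt(((mags - mags.mean()) ** 2).sum() / (len(mags) - 1))
        assert gain_change(series) == pytest.approx(want)

    def test_scales_linearly_while_complexity_invariant(self, rng):
        series = rng.standard_normal((15, LAG, FREQ))
        assert gain_change(3 * series) == pytest.approx(3 * gain_change(series))
        assert complexity(3 * series) == pytest.approx(complexity(series))


def blob(lag_c=13, f_c=6):
    """Non-oscillatory localized pattern: its autocorrelation decays
    monotonically with lag shift, so realignment comparisons are clean."""
    tt, ff = np.meshgrid(np.arange(LAG), np.arange(FREQ), indexing="ij")
    w = np.exp(-0.5 * (((tt - lag_c) / 2.0) ** 2 + ((ff - f_c) / 1.5) ** 2))
    return w / np.linalg.norm(w)


def drift_fixture(hold=5, n_events=120, gap=9, noise=1e-2, seed=0):
    """Events whose pattern moves one lag toward older per frame for
    exactly `hold` steps, separated by noise-filled gaps long enough that
    cross-event comparisons carry no systematic alignment."""
    rng = np.random.default_rng(seed)
    slices = []
    base = blob()
    for _ in range(n_events):
        for j in range(hold + 1):
            slices.append(_shift_lags(base[None], j)[0]
                          + noise * rng.standard_normal((LAG, FREQ)))
        for _ in range(gap):
            slices.append(noise * rng.standard_normal((LAG, FREQ)))
    return np.stack(slices)


class TestTemporalHold:
    def test_static_pattern_has_zero_hold(self, rng):
        series = np.repeat(pattern()[None], 80, axis=0)
        series += 1e-4 * rng.standard_normal(series.shape)
        assert temporal_hold(series, max_shift=10) == 0

    def test_recovers_planted_drift_length(self):
        assert temporal_hold(drift_fixture(hold=5), max_shift=10) == 5
        assert temporal_hold(drift_fixture(hold=3), max_shift=10) == 3

    def test_drift_recovery_is_seed_stable(self):
        holds = [temporal_hold(drift_fixture(hold=5, seed=s), max_shift=10)
                 for s in range(5)]
        assert int(np.median(holds)) == 5

    def test_drift_fixture_agrees_with_direct_test_oracle(self):
        """Directly evaluate the shifted/unshifted correlations and the
        signed-rank test for a few n, mirroring the metric's definition."""
        series = drift_fixture(hold=5)
        flat = series.reshape(series.shape[0], -1)
        for n, expect_sig in ((3, True), (8, False)):
            a, b = [], []
            for t in range(len(series) - n):
                x = flat[t]
                y_un = flat[t + n]
                y_sh = _shift_lags(series[t + n: t + n + 1], -n)[0].ravel()
                if x.std() == 0 or y_un.std() == 0 or y_sh.std() == 0:
                    continue
                a.append(np.corrcoef(x, y_un)[0, 1])
                b.append(np.corrcoef(x, y_sh)[0, 1])
            p = stats.wilcoxon(b, a, alternative="greater").pvalue
            assert (p < 0.05) == expect_sig

    def test_independent_noise_has_zero_hold(self, rng):
        series = rng.standard_normal((90, LAG, FREQ))
        assert temporal_hold(series, max_shift=10) == 0

    def test_rejects_short_series(self, rng):
        with pytest.raises(ValueError):
            temporal_hold(rng.standard_normal((10, LAG, FREQ)), max_shift=10)


class TestAlignment:
    def test_already_aligned_series_keeps_zero_shifts(self, rng):
        series = np.repeat(pattern()[None], 12, axis=0)
        series += 1e-5 * rng.standard_normal(series.shape)
        res = align_dstrfs(series, max_shift=8)
        assert np.all(res.shifts == res.shifts[0])
        assert res.converged

    def test_recovers_planted_shifts_up_to_global_offset(self):
        base = pattern(lag_c=10)
        true_shifts = np.array([0, 1, 2, 3, 0, 1, 2, 3, 0, 2] * 3)
        series = np.stack([_shift_lags(base[None], s)[0] for s in true_shifts])
        res = align_dstrfs(series, max_shift=6)
        rec = -res.shifts  # undo-shift recovers the planted displacement
        offset = rec[0] - true_shifts[0]
        np.testing.assert_array_equal(rec - offset, true_shifts)

    def test_alignment_never_hurts_mean_correlation(self, rng):
        base = pattern(lag_c=10)
        series = np.stack([
            _shift_lags(base[None], int(s))[0]
            for s in rng.integers(-4, 5, size=30)])
        series += 0.02 * rng.standard_normal(series.shape)
        res = align_dstrfs(series, max_shift=8)
        before = np.mean([np.corrcoef(s.ravel(), series.mean(0).ravel())[0, 1]
                          for s in series])
        assert res.mean_correlation >= before - 1e-9


class TestShapeChange:
    def test_gain_only_series_is_rank_one(self, rng):
        base = pattern()
        gains = rng.uniform(0.5, 3.0, 40)
        series = gains[:, None, None] * base[None]
        assert shape_change(series, max_shift=6) == pytest.approx(1.0, abs=1e-6)

    def test_alignment_removes_drift_induced_rank(self, rng):
        base = pattern(lag_c=10)
        series = np.stack([
            _shift_lags(base[None], int(s))[0]
            for s in rng.integers(0, 5, size=40)])
        sc = shape_change(series, max_shift=8)
        assert sc < complexity(series)
        assert sc < 1.6

    def test_two_orthogonal_templates_give_two(self):
        p1, p2 = orthogonal_patterns(2)
        series = np.stack([p1 if t % 2 == 0 else p2 for t in range(40)])
        assert shape_change(series, max_shift=4) == pytest.approx(2.0, abs=0.25)


class TestClustering:
    def test_recovers_two_planted_templates(self, rng):
        p1, p2 = pattern(lag_c=5, f_c=3), pattern(lag_c=15, f_c=9)
        series = np.stack([
            (p1 if t % 2 == 0 else p2) + 0.05 * rng.standard_normal((LAG, FREQ))
            for t in range(60)])
        res = cluster_dstrfs(series, seed=1)
        assert res.k == 2
        sims = np.zeros((2, 2))
        for i, c in enumerate(res.cluster_means):
            for j, p in enumerate((p1, p2)):
                sims[i, j] = np.corrcoef(c.ravel(), p.ravel())[0, 1]
        assert sims.max(axis=1).min() > 0.9

    def test_single_template_gives_one_cluster(self, rng):
        base = pattern()
        series = base[None] + 0.05 * rng.standard_normal((60, LAG, FREQ))
        res = cluster_dstrfs(series, seed=1)
        assert res.k == 1

    def test_labels_invariant_to_global_rescaling(self, rng):
        p1, p2 = pattern(lag_c=5, f_c=3), pattern(lag_c=15, f_c=9)
        series = np.stack([
            (p1 if t % 3 == 0 else p2) + 0.03 * rng.standard_normal((LAG, FREQ))
            for t in range(30)])
        a = cluster_dstrfs(series, seed=3)
        b = cluster_dstrfs(5.0 * series, seed=3)
        assert a.k == b.k
        # identical up to label permutation
        table = np.zeros((a.k, b.k), dtype=int)
        for la, lb in zip(a.labels, b.labels):
            table[la, lb] += 1
        assert (table.max(axis=1).sum()) == len(a.labels)
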