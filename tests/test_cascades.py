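"""LN/STP cascades: closed forms, adaptation dynamics, analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dstrf.cascades import (CascadeModel, LnParams, StpParams, _CascadeFitState,
                            _stp_forward, double_exponential, fit_cascade,
                            stp_adaptation)
from dstrf.stimulus import make_windows, split_dataset
from dstrf.synth import generate_stimulus


class TestDoubleExponential:
    def test_saturation_limits(self):
        a, b, c, kappa = 2.0, -1.0, 0.3, 0.5
        assert double_exponential(60.0, a, b, c, kappa) == pytest.approx(b + a)
        assert double_exponential(-60.0, a, b, c, kappa) == pytest.approx(b)

    def test_value_at_inflection(self):
        a, b, c = 2.0, -1.0, 0.3
        assert double_exponential(c, a, b, c, 0.7) == pytest.approx(b + a / np.e)

    def test_monotone_for_positive_gain(self):
        x = np.linspace(-5, 5, 201)
        y = double_exponential(x, 1.5, 0.0, 0.0, 0.0)
        assert np.all(np.diff(y) > 0)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(-1e3, 1e3),
           a=st.floats(1e-3, 1e3), b=st.floats(-1e3, 1e3),
           c=st.floats(-100, 100), kappa=st.floats(-3, 3))
    def test_bounded_between_floor_and_saturation(self, x, a, b, c, kappa):
        y = float(double_exponential(x, a, b, c, kappa))
        assert b - 1e-9 * abs(b) <= y <= b + a + 1e-9 * (abs(b) + a)


class TestStpAdaptation:
    def test_zero_input_gives_zero_output(self):
        y = stp_adaptation(np.zeros((50, 4)), u=np.full(4, 0.5), tau=np.full(4, 10.0))
        np.testing.assert_array_equal(y, 0.0)

    def test_no_release_relaxes_geometrically(self):
        tau, d0, T = 8.0, 0.6, 30
        x = np.zeros((T, 1))
        d = _stp_forward(x, np.array([0.0]), np.array([tau]), d0)
        expected = d0 * (1 - 1 / tau) ** np.arange(T)
        np.testing.assert_allclose(d[:, 0], expected, rtol=1e-12)

    def test_constant_drive_reaches_fixed_point(self):
        u, tau, X = 0.3, 12.0, 1.7
        x = np.full((4000, 1), X)
        d = _stp_forward(x, np.array([u]), np.array([tau]), 0.0)
        # iteration oracle: run the recursion independently to convergence
        dd = 0.0
        for _ in range(4000):
            dd = dd + u * X * (1 - dd) - dd / tau
        assert d[-1, 0] == pytest.approx(dd, rel=1e-10)
        assert dd == pytest.approx(u * X * tau / (1 + u * X * tau), rel=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(u=st.floats(0.0, 1.0), tau=st.floats(1.0, 200.0),
           seed=st.integers(0, 1000))
    def test_gain_state_stays_bounded_for_unit_drive(self, u, tau, seed):
        """With u*x <= 1 the gain state is confined to [0, 1]."""
        x = np.abs(np.random.default_rng(seed).standard_normal((200, 1)))
        x /= x.max() + 1e-12
        d = _stp_forward(x, np.array([u]), np.array([tau]), 0.0)
        assert np.all(d >= -1e-12)
        assert np.all(d <= 1.0 + 1e-12)

    def test_causality(self, rng):
        x = np.abs(rng.standard_normal((100, 2)))
        y1 = stp_adaptation(x, u=[0.4, 0.2], tau=[5.0, 9.0])
        x2 = x.copy()
        x2[60:] += 1.0  # future change
        y2 = stp_adaptation(x2, u=[0.4, 0.2], tau=[5.0, 9.0])
        np.testing.assert_array_equal(y1[:60], y2[:60])

    def test_rejects_bad_parameters(self, rng):
        x = np.abs(rng.standard_normal((10, 1)))
        with pytest.raises(ValueError):
            stp_adaptation(x, u=[0.5], tau=[0.0])
        with pytest.raises(ValueError):
            stp_adaptation(-x - 0.1, u=[0.5], tau=[5.0])
        with pytest.raises(ValueError):
            StpParams(u=np.array([1.5]), tau=np.array([5.0]))


class TestCascadeModel:
    def _ln(self, rng, dexp=(1.0, 0.0, 0.0, 0.0)):
        return LnParams(
            centers=np.array([4.0, 10.0, 18.0, 26.0]),
            widths=np.full(4, 2.0),
            amps=rng.standard_normal(4) * 0.3,
            fir=rng.standard_normal((4, 40)) * 0.2,
            dexp=dexp,
        )

    def test_zero_amplitude_output_nonlinearity_is_constant(self, rng):
        ln = self._ln(rng, dexp=(0.0, 1.3, 0.0, 0.0))
        model = CascadeModel(ln=ln)
        spec = np.abs(rng.standard_normal((200, 32)))
        np.testing.assert_allclose(model.response(spec), 1.3)

    def test_stp_with_zero_u_matches_scaled_ln(self, rng):
        """With u = 0 the adaptation gate stays at d0 for ever, so the STP
        cascade equals the LN cascade with the drive scaled by d0."""
        ln = self._ln(rng)
        ln.amps = np.abs(ln.amps)  # keep the drive nonnegative
        spec = np.abs(rng.standard_normal((300, 32)))
        stp = StpParams(u=np.zeros(4), tau=np.full(4, 10.0), d0=1.0)
        with_stp = CascadeModel(ln=ln, stp=stp).response(spec)
        # d(t) decays from d0 by 1/tau each step; with tau -> inf it stays 1
        stp_inf = StpParams(u=np.zeros(4), tau=np.full(4, 1e9), d0=1.0)
        with_inf = CascadeModel(ln=ln, stp=stp_inf).response(spec)
        plain = CascadeModel(ln=ln).response(spec)
        np.testing.assert_allclose(with_inf, plain, rtol=1e-6, atol=1e-9)
        assert not np.allclose(with_stp, plain)

    def test_predict_aligns_with_response(self, rng):
        ln = self._ln(rng)
        model = CascadeModel(ln=ln)
        spec = np.abs(rng.standard_normal((120, 32)))
        ws = make_windows(spec, 40)
        pred = model.predict(ws)
        full = model.response(spec)
        np.testing.assert_allclose(pred, full[39:], atol=1e-12)


@pytest.mark.parametrize("variant", ["LN", "STP"])
def test_fit_state_gradients_match_finite_differences(rng, variant):
    """The hand-derived backward pass (including BPTT through the
    Tsodyks-Markram recursion) agrees with numerical differentiation."""
    s = np.abs(rng.standard_normal((60, 8))) * 0.5
    y = rng.standard_normal(60)
    mask = np.zeros(60, dtype=bool)
    mask[10:] = True
    state = _CascadeFitState(8, variant, rng, y_scale=1.0, y_mean=0.0)
    _, grads, _ = state.loss_and_grads(s, y, mask)
    eps = 1e-6
    for key in sorted(state.p):
        flat_idx = 0 if state.p[key].ndim == 0 else \
            tuple(np.unravel_index(state.p[key].size // 2, state.p[key].shape))
        orig = state.p[key][flat_idx]
        state.p[key][flat_idx] = orig + eps
        lp, _, _ = state.loss_and_grads(s, y, mask)
        state.p[key][flat_idx] = orig - eps
        lm, _, _ = state.loss_and_grads(s, y, mask)
        state.p[key][flat_idx] = orig
        fd = (lp - lm) / (2 * eps)
        assert np.asarray(grads[key])[flat_idx] == pytest.approx(fd, rel=2e-4, abs=1e-7), key


def test_ln_fit_recovers_separable_neuron():
    """Gradient fit on data from a rank-1 separable neuron reaches high
    held-out correlation and an output curve close to the generator's."""
    stim = generate_stimulus(40.0, seed=3)
    spec = stim.values
    f = np.arange(32)
    kernel = np.exp(-((f - 12.0) ** 2) / (2 * 2.5 ** 2))
    fir = np.zeros(40)
    fir[30:] = np.hanning(10)
    chan = spec @ kernel
    drive = np.convolve(chan, fir[::-1])[: spec.shape[0]]
    drive = (drive - drive.mean()) / drive.std()
    y = double_exponential(drive, 2.0, 0.1, 0.0, 0.3)
    split = split_dataset(spec, y, fractions=(0.85, 0.15))
    model, hist = fit_cascade(split, variant="LN", seed=0, max_iters=800)
    v0, v1 = split.validation
    pred = model.response(spec)[v0 + 39: v1]
    truth = y[v0 + 39: v1]
    assert np.corrcoef(pred, truth)[0, 1] > 0.9
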