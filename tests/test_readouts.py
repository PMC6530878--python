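"""Readouts: linking-hypothesis oracles and monotonicity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdbench.readouts import (SPARSE_RETAIN_FRAC, PsychometricFit, RawScore,
                                 apply_psychometric, decoder_accuracy,
                                 fit_psychometric, lr_difference,
                                 template_xcorr, to_threshold, train_decoder)


class TestLRDifference:
    def test_identical_outputs_score_zero(self, rng):
        img = rng.random((8, 8))
        assert lr_difference(img, img).value == pytest.approx(0.0)

    def test_disjoint_single_pixels_score_two(self):
        left = np.array([[1.0, 0.0], [0.0, 0.0]])
        right = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert lr_difference(left, right).value == pytest.approx(2.0)

    def test_scaling_invariance(self, rng):
        left, right = rng.random((6, 6)), rng.random((6, 6))
        base = lr_difference(left, right).value
        assert lr_difference(left, 5.0 * right).value == pytest.approx(base)

    def test_range(self, rng):
        for _ in range(20):
            v = lr_difference(rng.random((5, 5)), rng.random((5, 5))).value
            assert 0.0 <= v <= 2.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lr_difference(np.zeros((4, 4)), np.ones((4, 4)))


class TestTemplateXcorr:
    def test_self_correlation_is_one(self, rng):
        m = rng.random((8, 8))
        assert template_xcorr(m, m, max_shift=0).value == pytest.approx(1.0)

    def test_shift_recovered_within_window(self, rng):
        ref = rng.random((8, 8))
        shifted = np.roll(ref, 1, axis=1)
        assert template_xcorr(shifted, ref, max_shift=1).value == pytest.approx(1.0)
        assert template_xcorr(shifted, ref, max_shift=0).value < 0.9

    def test_disjoint_supports_near_zero(self):
        a = np.zeros((8, 8)); a[1, 1] = 1.0
        b = np.zeros((8, 8)); b[6, 6] = 1.0
        assert abs(template_xcorr(a, b, max_shift=0).value) < 0.1

    def test_intensity_scaling_invariance(self, rng):
        out, ref = rng.random((8, 8)), rng.random((8, 8))
        v1 = template_xcorr(out, ref).value
        v2 = template_xcorr(7.0 * out, ref).value
        assert v1 == pytest.approx(v2)

    def test_multichannel_sum(self, rng):
        m = rng.random((3, 8, 8))
        assert template_xcorr(m, m, max_shift=0,
                              reduce="sum").value == pytest.approx(3.0)

    def test_zero_variance_channel_scores_zero(self, rng):
        ref = rng.random((2, 6, 6))
        out = np.stack([np.full((6, 6), 0.5), rng.random((6, 6))])
        v = template_xcorr(out, ref, max_shift=0, reduce="sum").value
        assert v <= 1.0


class TestToThreshold:
    def test_reciprocal(self):
        assert to_threshold(RawScore(2.0, "xcorr"), scale=1.0).value == 0.5

    def test_doubling_raw_halves_threshold(self):
        t1 = to_threshold(1.5).value
        t2 = to_threshold(3.0).value
        assert t2 == pytest.approx(t1 / 2)

    def test_u_shape_preserved_inverted(self):
        raws = (3.0, 1.0, 2.0)
        ts = [to_threshold(r).value for r in raws]
        assert np.argmax(ts) == np.argmin(raws)

    def test_zero_raw_hits_ceiling(self):
        assert to_threshold(0.0, ceiling=123.0).value == 123.0


class TestPsychometric:
    def test_exact_recovery(self):
        c = np.array([0.5, 1.0, 2.0, 4.0])
        t = 2.0 * c ** -1.0
        fit = fit_psychometric(c, t)
        assert fit.a == pytest.approx(2.0, rel=1e-6)
        assert fit.b == pytest.approx(-1.0, rel=1e-6)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_psychometric([1.0], [2.0])

    def test_noisy_recovery_within_ten_percent(self, rng):
        c = rng.uniform(0.5, 5.0, size=20)
        t = 3.0 * c ** -1.5 * np.exp(rng.normal(0, 0.05, size=20))
        fit = fit_psychometric(c, t)
        assert fit.a == pytest.approx(3.0, rel=0.1)
        assert fit.b == pytest.approx(-1.5, rel=0.1)

    def test_positive_exponent_warns(self):
        with pytest.warns(UserWarning):
            fit_psychometric([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_apply_is_decreasing(self):
        fit = PsychometricFit(a=2.0, b=-1.2)
        vals = [apply_psychometric(fit, c).value for c in (0.5, 1.0, 2.0)]
        assert vals[0] > vals[1] > vals[2]


def _shape_class(triple):
    """monotone-increasing / monotone-decreasing / U / inverted-U."""
    a, b, c = triple
    if a <= b <= c:
        return "inc"
    if a >= b >= c:
        return "dec"
    return "U" if b < min(a, c) else "invU"


@given(st.tuples(*[st.floats(0.05, 50.0) for _ in range(3)])
       .filter(lambda t: min(abs(a - b) for a, b in
                             [(t[0], t[1]), (t[1], t[2]), (t[0], t[2])]) > 1e-3))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_order_reversal_never_order_destruction(raws):
    """Monotone raw triples map onto monotone threshold triples and U-shapes
    onto inverted-U (and vice versa): readouts cannot confuse crowding with
    uncrowding."""
    flip = {"inc": "dec", "dec": "inc", "U": "invU", "invU": "U"}
    ts = [to_threshold(r).value for r in raws]
    assert _shape_class(ts) == flip[_shape_class(raws)]
    fit = PsychometricFit(a=1.7, b=-0.8)
    ps = [apply_psychometric(fit, r).value for r in raws]
    assert _shape_class(ps) == flip[_shape_class(raws)]


class TestDecoder:
    @staticmethod
    def _toy(rng, n=120, d=12, margin=1.0):
        w = rng.normal(size=d)
        X = rng.normal(size=(n, d))
        y = np.where(X @ w > 0, "left", "right")
        X += margin * np.outer(np.where(y == "left", 1.0, -1.0), w) / np.linalg.norm(w)
        return X, y, w

    def test_linearly_separable_perfect(self, rng):
        X, y, w = self._toy(rng, margin=3.0)
        # independent separability check: a hyperplane classifies perfectly
        assert np.all(np.where(X @ w > 0, "left", "right") == y)
        dec = train_decoder(X, y, hidden_units=32, seed=0)
        assert decoder_accuracy(dec, X, y).value == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self, rng):
        X, y, _ = self._toy(rng, n=200)
        y_shuf = rng.permutation(y)
        dec = train_decoder(X, y_shuf, hidden_units=16, seed=0)
        X_test, y_test, _ = self._toy(rng, n=400)
        acc = decoder_accuracy(dec, X_test, y_test).value
        # binomial noise at n=400: 0.5 +- ~4 sigma
        assert abs(acc - 0.5) < 0.12

    def test_sparse_readout_never_better(self, rng):
        X, y, _ = self._toy(rng, n=200, d=40, margin=1.0)
        Xt, yt, _ = self._toy(rng, n=200, d=40, margin=1.0)
        full = decoder_accuracy(train_decoder(X, y, 16, 1.0, seed=3), X, y).value
        sparse = decoder_accuracy(
            train_decoder(X, y, 16, SPARSE_RETAIN_FRAC, seed=3), X, y).value
        assert sparse <= full + 1e-9

    def test_sparse_mask_size(self, rng):
        X, y, _ = self._toy(rng, d=40)
        dec = train_decoder(X, y, hidden_units=8, retain_frac=0.25, seed=0)
        assert dec.retained.size == 10

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            train_decoder(X, ["left"] * 10)
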