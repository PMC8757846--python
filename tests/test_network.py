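"""Forward pass, scaling, fixed-point emulation, model persistence."""

import json

import numpy as np
import pytest

from idpcg.activation import ActivationSpec, arctanh_taylor, taylor_error_bound
from idpcg.network import (
    FeatureScaler,
    FixedPointFormat,
    MLPModel,
    ModelFormatError,
    classify,
    forward,
    forward_fixed,
    forward_settled,
    load_model,
    mse,
    quantize_model,
    regression_r,
    save_model,
)


def random_model(rng, ni=6, nh=12, no=5, scale=0.5, act=None):
    return MLPModel(
        W_hidden=rng.uniform(-scale, scale, (nh, ni)),
        b_hidden=rng.uniform(-scale, scale, nh),
        W_out=rng.uniform(-scale, scale, (no, nh)),
        b_out=rng.uniform(-scale, scale, no),
        act=act or ActivationSpec(),
    )


class TestScaler:
    def test_endpoints_and_midpoint(self):
        sc = FeatureScaler().fit(np.array([[1.0, 10.0], [3.0, 30.0]]))
        z = sc.transform(np.array([[1.0, 20.0]]))
        assert z[0, 0] == pytest.approx(-1.0)
        assert z[0, 1] == pytest.approx(0.0)

    def test_roundtrip(self, rng):
        X = rng.normal(size=(20, 6))
        sc = FeatureScaler().fit(X)
        assert np.allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-12)

    def test_out_of_range_clamped(self):
        sc = FeatureScaler().fit(np.array([[0.0], [1.0]]))
        assert sc.transform(np.array([[5.0]]))[0, 0] == 1.0

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError):
            FeatureScaler().transform(np.zeros((1, 6)))


class TestForward:
    def test_zero_network_zero_scores(self):
        m = MLPModel(
            W_hidden=np.zeros((12, 6)), b_hidden=np.zeros(12),
            W_out=np.zeros((5, 12)), b_out=np.zeros(5),
        )
        assert np.allclose(forward(m, np.ones(6)), 0.0)

    def test_hand_computed_single_hidden_unit(self):
        # 2 -> 1 -> 1 with act(z) = z + z^3/3 (no clamping in range)
        m = MLPModel(
            W_hidden=np.array([[0.3, -0.2]]), b_hidden=np.array([0.1]),
            W_out=np.array([[0.5]]), b_out=np.array([-0.05]),
        )
        f = np.array([0.4, 0.6])
        z1 = 0.3 * 0.4 - 0.2 * 0.6 + 0.1
        h = z1 + z1**3 / 3
        z2 = 0.5 * h - 0.05
        y = z2 + z2**3 / 3
        assert forward(m, f)[0] == pytest.approx(y, abs=1e-12)

    def test_hidden_permutation_invariance(self, rng):
        m = random_model(rng)
        perm = rng.permutation(12)
        m2 = MLPModel(
            W_hidden=m.W_hidden[perm], b_hidden=m.b_hidden[perm],
            W_out=m.W_out[:, perm], b_out=m.b_out, act=m.act,
        )
        f = rng.uniform(-1, 1, 6)
        assert np.allclose(forward(m, f), forward(m2, f), atol=1e-12)

    def test_scores_inside_open_interval(self, rng):
        m = random_model(rng, scale=3.0)
        y = forward(m, rng.uniform(-1, 1, (50, 6)))
        assert np.all(np.abs(y) < 1.0)

    def test_truncated_vs_exact_within_propagated_remainder(self, rng):
        """With all pre-activations inside [-0.5, 0.5], the cubic and exact
        activations may differ per unit by at most the series remainder;
        the output difference is bounded by propagating that remainder
        through the output layer with the activation's Lipschitz constant."""
        small = random_model(rng, scale=0.07)  # keeps |z| <= ~0.5
        exact = MLPModel(
            W_hidden=small.W_hidden, b_hidden=small.b_hidden,
            W_out=small.W_out, b_out=small.b_out,
            act=ActivationSpec(form="exact_arctanh"),
        )
        for _ in range(20):
            f = rng.uniform(-1, 1, 6)
            z1 = small.W_hidden @ f + small.b_hidden
            assert np.all(np.abs(z1) <= 0.5)
            dh = np.asarray(taylor_error_bound(z1))
            z2 = np.asarray(arctanh_taylor(z1)) @ small.W_out.T + small.b_out
            assert np.all(np.abs(z2) <= 0.5)
            lipschitz = 1.0 / (1.0 - 0.6**2)  # exact-act slope bound near |z|<=0.6
            bound = np.asarray(taylor_error_bound(z2)) + lipschitz * (np.abs(small.W_out) @ dh)
            diff = np.abs(forward(small, f) - forward(exact, f))
            assert np.all(diff <= bound + 1e-12)

    def test_settled_inference_reaches_dynamical_fixed_point(self, rng):
        # at the settled state g(x) = u; with K = 0, g = arctanh, so each
        # layer's output is tanh of its weighted-sum drive
        m = random_model(rng, scale=0.3, act=ActivationSpec(form="exact_arctanh"))
        f = rng.uniform(-0.8, 0.8, 6)
        settled = forward_settled(m, f, tol=1e-8)
        hidden = np.tanh(m.W_hidden @ f + m.b_hidden)
        expected = np.tanh(m.W_out @ hidden + m.b_out)
        assert np.allclose(settled, expected, atol=1e-4)


class TestClassify:
    def test_argmax_and_tie_break(self):
        scores = np.array([0.9, -0.8, -0.8, -0.8, -0.8])
        assert int(np.argmax(scores)) == 0
        m = MLPModel(
            W_hidden=np.zeros((12, 6)), b_hidden=np.zeros(12),
            W_out=np.zeros((5, 12)), b_out=np.zeros(5),
        )
        # all five scores exactly tie at 0 -> lowest index wins
        assert classify(m, np.ones(6)) == 0

    def test_matches_exhaustive_score_comparison(self, rng):
        m = random_model(rng)
        F = rng.uniform(-1, 1, (30, 6))
        scores = forward(m, F)
        got = classify(m, F)
        for i in range(30):
            best = 0
            for k in range(1, 5):
                if scores[i, k] > scores[i, best]:
                    best = k
            assert got[i] == best


class TestFixedPoint:
    FMT = FixedPointFormat(word_bits=32, frac_bits=24)

    def test_format_validation(self):
        with pytest.raises(ValueError):
            FixedPointFormat(word_bits=8, frac_bits=8)

    def test_zero_weights_unchanged(self):
        m = MLPModel(
            W_hidden=np.zeros((2, 2)), b_hidden=np.zeros(2),
            W_out=np.zeros((1, 2)), b_out=np.zeros(1),
        )
        q = quantize_model(m, self.FMT)
        assert np.all(q.W_hidden == 0) and np.all(q.b_out == 0)

    def test_representable_value_roundtrips(self):
        assert self.FMT.quantize(0.5) == 0.5
        assert self.FMT.quantize(-0.25) == -0.25

    def test_saturation(self):
        big = self.FMT.max_val + 10
        assert self.FMT.quantize(big) == self.FMT.max_val
        with pytest.raises(OverflowError):
            self.FMT.quantize(big, saturate=False)

    def test_fixed_scores_close_to_float(self, rng):
        m = random_model(rng)
        q = quantize_model(m, self.FMT)
        F = rng.uniform(-1, 1, (500, 6))
        delta = np.abs(forward_fixed(q, F, self.FMT) - forward(m, F))
        assert delta.max() <= 1e-3

    def test_labels_essentially_unchanged(self, rng):
        m = random_model(rng)
        q = quantize_model(m, self.FMT)
        F = rng.uniform(-1, 1, (1000, 6))
        lab_f = np.argmax(forward(m, F), axis=1)
        lab_q = np.argmax(forward_fixed(q, F, self.FMT), axis=1)
        assert np.mean(lab_f == lab_q) >= 0.995


class TestPersistence:
    def test_roundtrip(self, rng, tmp_path):
        m = random_model(rng)
        m.scaler = FeatureScaler().fit(rng.normal(size=(10, 6)))
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        assert np.array_equal(m.W_hidden, m2.W_hidden)
        assert np.array_equal(m.b_out, m2.b_out)
        assert m2.act == m.act
        assert np.array_equal(m.scaler.mins, m2.scaler.mins)

    def test_missing_field_named(self, rng, tmp_path):
        m = random_model(rng)
        path = tmp_path / "model.json"
        save_model(m, path)
        doc = json.loads(path.read_text())
        del doc["W_out"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="W_out"):
            load_model(path)

    def test_version_mismatch_refused(self, rng, tmp_path):
        m = random_model(rng)
        path = tmp_path / "model.json"
        save_model(m, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)


class TestFitMetrics:
    def test_identity_and_anticorrelation(self, rng):
        v = rng.normal(size=40)
        assert mse(v, v) == 0.0
        assert regression_r(v, v) == pytest.approx(1.0)
        z = v - v.mean()
        assert regression_r(-z, z) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        p = rng.normal(size=25)
        t = rng.normal(size=25)
        n = 25
        sp = np.sqrt(sum((x - p.mean()) ** 2 for x in p) / n)
        st_ = np.sqrt(sum((x - t.mean()) ** 2 for x in t) / n)
        r_oracle = sum((a - p.mean()) * (b - t.mean()) for a, b in zip(p, t)) / (n * sp * st_)
        mse_oracle = sum((a - b) ** 2 for a, b in zip(p, t)) / n
        assert regression_r(p, t) == pytest.approx(r_oracle, abs=1e-12)
        assert mse(p, t) == pytest.approx(mse_oracle, abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            regression_r(np.ones(5), np.arange(5.0))
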