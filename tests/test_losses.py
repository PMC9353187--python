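"""Loss oracles: independent numeric evaluation, identities, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, rel_entr, xlogy

from cpgfill.losses import (LossConfig, binarize, kl_divergence, logistic_loss,
                            mse_loss, multi_task_loss,
                            multi_task_weight_matrix, per_site_loss,
                            per_site_loss_grad, sample_weights)

RNG = np.random.default_rng(2024)


def grid_points(n=100):
    y = RNG.random(n)
    yhat = RNG.uniform(0.01, 0.99, n)
    return y, yhat


class TestKL:
    def test_matches_rel_entr_oracle_on_grid(self):
        y, yhat = grid_points()
        ours = kl_divergence(y, yhat)
        oracle = rel_entr(y, yhat) + rel_entr(1 - y, 1 - yhat)
        assert np.max(np.abs(ours - oracle)) < 1e-9

    def test_identical_distributions_zero(self):
        assert kl_divergence(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_binary_label_value(self):
        assert kl_divergence(1.0, 0.5) == pytest.approx(np.log(2), abs=1e-12)

    def test_near_binary_example(self):
        # independent evaluation: 0.99 log(0.99/0.51) + 0.01 log(0.01/0.49)
        expected = 0.99 * np.log(0.99 / 0.51) + 0.01 * np.log(0.01 / 0.49)
        assert kl_divergence(0.99, 0.51) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.6177, abs=5e-4)

    def test_nonnegative_with_equality_iff_equal(self):
        ys = np.linspace(0, 1, 21)
        qs = np.linspace(0.02, 0.98, 25)
        for y in ys:
            vals = kl_divergence(np.full_like(qs, y), qs)
            assert (vals >= -1e-15).all()
            if 0.02 <= y <= 0.98:
                at_y = kl_divergence(y, y)
                assert at_y == pytest.approx(0.0, abs=1e-12)
                assert (vals[np.abs(qs - y) > 1e-6] > 0).all()

    def test_label_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(1.2, 0.5)


class TestLogistic:
    def test_matches_xlogy_oracle_on_grid(self):
        y = (RNG.random(100) > 0.5).astype(float)
        yhat = RNG.uniform(0.01, 0.99, 100)
        ours = logistic_loss(y, yhat)
        oracle = -(xlogy(y, yhat) + xlogy(1 - y, 1 - yhat))
        assert np.max(np.abs(ours - oracle)) < 1e-9

    @pytest.mark.parametrize("y,yhat,expected", [
        (1.0, 0.5, np.log(2)),
        (0.0, 0.9, -np.log(0.1)),
    ])
    def test_reference_values(self, y, yhat, expected):
        assert logistic_loss(y, yhat) == pytest.approx(expected, abs=1e-9)

    def test_perfect_prediction_approaches_zero(self):
        # clipping at epsilon floors the loss near -log(1 - eps)
        assert logistic_loss(1.0, 1.0 - 1e-9) < 1e-5

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binar"):
            logistic_loss(0.7, 0.5)

    def test_kl_equals_logistic_for_binary_labels(self):
        y = (RNG.random(200) > 0.3).astype(float)
        yhat = RNG.uniform(0.01, 0.99, 200)
        np.testing.assert_array_equal(kl_divergence(y, yhat),
                                      logistic_loss(y, yhat))


class TestMSE:
    @pytest.mark.parametrize("y,yhat,expected", [
        (0.3, 0.3, 0.0), (1.0, 0.5, 0.25), (0.2, 0.7, 0.25)])
    def test_values(self, y, yhat, expected):
        assert mse_loss(y, yhat) == pytest.approx(expected, abs=1e-12)

    def test_sigmoid_variant_squashes_raw_score(self):
        assert mse_loss(0.5, 0.0, with_sigmoid=True) == pytest.approx(0.0)
        assert mse_loss(1.0, 3.0, with_sigmoid=True) == \
            pytest.approx((1 - expit(3.0)) ** 2)


class TestBinarize:
    @pytest.mark.parametrize("y,expected", [(0.51, 1), (0.5, 0), (0.0, 0)])
    def test_strict_threshold(self, y, expected):
        assert binarize(y) == expected


class TestGradients:
    @pytest.mark.parametrize("kind", ["logistic", "kl", "mse", "mse_sigmoid"])
    def test_analytic_matches_central_differences(self, kind):
        rng = np.random.default_rng(5)
        y = ((rng.random(40) > 0.5).astype(float) if kind == "logistic"
             else rng.random(40))
        yhat = rng.uniform(0.05, 0.95, 40)
        ana = per_site_loss_grad(kind, y, yhat)
        h = 1e-7
        num = (per_site_loss(kind, y, yhat + h)
               - per_site_loss(kind, y, yhat - h)) / (2 * h)
        assert np.max(np.abs(ana - num)) < 1e-5


class TestMultiTask:
    def test_hand_summed_example(self):
        # two tasks, one missing entry; sum reduction, unit weights
        L = np.array([[0.2, 0.0], [0.4, 0.6]])
        mask = np.array([[True, False], [True, True]])
        cfg = LossConfig(reduction="sum", sample_weight_scheme="uniform")
        assert multi_task_loss(L, mask, cfg) == pytest.approx(1.2)

    def test_zero_task_weight_silences_task(self):
        L = np.array([[0.2, 0.7], [0.4, 0.6]])
        mask = np.ones((2, 2), dtype=bool)
        cfg = LossConfig(reduction="sum", sample_weight_scheme="uniform",
                         task_weights=np.array([0.0, 1.0]))
        assert multi_task_loss(L, mask, cfg) == pytest.approx(1.3)

    def test_weights_scale_linearly(self):
        L = np.abs(RNG.normal(size=(6, 2)))
        mask = RNG.random((6, 2)) > 0.3
        cfg = LossConfig(reduction="sum", sample_weight_scheme="uniform")
        base = multi_task_loss(L, mask, cfg, weights=np.ones((6, 2)))
        doubled = multi_task_loss(L, mask, cfg, weights=2 * np.ones((6, 2)))
        assert doubled == pytest.approx(2 * base)

    def test_task_permutation_invariance(self):
        L = np.abs(RNG.normal(size=(8, 3)))
        mask = RNG.random((8, 3)) > 0.2
        alpha = np.array([0.5, 1.0, 2.0])
        beta = np.abs(RNG.normal(size=(8, 3))) + 0.1
        cfg = LossConfig(reduction="sum", task_weights=alpha)
        base = multi_task_loss(L, mask, cfg, weights=beta)
        perm = [2, 0, 1]
        cfgp = LossConfig(reduction="sum", task_weights=alpha[perm])
        permuted = multi_task_loss(L[:, perm], mask[:, perm], cfgp,
                                   weights=beta[:, perm])
        assert permuted == pytest.approx(base)

    def test_all_masked_batch_is_zero(self):
        L = np.ones((3, 2))
        mask = np.zeros((3, 2), dtype=bool)
        assert multi_task_loss(L, mask, LossConfig()) == 0.0

    def test_inverse_frequency_weights_sum_to_count(self):
        labels = RNG.random((50, 2))
        mask = RNG.random((50, 2)) > 0.3
        w = sample_weights(labels, mask, LossConfig())
        for j in range(2):
            nj = mask[:, j].sum()
            assert w[mask[:, j], j].sum() == pytest.approx(nj)

    def test_weight_matrix_is_loss_gradient(self):
        L = np.abs(RNG.normal(size=(5, 2)))
        mask = RNG.random((5, 2)) > 0.2
        cfg = LossConfig(reduction="mean", sample_weight_scheme="uniform")
        W = multi_task_weight_matrix(L.shape, mask, cfg)
        assert multi_task_loss(L, mask, cfg) == pytest.approx(
            (W * np.where(mask, L, 0)).sum())


class TestPropertyInvariants:
    """Hypothesis-driven invariants over the loss functions."""

    @given(y=st.floats(0.0, 1.0), q=st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kl_nonnegative_and_zero_at_truth(self, y, q):
        assert kl_divergence(y, q) >= -1e-12
        if 0.01 <= y <= 0.99:
            assert kl_divergence(y, y) <= 1e-12

    @given(y=st.floats(0.0, 1.0), q=st.floats(0.01, 0.99),
           t=st.floats(0.05, 0.95))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_binarize_is_idempotent_and_monotone(self, y, q, t):
        b = binarize(y, t)
        assert binarize(b, 0.5) == b
        assert b in (0.0, 1.0)
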