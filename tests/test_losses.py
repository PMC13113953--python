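import numpy as np
import pytest

from edgeunet.autodiff import Tensor
from edgeunet.losses import (LossWeights, bce, boundary_dice, bso_loss,
                             lambda_sensitivity_sweep, multitask_loss,
                             weighted_bce)

LN2 = float(np.log(2.0))


def make_bdice_case():
    """Inside Mb: sum(y)=4, sum(p)=3, sum(y*p)=2 -> loss 1 - 4/7."""
    y = np.array([1, 1, 1, 1, 0, 0, 0], float)
    p = np.array([1, 1, 0, 0, 1, 0, 0], float)
    mb = np.ones(7)
    return y, p, mb


class TestWeightedBCE:
    def test_hand_evaluated_micro_examples(self):
        assert weighted_bce(np.array([1.0]), np.array([0.5]), 2.5) == \
            pytest.approx(2.5 * LN2, abs=1e-6)
        assert weighted_bce(np.array([0.0]), np.array([0.5]), 2.5) == \
            pytest.approx(LN2, abs=1e-6)

    def test_perfect_prediction_is_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert weighted_bce(y, y, 2.5) <= 1e-5

    def test_beta_one_equals_plain_bce_oracle(self, rng):
        y = (rng.random(50) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, 50)
        oracle = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert weighted_bce(y, p, beta=1.0) == pytest.approx(oracle, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(np.zeros(3), np.zeros(4))


class TestBoundaryDice:
    def test_hand_evaluated_micro_example(self):
        y, p, mb = make_bdice_case()
        assert boundary_dice(y, p, mb) == pytest.approx(1 - 4 / 7, abs=1e-6)

    def test_perfect_overlap_is_zero_and_disjoint_is_one(self):
        y = np.array([1.0, 1, 0, 0])
        mb = np.ones(4)
        assert boundary_dice(y, y, mb) == pytest.approx(0.0, abs=1e-6)
        assert boundary_dice(y, 1 - y, mb) == pytest.approx(1.0, abs=1e-5)

    def test_invariant_to_predictions_outside_band(self, rng):
        y = (rng.random((8, 8)) < 0.5).astype(float)
        mb = np.zeros((8, 8))
        mb[2:6, 2:6] = 1
        p = rng.random((8, 8))
        p2 = p.copy()
        p2[mb == 0] = rng.random((mb == 0).sum())
        assert boundary_dice(y, p, mb) == pytest.approx(
            boundary_dice(y, p2, mb), abs=1e-12)

    def test_permutation_equivariance_within_band_strata(self, rng):
        y = (rng.random(20) < 0.5).astype(float)
        p = rng.random(20)
        mb = (rng.random(20) < 0.6).astype(float)
        inside = np.flatnonzero(mb == 1)
        perm = rng.permutation(inside)
        y2, p2 = y.copy(), p.copy()
        y2[inside], p2[inside] = y[perm], p[perm]
        assert boundary_dice(y, p, mb) == pytest.approx(
            boundary_dice(y2, p2, mb), abs=1e-12)


class TestBSOLoss:
    def test_composition_of_hand_examples(self):
        # one pixel in-band contributing the wBCE value 2.5*ln2 is mixed
        # with the bDice case to the lambda-weighted total
        y, p, mb = make_bdice_case()
        expected = 0.6 * weighted_bce(y, p) + 0.4 * (1 - 4 / 7)
        assert bso_loss(y, p, mb) == pytest.approx(expected, abs=1e-6)
        known = 0.6 * 2.5 * LN2 + 0.4 * (1 - 4 / 7)
        assert 0.6 * weighted_bce(np.array([1.0]), np.array([0.5])) + \
            0.4 * boundary_dice(y, p, mb) == pytest.approx(known, abs=1e-6)

    def test_degenerate_weights_reduce_to_wbce(self, rng):
        y = (rng.random(30) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, 30)
        mb = np.ones(30)
        w = LossWeights(lambda1=1.0, lambda2=0.0)
        assert bso_loss(y, p, mb, w) == pytest.approx(
            weighted_bce(y, p, w.beta), abs=1e-12)

    def test_tensor_and_numpy_paths_agree(self, rng):
        y = (rng.random((6, 6)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (6, 6))
        mb = (rng.random((6, 6)) < 0.7).astype(float)
        t = bso_loss(y, Tensor(p.astype(np.float32)), mb)
        assert t.item() == pytest.approx(bso_loss(y, p, mb), abs=1e-5)

    def test_autodiff_gradient_matches_finite_differences(self, rng):
        y = (rng.random((8, 8)) < 0.5).astype(float)
        mb = (rng.random((8, 8)) < 0.6).astype(float)
        p0 = rng.uniform(0.1, 0.9, (8, 8))
        pt = Tensor(p0.astype(np.float32), requires_grad=True)
        bso_loss(y, pt, mb).backward()
        eps = 1e-4
        num = np.zeros_like(p0)
        it = np.nditer(p0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            pp = p0.copy(); pp[i] += eps
            pm = p0.copy(); pm[i] -= eps
            num[i] = (bso_loss(y, pp, mb) - bso_loss(y, pm, mb)) / (2 * eps)
        assert np.abs(num - pt.grad).max() < 1e-4


class TestMultitaskLoss:
    def test_no_auxiliary_heads_equals_bso(self, rng):
        y = (rng.random((6, 6)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (6, 6))
        mb = np.ones((6, 6))
        total, breakdown = multitask_loss(
            {"seg": p}, {"mask": y, "boundary_band": mb})
        assert total == pytest.approx(bso_loss(y, p, mb), abs=1e-12)
        assert breakdown["aux"] == 0.0

    def test_alpha_zero_ignores_auxiliary_predictions(self, rng):
        y = (rng.random((8, 8)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (8, 8))
        mb = np.ones((8, 8))
        taux = (rng.random((4, 4)) < 0.5).astype(float)
        preds = {"seg": p, "boundary": {2: rng.random((4, 4))}}
        targets = {"mask": y, "boundary_band": mb, "boundary": {2: taux}}
        w = LossWeights(alpha_aux=0.0)
        total, _ = multitask_loss(preds, targets, w)
        assert total == pytest.approx(bso_loss(y, p, mb, w), abs=1e-12)

    def test_two_heads_compose_arithmetically(self, rng):
        y = (rng.random((8, 8)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (8, 8))
        mb = np.ones((8, 8))
        t1 = (rng.random((4, 4)) < 0.5).astype(float)
        t2 = (rng.random((2, 2)) < 0.5).astype(float)
        p1, p2 = rng.random((4, 4)), rng.random((2, 2))
        preds = {"seg": p, "boundary": {2: p1}, "edge": {4: p2}}
        targets = {"mask": y, "boundary_band": mb,
                   "boundary": {2: t1}, "edge": {4: t2}}
        total, breakdown = multitask_loss(preds, targets)
        expected = bso_loss(y, p, mb) + 0.2 * bce(t1, p1) + 0.2 * bce(t2, p2)
        assert total == pytest.approx(expected, abs=1e-10)
        assert breakdown["total"] == pytest.approx(
            breakdown["seg_total"] + breakdown["aux"], abs=1e-10)

    def test_missing_target_for_declared_head_raises(self, rng):
        y = np.zeros((4, 4))
        preds = {"seg": np.full((4, 4), 0.5), "boundary": {2: np.zeros((2, 2))}}
        targets = {"mask": y, "boundary_band": np.ones((4, 4))}
        with pytest.raises(ValueError, match="missing boundary target"):
            multitask_loss(preds, targets)


class TestLossWeights:
    def test_default_weight_values(self):
        w = LossWeights()
        assert (w.beta, w.lambda1, w.lambda2, w.epsilon) == (2.5, 0.6, 0.4, 1e-6)

    @pytest.mark.parametrize("kwargs", [
        {"lambda1": 0.8, "lambda2": 0.4},
        {"epsilon": 0.01},
        {"beta": -1.0},
    ])
    def test_invalid_weights_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossWeights(**kwargs)


class TestLambdaSweep:
    def test_row_per_grid_value_and_reproducibility(self):
        calls = []

        def fake_train(w):
            calls.append(w.lambda1)
            return {"dice": 0.9 - w.lambda1 * 0.01, "iou": 0.8, "hd95": 2.0}

        table = lambda_sensitivity_sweep(fake_train, [0.5])
        assert len(table) == 1
        table = lambda_sensitivity_sweep(fake_train, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert len(table) == 5
        assert np.allclose(table["lambda1"] + table["lambda2"], 1.0)
        again = lambda_sensitivity_sweep(fake_train, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert table.equals(again)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            lambda_sensitivity_sweep(lambda w: {}, [])
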