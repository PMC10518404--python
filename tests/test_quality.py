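"""Quality regressors: fitting contracts, prediction, selection, calibration."""

import hashlib

import numpy as np
import pytest

from qcdseg import agreement_matrix, build_candidate_set, dice, \
    fit_quality_model, predict_quality, select_best
from qcdseg.fusion import AgreementMatrix
from qcdseg.quality import DiceRegressorBank
from qcdseg.perturb import perturbation_pool


def ring(shift=0, grid=24):
    yy, xx = np.mgrid[0:grid, 0:grid]
    d = np.sqrt((yy - grid / 2 - shift) ** 2 + (xx - grid / 2) ** 2)
    return ((d >= 5) & (d < 9)).astype(np.uint8)


def triples_from_masks(scs_per_image, gts):
    out = []
    for scs, gt in zip(scs_per_image, gts):
        cs = build_candidate_set(scs)
        out.append((cs, agreement_matrix(cs), gt))
    return out


class TestFitting:
    def test_constant_fit_degenerate(self):
        """All candidates equal to ground truth: features and targets are all
        1; prediction on the all-ones matrix is 1 within 1e-6."""
        gt = ring()
        triples = triples_from_masks([[gt.copy() for _ in range(3)]] * 4,
                                     [gt] * 4)
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_quality_model(triples)
        preds = predict_quality(model, triples[0][1])
        assert np.allclose(preds, 1.0, atol=1e-6)

    def test_sample_duplication_leaves_ols_weights_unchanged(self):
        pool = perturbation_pool(20, seed=3, n_scs=3, grid_size=32)
        mats = [p.matrix for p in pool]
        targets = np.asarray([p.true_dice for p in pool])
        m1 = DiceRegressorBank().fit(mats, targets)
        m2 = DiceRegressorBank().fit(mats + mats,
                                     np.concatenate([targets, targets]))
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-8)
        assert np.allclose(m1.intercept_, m2.intercept_, atol=1e-8)

    def test_inconsistent_candidate_count_rejected(self):
        p3 = perturbation_pool(8, seed=1, n_scs=3, grid_size=32)
        p4 = perturbation_pool(8, seed=1, n_scs=4, grid_size=32)
        mats = [p.matrix for p in p3] + [p4[0].matrix]
        targets = np.zeros((9, 6))
        with pytest.raises(ValueError, match="ordering|candidate"):
            DiceRegressorBank().fit(mats, targets)


class TestPrediction:
    def test_predictions_clipped_to_unit_interval(self):
        pool = perturbation_pool(30, seed=5, n_scs=3, grid_size=32)
        model = DiceRegressorBank().fit(
            [p.matrix for p in pool],
            np.asarray([p.true_dice for p in pool]))
        for p in pool[:10]:
            preds = model.predict(p.matrix)
            assert np.all((preds >= 0) & (preds <= 1))

    def test_ordering_hash_mismatch_is_an_error(self):
        pool = perturbation_pool(30, seed=5, n_scs=3, grid_size=32)
        model = DiceRegressorBank().fit(
            [p.matrix for p in pool],
            np.asarray([p.true_dice for p in pool]))
        scrambled = AgreementMatrix(values=pool[0].matrix.values,
                                    ordering_hash="deadbeefdeadbeef")
        with pytest.raises(ValueError, match="ordering"):
            model.predict(scrambled)

    def test_prediction_never_consults_ground_truth(self):
        """predict_quality's inputs are the fitted model and the agreement
        matrix only — the interface admits no ground truth."""
        import inspect
        params = inspect.signature(predict_quality).parameters
        assert list(params) == ["model", "matrix"]


class TestSelection:
    def test_argmax_and_pass_flag(self):
        res = select_best(np.array([0.6, 0.9, 0.7]))
        assert res.selected_index == 1
        assert res.predicted_dsc == pytest.approx(0.9)
        assert res.pass_flag

    def test_tie_breaks_to_lowest_index(self):
        res = select_best(np.array([0.8, 0.8, 0.8]))
        assert res.selected_index == 0

    def test_below_threshold_fails(self):
        assert not select_best(np.array([0.5, 0.65])).pass_flag

    def test_false_positive_outcome(self):
        """Predicted >= 0.7 but observed < 0.7 is a false positive."""
        gt = ring()
        bad = ring(shift=6)  # overlaps gt poorly
        cs = build_candidate_set([bad, bad.copy()])
        assert dice(bad, gt) < 0.7
        res = select_best(np.array([0.8, 0.75]), candidates=cs,
                          ground_truth=gt)
        assert res.outcome == "FP"

    def test_false_negative_outcome(self):
        gt = ring()
        cs = build_candidate_set([gt.copy(), gt.copy()])
        res = select_best(np.array([0.65, 0.6]), candidates=cs,
                          ground_truth=gt)
        assert res.observed_dsc == 1.0
        assert res.outcome == "FN"

    def test_true_outcomes(self):
        gt = ring()
        cs = build_candidate_set([gt.copy(), ring(shift=6)])
        assert select_best(np.array([0.9, 0.1]), candidates=cs,
                           ground_truth=gt).outcome == "TP"
        assert select_best(np.array([0.2, 0.1]),
                           candidates=build_candidate_set(
                               [ring(shift=6), ring(shift=6)]),
                           ground_truth=gt).outcome == "TN"

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_best(np.array([]))


class TestCalibration:
    def test_ols_recovers_linear_dice_with_gaussian_noise(self):
        """When true Dice is exactly linear in the agreement features plus
        N(0, sigma) noise, held-out MAE approaches sigma * sqrt(2/pi)."""
        rng = np.random.default_rng(42)
        n_cand, sigma = 4, 0.05
        w_true = rng.normal(0, 0.3, size=(n_cand, n_cand - 1))
        b_true = rng.uniform(0.3, 0.5, size=n_cand)

        def make(n):
            mats, ys = [], []
            for _ in range(n):
                m = np.eye(n_cand)
                iu = np.triu_indices(n_cand, 1)
                vals = rng.uniform(0.2, 0.9, size=len(iu[0]))
                m[iu] = vals
                m.T[iu] = vals
                mat = AgreementMatrix(values=m, ordering_hash="fixed")
                y = np.array([
                    w_true[i] @ mat.row_features(i) + b_true[i]
                    for i in range(n_cand)
                ]) + rng.normal(0, sigma, size=n_cand)
                mats.append(mat)
                ys.append(y)
            return mats, np.asarray(ys)

        mats, ys = make(2000)
        model = DiceRegressorBank().fit(mats, ys)
        mats_te, ys_te = make(500)
        errs = np.concatenate([
            np.abs(model.predict(m) - y) for m, y in zip(mats_te, ys_te)
        ])
        expected = sigma * np.sqrt(2 / np.pi)
        assert errs.mean() == pytest.approx(expected, rel=0.15)

    def test_perturbation_pool_held_out_mae(self):
        """Graded erosion/dilation/noise pool: predictions track true Dice."""
        fit_pool = perturbation_pool(120, seed=8, grid_size=48)
        test_pool = perturbation_pool(120, seed=9, grid_size=48)
        model = DiceRegressorBank().fit(
            [p.matrix for p in fit_pool],
            np.asarray([p.true_dice for p in fit_pool]))
        errs = np.concatenate([
            np.abs(model.predict(p.matrix) - p.true_dice) for p in test_pool
        ])
        assert errs.mean() <= 0.10
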