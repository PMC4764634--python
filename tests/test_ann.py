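"""Feed-forward network: forward pass, backprop deltas, training."""

import math

import numpy as np
import pytest

from silkspin.ann import (
    AnnTrainConfig,
    AnnTrainingError,
    MlpModel,
    backprop_deltas,
    fit_ann,
    forward,
    predict_ann,
    predict_matrix,
    weight_gradients,
)
from silkspin.dataset import load_table1
from silkspin.evaluation import mard
from silkspin.synth import GroundTruth, generate_dataset

IDENTITY_SCALING = tuple((1.0, 0.0) for _ in range(5))


def toy_model(hidden=3, seed=0, input_scaling=IDENTITY_SCALING,
              output_scaling=(1.0, 0.0)):
    rng = np.random.default_rng(seed)
    w0 = rng.uniform(-0.5, 0.5, (hidden, 6))
    w1 = rng.uniform(-0.5, 0.5, (1, hidden + 1))
    return MlpModel((hidden,), (w0, w1), input_scaling, output_scaling)


class TestForward:
    def test_zero_weights_give_half_activations_and_zero_output(self):
        model = MlpModel((4,), (np.zeros((4, 6)), np.zeros((1, 5))),
                         IDENTITY_SCALING, (1.0, 0.0))
        # hidden sigmoids at net=0 are exactly 0.5; zero output weights
        # make the linear output 0 regardless
        assert forward(model, [1.0, 2.0, 3.0, 4.0, 5.0]) == 0.0
        # hidden activations show up as -delta*O in the output-weight
        # gradient: all 0.5 at net = 0
        grads = weight_gradients(model, [1.0, 2.0, 3.0, 4.0, 5.0], 1.0)
        assert grads[1][0, :4] == pytest.approx([-0.5] * 4)  # -delta*O, O=0.5

    def test_single_neuron_net_zero_outputs_half(self):
        w0 = np.zeros((1, 6))
        w1 = np.array([[1.0, 0.0]])
        model = MlpModel((1,), (w0, w1), IDENTITY_SCALING, (1.0, 0.0))
        assert forward(model, [0.3, -1.0, 2.0, 0.0, 5.0]) == pytest.approx(0.5)

    def test_matches_independent_loop_computation(self):
        """Longhand sigmoid arithmetic (math.exp, python loops) agrees
        with the vectorized forward pass to 12 digits."""
        w0 = np.array([[0.2, -0.1, 0.05, 0.3, -0.25, 0.1],
                       [-0.3, 0.2, -0.15, 0.05, 0.1, -0.2],
                       [0.1, 0.1, -0.1, -0.1, 0.2, 0.05]])
        w1 = np.array([[0.5, -0.4, 0.3, 0.1]])
        scaling = tuple((0.1, 0.05 * j) for j in range(5))
        model = MlpModel((3,), (w0, w1), scaling, (0.01, -1.0))
        x = [10.0, 0.4, 20.0, 12.0, 600.0]
        assert forward(model, x) == pytest.approx(100.20037804765258, rel=1e-12)
        z = [0.1 * x[j] + 0.05 * j for j in range(5)]
        h = [1 / (1 + math.exp(-(sum(w0[i][j] * z[j] for j in range(5)) + w0[i][5])))
             for i in range(3)]
        o = sum(w1[0][i] * h[i] for i in range(3)) + w1[0][3]
        assert forward(model, x) == pytest.approx((o + 1.0) / 0.01, rel=1e-12)

    def test_scaling_round_trip(self):
        model = toy_model(output_scaling=(0.004, -0.5))
        d = np.array([120.0, 250.0, 333.3])
        assert model.unscale_output(model.scale_output(d)) == pytest.approx(d)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception, match="shape"):
            MlpModel((3,), (np.zeros((3, 6)), np.zeros((1, 3))),
                     IDENTITY_SCALING, (1.0, 0.0))


class TestDeltas:
    def test_perfect_prediction_gives_zero_output_delta(self):
        model = toy_model(seed=1)
        x = [0.2, 0.4, 0.6, 0.8, 1.0]
        deltas = backprop_deltas(model, x, forward(model, x))
        assert deltas[-1] == pytest.approx([0.0], abs=1e-15)
        assert deltas[0] == pytest.approx(np.zeros(3), abs=1e-15)

    def test_saturated_neuron_delta_vanishes(self):
        w0 = np.array([[50.0, 50.0, 50.0, 50.0, 50.0, 50.0]])  # O -> 1
        w1 = np.array([[1.0, 0.0]])
        model = MlpModel((1,), (w0, w1), IDENTITY_SCALING, (1.0, 0.0))
        deltas = backprop_deltas(model, [1.0, 1.0, 1.0, 1.0, 1.0], 5.0)
        assert abs(deltas[0][0]) < 1e-15  # O(1-O) factor kills it

    @pytest.mark.parametrize("trial", range(20))
    def test_deltas_match_finite_difference_gradients(self, trial):
        """Analytic backprop gradients of E = 1/2 (t-O)^2 agree with
        central finite differences on random 5-3-1 networks."""
        model = toy_model(seed=100 + trial)
        rng = np.random.default_rng(200 + trial)
        x = rng.uniform(-1, 1, 5)
        target = float(rng.uniform(-1, 1))
        _assert_gradients_match(model, x, target, tol=1e-6)


def _assert_gradients_match(model, x, target, tol):
    analytic = weight_gradients(model, x, target)
    h = 1e-5

    def loss(weights):
        m = MlpModel(model.hidden_sizes, weights, model.input_scaling,
                     model.output_scaling)
        o = m.scale_output(np.array([forward(m, x)]))
        t = m.scale_output(np.array([target]))
        return 0.5 * float(((t - o) ** 2)[0])

    for l, w in enumerate(model.weights):
        for idx in np.ndindex(w.shape):
            wp = [v.copy() for v in model.weights]
            wm = [v.copy() for v in model.weights]
            wp[l][idx] += h
            wm[l][idx] -= h
            fd = (loss(tuple(wp)) - loss(tuple(wm))) / (2 * h)
            a = analytic[l][idx]
            assert abs(a - fd) / max(abs(a), abs(fd), 1e-8) < tol


LINEAR_TRUTH = GroundTruth(terms=(((0, 0, 0, 0, 0), 100.0), ((0, 1, 0, 0, 0), 50.0)))


class TestTraining:
    def test_backprop_epoch_decreases_mse(self):
        """One batch epoch with a small learning rate reduces batch MSE
        on a smooth target (descent property, over several seeds)."""
        data = generate_dataset(LINEAR_TRUTH, n=30, seed=2)
        wins = 0
        for seed in range(5):
            cfg0 = AnnTrainConfig(algorithm="backprop", learning_rate=0.05,
                                  max_iterations=1, hidden_sizes=(4,), seed=seed)
            cfg50 = AnnTrainConfig(algorithm="backprop", learning_rate=0.05,
                                   max_iterations=60, hidden_sizes=(4,), seed=seed)
            m1 = fit_ann(data, cfg0)
            m2 = fit_ann(data, cfg50)
            mse1 = np.mean((predict_matrix(m1, data) - data.diameters()) ** 2)
            mse2 = np.mean((predict_matrix(m2, data) - data.diameters()) ** 2)
            wins += mse2 < mse1
        assert wins >= 4

    def test_linear_target_trains_below_1pct_mard(self):
        data = generate_dataset(LINEAR_TRUTH, n=30, seed=2)
        cfg = AnnTrainConfig(algorithm="levenberg_marquardt", hidden_sizes=(4,),
                             max_iterations=200, seed=0)
        model = fit_ann(data, cfg)
        report = mard(data.diameters(), predict_matrix(model, data))
        assert report.mard_percent < 1.0

    def test_lm_and_backprop_reach_same_mse_on_linear_target(self):
        data = generate_dataset(LINEAR_TRUTH, n=30, seed=2)
        lm = fit_ann(data, AnnTrainConfig(algorithm="levenberg_marquardt",
                                          hidden_sizes=(3,), max_iterations=300,
                                          seed=1))
        bp = fit_ann(data, AnnTrainConfig(algorithm="backprop", learning_rate=0.02,
                                          hidden_sizes=(3,), max_iterations=20000,
                                          convergence_tol=1e-15, seed=1))
        mse_lm = float(np.mean((predict_matrix(lm, data) - data.diameters()) ** 2))
        mse_bp = float(np.mean((predict_matrix(bp, data) - data.diameters()) ** 2))
        scale = float(np.var(data.diameters()))
        # both essentially interpolate; compare on the scale of the data
        assert mse_lm / scale < 1e-4
        assert mse_bp / scale < 1e-2

    def test_same_seed_identical_weights(self):
        data = generate_dataset(LINEAR_TRUTH, n=20, seed=4)
        cfg = AnnTrainConfig(hidden_sizes=(5,), max_iterations=50, seed=9)
        a = fit_ann(data, cfg)
        b = fit_ann(data, cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_divergence_raises_named_error(self):
        data = generate_dataset(LINEAR_TRUTH, n=20, seed=4)
        cfg = AnnTrainConfig(algorithm="backprop", learning_rate=1e9,
                             hidden_sizes=(4,), max_iterations=50, seed=0)
        with pytest.raises(AnnTrainingError, match="iteration"):
            fit_ann(data, cfg)

    def test_hidden_size_selected_from_search_space(self):
        data = load_table1()
        cfg = AnnTrainConfig(hidden_sizes=None, max_iterations=60, seed=3,
                             size_search=(3, 5))
        model = fit_ann(data, cfg)
        assert model.hidden_sizes[0] in (3, 5)


class TestPredict:
    def test_empty_dataset_gives_empty_list(self):
        from silkspin.dataset import Dataset

        model = toy_model()
        assert predict_ann(model, Dataset(())) == []

    def test_singleton_matches_forward(self):
        ds = load_table1().subset([4])
        model = toy_model(seed=3)
        assert predict_ann(model, ds) == [forward(model, ds.samples[0])]

    def test_row_permutation_permutes_predictions(self):
        ds = load_table1()
        model = toy_model(seed=5)
        preds = predict_ann(model, ds)
        from silkspin.dataset import Dataset

        reversed_ds = Dataset(tuple(reversed(ds.samples)), name="rev")
        assert predict_ann(model, reversed_ds) == list(reversed(preds))
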