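"""Surrogate network: forward pass, gradients, LM/SCG trainers, selection."""

import json

import numpy as np
import pytest
from scipy.optimize import least_squares

import fermopt as fo
from fermopt import bpnet
from fermopt.bpnet import (
    NetworkParams,
    TrainConfig,
    forward,
    init_network,
    loss_gradient,
    mse,
    prediction_jacobian,
    train,
)


def tiny_net(w1=1.0, w2=1.0, b1=0.0, b2=0.0):
    """A 1-1-1 network with hand-set parameters."""
    return NetworkParams(
        np.array([[w1]]), np.array([b1]), np.array([[w2]]), np.array([b2])
    )


class TestInit:
    def test_same_seed_gives_identical_parameters(self):
        a, b = init_network(9, 11, seed=0), init_network(9, 11, seed=0)
        assert np.array_equal(a.flatten(), b.flatten())
        c = init_network(9, 11, seed=1)
        assert not np.array_equal(a.flatten(), c.flatten())

    def test_shapes_and_fan_in_bound(self):
        net = init_network(9, 11, seed=3)
        assert net.hidden_weights.shape == (11, 9)
        assert net.output_weights.shape == (1, 11)
        assert np.all(np.abs(net.hidden_weights) <= 1 / np.sqrt(9))
        assert np.all(np.abs(net.output_weights) <= 1 / np.sqrt(11))
        assert np.all(net.hidden_biases == 0) and np.all(net.output_biases == 0)

    @pytest.mark.parametrize("n_in,n_hidden", [(0, 5), (5, 0), (-1, 3)])
    def test_non_positive_sizes_rejected(self, n_in, n_hidden):
        with pytest.raises(ValueError):
            init_network(n_in, n_hidden)


class TestForward:
    def test_zero_network_outputs_zero(self, rng):
        net = NetworkParams(
            np.zeros((4, 9)), np.zeros(4), np.zeros((1, 4)), np.zeros(1)
        )
        assert forward(net, rng.uniform(-5, 5, 9)) == 0.0

    def test_unit_chain_at_origin(self):
        # tanh(0) = 0, so a 1-1-1 net with zero biases maps 0 -> 0
        assert forward(tiny_net(), np.zeros(1)) == 0.0

    def test_tanh_saturation(self):
        # closed form: tanh(10) = 0.9999999958...
        assert forward(tiny_net(), np.array([10.0])) == pytest.approx(
            np.tanh(10.0), abs=1e-12
        )
        assert abs(forward(tiny_net(), np.array([10.0])) - 1.0) < 1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="features"):
            forward(init_network(9, 3), np.zeros(5))

    def test_batch_matches_per_sample(self, rng):
        net = init_network(9, 5, seed=7)
        X = rng.uniform(0, 1, (6, 9))
        batch = forward(net, X)
        singles = [forward(net, x) for x in X]
        assert np.allclose(batch, singles)


class TestMSE:
    def test_perfect_predictions_give_zero(self, rng):
        net = init_network(2, 3, seed=0)
        X = rng.uniform(0, 1, (5, 2))
        assert mse(net, X, forward(net, X)) == 0.0

    def test_constant_error_quarter(self, rng):
        net = NetworkParams(
            np.zeros((3, 9)), np.zeros(3), np.zeros((1, 3)), np.zeros(1)
        )
        X = rng.uniform(0, 1, (4, 9))
        assert mse(net, X, np.full(4, 0.5)) == pytest.approx(0.25)

    def test_hand_computed_three_sample_case(self):
        # 1-1-1 net, w1=w2=1, biases 0: predictions tanh(x)
        net = tiny_net()
        X = np.array([[0.0], [1.0], [-1.0]])
        y = np.array([0.5, 0.0, 1.0])
        expected = np.mean(
            [(0 - 0.5) ** 2, (np.tanh(1) - 0) ** 2, (np.tanh(-1) - 1) ** 2]
        )
        assert mse(net, X, y) == pytest.approx(expected, rel=1e-12)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            mse(tiny_net(), np.empty((0, 1)), np.empty(0))


class TestGradients:
    """Analytic derivatives vs central finite differences."""

    @pytest.mark.parametrize("n_in,n_hidden,n_samples", [(1, 1, 3), (3, 4, 6), (9, 5, 10)])
    def test_loss_gradient_matches_finite_differences(
        self, n_in, n_hidden, n_samples, rng
    ):
        net = init_network(n_in, n_hidden, seed=42)
        X = rng.uniform(-1, 1, (n_samples, n_in))
        y = rng.uniform(0, 1, n_samples)
        theta = net.flatten()
        analytic = loss_gradient(net, X, y)
        eps = 1e-6
        numeric = np.empty_like(theta)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            numeric[i] = (
                mse(net.with_flat(tp), X, y) - mse(net.with_flat(tm), X, y)
            ) / (2 * eps)
        denom = np.maximum(np.abs(numeric), 1e-8)
        assert np.max(np.abs(analytic - numeric) / denom) <= 1e-5

    def test_prediction_jacobian_matches_finite_differences(self, rng):
        net = init_network(3, 4, seed=5)
        X = rng.uniform(-1, 1, (4, 3))
        theta = net.flatten()
        J = prediction_jacobian(net, X)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            col = (forward(net.with_flat(tp), X) - forward(net.with_flat(tm), X)) / (
                2 * eps
            )
            assert np.allclose(J[:, i], col, atol=1e-6)


class TestTrainLM:
    def test_exact_fit_of_a_line_vs_least_squares_oracle(self):
        """y = 2x on 5 scaled points is exactly representable; the
        independent oracle is scipy's trust-region least squares on the
        same residual vector."""
        X = np.linspace(0, 1, 5).reshape(-1, 1)
        y = 2.0 * X[:, 0]
        net0 = init_network(1, 3, seed=0)
        cfg = TrainConfig(target_mse=1e-12, max_epochs=500)
        fitted, report = train(net0, X, y, cfg)
        assert report.final_mse < 1e-8

        def residuals(theta):
            return forward(net0.with_flat(theta), X) - y

        oracle = least_squares(residuals, net0.flatten(), method="trf")
        oracle_mse = np.mean(oracle.fun**2)
        assert report.final_mse <= oracle_mse + 1e-8

    def test_accepted_step_mse_is_non_increasing(self, table1_scaled):
        X, y = table1_scaled
        net0 = init_network(9, 11, seed=2)
        _, report = train(net0, X, y, TrainConfig(target_mse=1e-6, max_epochs=200))
        h = np.asarray(report.mse_history)
        assert len(h) >= 2
        assert np.all(np.diff(h) <= 0)
        assert report.final_mse == h[-1]

    def test_reaches_published_error_level_on_training_table(self, table1_scaled):
        """25 samples, >120 parameters: at least one of 10 seeds must
        drive the scaled training MSE to 0.018999 or below."""
        X, y = table1_scaled
        finals = []
        for seed in range(10):
            net0 = init_network(9, 11, seed=seed)
            _, rep = train(net0, X, y, TrainConfig(target_mse=0.018999))
            finals.append(rep.final_mse)
        assert min(finals) <= 0.018999

    def test_zero_epochs_is_a_no_op(self, table1_scaled):
        X, y = table1_scaled
        net0 = init_network(9, 11, seed=0)
        fitted, report = train(net0, X, y, TrainConfig(max_epochs=0))
        assert np.array_equal(fitted.flatten(), net0.flatten())
        assert report.epochs_run == 0
        assert report.final_mse == pytest.approx(mse(net0, X, y))

    def test_seeded_determinism(self, table1_scaled):
        X, y = table1_scaled
        runs = []
        for _ in range(2):
            net0 = init_network(9, 11, seed=5)
            fitted, rep = train(net0, X, y, TrainConfig())
            runs.append((fitted.flatten(), rep.mse_history))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]


class TestTrainSCG:
    def test_scg_converges_and_accepted_steps_decrease(self, table1_scaled):
        X, y = table1_scaled
        net0 = init_network(9, 11, seed=0)
        cfg = TrainConfig(
            algorithm="scaled_conjugate_gradient",
            target_mse=0.019,
            max_epochs=2000,
        )
        fitted, report = train(net0, X, y, cfg)
        assert report.converged
        h = np.asarray(report.mse_history)
        assert np.all(np.diff(h) <= 1e-12)


class TestHiddenSizeSelection:
    def test_singleton_candidate_is_returned(self, table1_scaled):
        X, y = table1_scaled
        assert bpnet.select_hidden_size(X, y, candidates={7}, seed=0) == 7

    def test_recovers_small_generator_network(self, rng):
        """Noiseless data from a 1-hidden-unit net: CV must not prefer a
        large network over the small ones that already fit exactly."""
        gen = tiny_net(w1=2.0, w2=1.5, b1=0.1, b2=0.2)
        X = rng.uniform(-1, 1, (40, 1))
        y = forward(gen, X)
        cfg = TrainConfig(target_mse=1e-10, max_epochs=300)
        size = bpnet.select_hidden_size(
            X, y, candidates=range(1, 6), seed=0, n_restarts=2, config=cfg
        )
        assert size in range(1, 6)
        # the chosen size must fit essentially as well as the generator
        net0 = init_network(1, size, seed=0)
        fitted, rep = train(net0, X, y, cfg)
        assert rep.final_mse < 1e-6

    def test_empty_candidates_rejected(self, table1_scaled):
        X, y = table1_scaled
        with pytest.raises(ValueError):
            bpnet.select_hidden_size(X, y, candidates=[])


class TestPredictProduction:
    def test_single_point_interpolation(self, table1, table1_scaler):
        """A net trained to exactly fit one training row must predict that
        row's measured yield (row with TF = 1560 μg/mL)."""
        row = table1[19]
        chrom = np.array(row[:9])
        Xs = table1_scaler.transform_features(chrom)
        ys = np.array([table1_scaler.transform_target(row.total_flavonoids)])
        net0 = init_network(9, 11, seed=0)
        fitted, rep = train(net0, Xs, ys, TrainConfig(target_mse=1e-14, max_epochs=200))
        pred = bpnet.predict_production(fitted, table1_scaler, chrom)
        assert row.total_flavonoids == 1560
        assert pred == pytest.approx(1560, abs=1e-3)

    def test_zero_network_is_a_constant_predictor(self, table1_scaler):
        net = NetworkParams(
            np.zeros((11, 9)), np.zeros(11), np.zeros((1, 11)), np.array([0.3])
        )
        expected = table1_scaler.inverse_scale(0.3, "total_flavonoids")
        for chrom in (np.zeros(9), np.full(9, 7.0)):
            assert bpnet.predict_production(net, table1_scaler, chrom) == pytest.approx(
                expected
            )

    def test_trained_net_predictions_are_finite_and_unbounded_above(
        self, table1, table1_scaler, rng
    ):
        Xs = table1_scaler.transform_features(table1.X)
        ys = table1_scaler.transform_target(table1.y)
        fitted, _ = train(init_network(9, 11, seed=0), Xs, ys, TrainConfig())
        chroms = rng.uniform(0, 50, (200, 9))
        preds = bpnet.predict_production(fitted, table1_scaler, chroms)
        assert np.isfinite(preds).all()
        # linear output: nothing pins predictions to the training range


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, table1_scaler, tmp_path):
        net = init_network(9, 11, seed=9)
        path = tmp_path / "model.json"
        bpnet.save_model(path, net, table1_scaler)
        net2, scaler2 = bpnet.load_model(path)
        assert np.array_equal(net.flatten(), net2.flatten())
        assert np.array_equal(table1_scaler.x_min, scaler2.x_min)
        assert np.array_equal(table1_scaler.x_max, scaler2.x_max)
        assert table1_scaler.columns == scaler2.columns
        json.loads(path.read_text())  # plain JSON document
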