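"""Splits, forward pass, Jacobian, LM/BR training and neuron trimming."""

import numpy as np
import pytest

from vinemetrics import ann
from vinemetrics.ann import (
    AffineScaler,
    Network,
    NetworkConfig,
    SplitSpec,
    error_jacobian,
    forward,
    load_network,
    neuron_trimming,
    save_network,
    split_dataset,
    train_bayesian_regularization,
    train_levenberg_marquardt,
)
from vinemetrics.evaluation import diagnostics


def _identity_scaler(n):
    return AffineScaler(minimum=-np.ones(n), maximum=np.ones(n))


def _teacher(n_in=6, n_hidden=10, n_out=2, seed=99):
    cfg = NetworkConfig(n_in, n_hidden, n_out, seed=seed)
    return ann._nguyen_widrow_init(cfg, _identity_scaler(n_in), _identity_scaler(n_out))


def _teacher_data(n=300, sigma=0.05, seed=2, **kw):
    rng = np.random.default_rng(seed)
    teacher = _teacher(**kw)
    X = rng.uniform(-1, 1, size=(n, teacher.W1.shape[1]))
    Y = forward(teacher, X) + rng.normal(0, sigma, size=(n, teacher.W2.shape[0]))
    return X, Y


class TestSplits:
    @pytest.mark.parametrize("fractions,expected", [
        ((0.75, 0.0, 0.25), (324, 0, 108)),
        ((0.60, 0.20, 0.20), (260, 86, 86)),
    ])
    def test_stage_counts_on_432_samples(self, fractions, expected):
        s = split_dataset(432, SplitSpec(fractions=fractions, seed=0))
        assert s.counts == expected

    def test_counts_within_one_of_fraction_times_n(self):
        for n in (50, 111, 216, 433):
            s = split_dataset(n, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=3))
            for count, frac in zip(s.counts, (0.6, 0.2, 0.2)):
                assert abs(count - frac * n) <= 1

    def test_same_seed_reproduces_assignment(self):
        a = split_dataset(100, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=7))
        b = split_dataset(100, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=7))
        assert a.assignment == b.assignment

    def test_partition_is_disjoint_and_exhaustive(self):
        s = split_dataset(101, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=5))
        combined = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert sorted(combined) == list(range(101))

    def test_empty_positive_stage_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(6, SplitSpec(fractions=(0.9, 0.05, 0.05), seed=0))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))


class TestForward:
    def test_zero_network_predicts_target_midpoint(self):
        net = Network(W1=np.zeros((3, 2)), b1=np.zeros(3),
                      W2=np.zeros((1, 3)), b2=np.zeros(1),
                      input_scaler=_identity_scaler(2),
                      target_scaler=AffineScaler(np.array([10.0]), np.array([30.0])))
        pred = forward(net, np.random.default_rng(0).normal(size=(5, 2)))
        assert np.allclose(pred, 20.0)

    def test_hand_set_1_1_1_network(self):
        net = Network(W1=np.ones((1, 1)), b1=np.zeros(1),
                      W2=np.ones((1, 1)), b2=np.zeros(1),
                      input_scaler=_identity_scaler(1),
                      target_scaler=_identity_scaler(1))
        assert forward(net, np.array([[0.0]]))[0, 0] == 0.0

    def test_matches_independent_arithmetic(self, rng):
        net = _teacher(n_in=3, n_hidden=4, n_out=2, seed=5)
        X = rng.normal(size=(5, 3))
        by_hand = np.array([
            net.W2 @ np.tanh(net.W1 @ x + net.b1) + net.b2 for x in X
        ])
        assert np.allclose(forward(net, X), by_hand, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        net = _teacher(n_in=3)
        with pytest.raises(ValueError):
            forward(net, np.zeros((4, 2)))


class TestScaling:
    def test_round_trip_identity(self, rng):
        X = rng.normal(size=(40, 5)) * 100 + 7
        sc = AffineScaler.fit(X)
        assert np.allclose(sc.unscale(sc.scale(X)), X, atol=1e-10)
        assert sc.scale(X).min() == pytest.approx(-1)
        assert sc.scale(X).max() == pytest.approx(1)

    def test_constant_feature_maps_to_minus_one_and_back(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        sc = AffineScaler.fit(X)
        assert np.allclose(sc.unscale(sc.scale(X)), X)

    def test_training_invariant_to_input_rescaling(self):
        X, Y = _teacher_data(n=200, sigma=0.05)
        spec = split_dataset(200, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=4))
        cfg = NetworkConfig(6, 5, 2, seed=8, max_epochs=150)
        net_a, _ = train_levenberg_marquardt((X, Y), spec, cfg)
        net_b, _ = train_levenberg_marquardt((X * 1000 + 55, Y), spec, cfg)
        r_a = diagnostics(forward(net_a, X), Y).r
        r_b = diagnostics(forward(net_b, X * 1000 + 55), Y).r
        assert r_b == pytest.approx(r_a, abs=0.02)


class TestJacobian:
    def test_analytic_matches_central_differences(self, rng):
        net = _teacher(n_in=3, n_hidden=4, n_out=2, seed=11)
        Xs = rng.normal(size=(6, 3))
        Ys = rng.normal(size=(6, 2))
        e, J = error_jacobian(net, Xs, Ys)
        w0 = net.flat()
        eps = 1e-6
        J_fd = np.empty_like(J)
        for k in range(len(w0)):
            wp = w0.copy()
            wp[k] += eps
            net.set_flat(wp)
            ep, _ = error_jacobian(net, Xs, Ys)
            wm = w0.copy()
            wm[k] -= eps
            net.set_flat(wm)
            em, _ = error_jacobian(net, Xs, Ys)
            J_fd[:, k] = (ep - em) / (2 * eps)
        net.set_flat(w0)
        rel = np.max(np.abs(J - J_fd)) / np.max(np.abs(J_fd))
        assert rel < 1e-5


class TestLevenbergMarquardt:
    def test_realizable_linear_target_fits_to_tiny_mse(self):
        X = np.linspace(-1, 1, 50)[:, None]
        Y = 3 * X - 1
        spec = split_dataset(50, SplitSpec(fractions=(0.8, 0.2, 0.0), seed=0))
        net, res = train_levenberg_marquardt(
            (X, Y), spec, NetworkConfig(1, 3, 1, seed=1, max_epochs=300))
        assert res.mse_train < 1e-5

    def test_single_step_with_vanishing_damping_solves_normal_equations(self, rng):
        # the residual is linear in the weights over one step: the damped
        # Gauss-Newton update must approach the least-squares solution
        net = _teacher(n_in=4, n_hidden=3, n_out=1, seed=3)
        Xs = rng.normal(size=(30, 4))
        Ys = rng.normal(size=(30, 1))
        e, J = error_jacobian(net, Xs, Ys)
        mu = 1e-12
        step = np.linalg.solve(J.T @ J + mu * np.eye(J.shape[1]), -J.T @ e)
        oracle = np.linalg.lstsq(J, -e, rcond=None)[0]
        assert np.allclose(step, oracle, atol=1e-8)

    def test_teacher_student_recovery(self):
        X, Y = _teacher_data(n=300, sigma=0.05)
        spec = split_dataset(300, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=3))
        net, res = train_levenberg_marquardt((X, Y), spec, NetworkConfig(6, 10, 2, seed=4))
        d = diagnostics(forward(net, X[spec.test_idx]), Y[spec.test_idx], "testing")
        assert d.r >= 0.95

    def test_accepted_steps_never_increase_objective(self):
        X, Y = _teacher_data(n=120, sigma=0.1)
        spec = split_dataset(120, SplitSpec(fractions=(0.8, 0.2, 0.0), seed=1))
        _, res = train_levenberg_marquardt(
            (X, Y), spec, NetworkConfig(6, 5, 2, seed=2, max_epochs=60))
        trace = np.array(res.objective_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_requires_matching_algorithm(self):
        with pytest.raises(ValueError):
            train_levenberg_marquardt(
                (np.zeros((10, 1)), np.zeros(10)),
                SplitSpec(fractions=(0.8, 0.2, 0.0), seed=0),
                NetworkConfig(1, 3, 1, algorithm="bayesian_regularization"))


class TestBayesianRegularization:
    def test_pure_noise_targets_are_shrunk(self, rng):
        X = rng.uniform(-1, 1, size=(20, 3))
        Y = rng.normal(size=(20, 1))  # no signal at all
        spec = split_dataset(20, SplitSpec(fractions=(1.0, 0.0, 0.0), seed=0))
        cfg_br = NetworkConfig(3, 5, 1, algorithm="bayesian_regularization",
                               seed=1, max_epochs=200)
        net_br, res_br = train_bayesian_regularization((X, Y), spec, cfg_br)
        cfg_lm = NetworkConfig(3, 5, 1, seed=1, max_epochs=200)
        net_lm, res_lm = train_levenberg_marquardt((X, Y), spec, cfg_lm)
        assert res_br.gamma < 0.5 * res_br.n_weights  # few effective parameters
        assert np.sum(net_br.flat() ** 2) < np.sum(net_lm.flat() ** 2)
        assert res_lm.mse_train < res_br.mse_train  # LM chases the noise

    def test_teacher_student_recovery_without_validation(self):
        X, Y = _teacher_data(n=300, sigma=0.05)
        spec = split_dataset(300, SplitSpec(fractions=(0.75, 0.0, 0.25), seed=6))
        cfg = NetworkConfig(6, 10, 2, algorithm="bayesian_regularization", seed=5)
        net, res = train_bayesian_regularization((X, Y), spec, cfg)
        d = diagnostics(forward(net, X[spec.test_idx]), Y[spec.test_idx], "testing")
        assert d.r >= 0.95
        assert res.mse_test <= 2 * res.mse_train

    def test_alpha_pinned_at_zero_reduces_to_plain_lm(self):
        X, Y = _teacher_data(n=80, sigma=0.1)
        spec = split_dataset(80, SplitSpec(fractions=(1.0, 0.0, 0.0), seed=2))
        cfg_br = NetworkConfig(6, 4, 2, algorithm="bayesian_regularization",
                               seed=9, max_epochs=40, alpha_fixed=0.0)
        cfg_lm = NetworkConfig(6, 4, 2, seed=9, max_epochs=40)
        net_br, _ = train_bayesian_regularization((X, Y), spec, cfg_br)
        net_lm, _ = train_levenberg_marquardt((X, Y), spec, cfg_lm)
        assert np.allclose(net_br.flat(), net_lm.flat(), atol=1e-9)


class TestDeterminism:
    def test_identical_runs_are_identical(self):
        X, Y = _teacher_data(n=100, sigma=0.1)
        spec = SplitSpec(fractions=(0.6, 0.2, 0.2), seed=5)
        cfg = NetworkConfig(6, 5, 2, seed=6, max_epochs=50)
        net_a, res_a = train_levenberg_marquardt((X, Y), spec, cfg)
        net_b, res_b = train_levenberg_marquardt((X, Y), spec, cfg)
        assert np.array_equal(net_a.flat(), net_b.flat())
        assert res_a.mse_train == pytest.approx(res_b.mse_train, abs=1e-9)


class TestNeuronTrimming:
    def test_small_teacher_selects_smallest_adequate_size(self):
        X, Y = _teacher_data(n=250, sigma=0.01, n_hidden=3, n_out=1, seed=12)
        spec = split_dataset(250, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=1))
        cfg = NetworkConfig(6, 3, 1, seed=3, max_epochs=200)
        report = neuron_trimming((X, Y), spec, cfg, candidates=[3, 5, 7, 10])
        assert report.selected == 3

    def test_single_candidate(self):
        X, Y = _teacher_data(n=100, sigma=0.1)
        spec = split_dataset(100, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=2))
        cfg = NetworkConfig(6, 3, 2, seed=3, max_epochs=50)
        report = neuron_trimming((X, Y), spec, cfg, candidates=[3])
        assert report.selected == 3

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            neuron_trimming((np.zeros((10, 2)), np.zeros(10)),
                            SplitSpec(fractions=(0.6, 0.2, 0.2), seed=0),
                            NetworkConfig(2, 3, 1), candidates=[])


def test_network_json_round_trip(tmp_path):
    net = _teacher(n_in=4, n_hidden=3, n_out=2, seed=21)
    X = np.random.default_rng(0).normal(size=(10, 4))
    path = tmp_path / "net.json"
    save_network(net, path, config=NetworkConfig(4, 3, 2))
    back = load_network(path)
    assert np.allclose(forward(net, X), forward(back, X), atol=1e-12)
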