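import math

import numpy as np
import pytest

from earmotion.models import (
    BonsaiClassifier,
    BonsaiParams,
    FastGrnnParams,
    FastRnnParams,
    ProtoNnParams,
    TcnClassifier,
    TcnConfig,
    Tensor,
    bonsai_predict,
    build_model,
    fastgrnn_step,
    fastrnn_step,
    iht_project,
    multiclass_hinge_loss,
    protonn_predict,
    tcn_receptive_field,
    train_model,
)


class TestFastRnnStep:
    def test_alpha_zero_beta_one_is_identity(self, rng):
        p = FastRnnParams(W=rng.normal(size=(4, 3)), U=rng.normal(size=(4, 4)),
                          b=rng.normal(size=4), alpha=0.0, beta_res=1.0)
        h = rng.normal(size=4)
        assert np.allclose(fastrnn_step(h, rng.normal(size=3), p), h)

    def test_alpha_one_beta_zero_is_vanilla_rnn(self, rng):
        p = FastRnnParams(W=rng.normal(size=(4, 3)), U=rng.normal(size=(4, 4)),
                          b=rng.normal(size=4), alpha=1.0, beta_res=0.0)
        h = rng.normal(size=4)
        x = rng.normal(size=3)
        expected = np.tanh(p.W @ x + p.U @ h + p.b)
        assert np.allclose(fastrnn_step(h, x, p), expected)

    def test_scalar_hand_evaluation(self):
        p = FastRnnParams(W=np.ones((1, 1)), U=np.ones((1, 1)), b=np.zeros(1),
                          alpha=0.1, beta_res=0.9)
        out = fastrnn_step(np.zeros(1), np.array([0.5]), p)
        assert out[0] == pytest.approx(0.1 * math.tanh(0.5))

    def test_dim_mismatch_rejected(self, rng):
        p = FastRnnParams(W=np.ones((2, 3)), U=np.ones((2, 2)), b=np.zeros(2),
                          alpha=0.1, beta_res=0.9)
        with pytest.raises(ValueError):
            fastrnn_step(np.zeros(2), np.zeros(4), p)


class TestFastGrnnStep:
    def test_closed_gate_keeps_state(self):
        p = FastGrnnParams(W1=np.zeros((2, 3)), U1=np.zeros((2, 2)),
                           b_h=np.zeros(2), b_z=np.full(2, 60.0), zeta=1.0, nu=0.0)
        h = np.array([0.3, -0.2])
        assert np.allclose(fastgrnn_step(h, np.ones(3), p), h, atol=1e-12)

    def test_identity_second_factor_is_full_rank_limit(self, rng):
        W1 = rng.normal(size=(3, 3))
        p_lr = FastGrnnParams(W1=W1, W2=np.eye(3), U1=np.eye(3), U2=np.eye(3),
                              b_h=np.zeros(3), b_z=np.zeros(3), zeta=1.0, nu=0.0)
        assert np.allclose(p_lr.W, W1)

    def test_scalar_hand_evaluation(self):
        p = FastGrnnParams(W1=np.full((1, 1), 0.5), U1=np.full((1, 1), 0.5),
                           b_h=np.full(1, 0.5), b_z=np.full(1, 0.5), zeta=1.0, nu=0.0)
        h, x = 0.2, 1.0
        pre = 0.5 * x + 0.5 * h
        z = 1 / (1 + math.exp(-(pre + 0.5)))
        h_tilde = math.tanh(pre + 0.5)
        expected = (1.0 * (1 - z) + 0.0) * h_tilde + z * h
        out = fastgrnn_step(np.array([h]), np.array([x]), p)
        assert out[0] == pytest.approx(expected)


class TestTcn:
    def test_receptive_field_base_case_and_formula(self):
        assert tcn_receptive_field(2, []) == 1
        assert tcn_receptive_field(2, [1, 2, 4]) == 8
        # dilation-1 stack reduces to the vanilla CNN span i*(k-1)+1
        for i in (1, 3, 5):
            assert tcn_receptive_field(3, [1] * i) == i * 2 + 1

    def test_receptive_field_matches_measured_dependency_span(self):
        cfg = TcnConfig(n_filters=2, kernel=2, dilations=(1, 2, 4))
        model = TcnClassifier(input_dim=1, n_classes=2, config=cfg, seed=0)
        T = 20
        base = model.features(np.zeros((1, T, 1))).data
        span = 0
        for back in range(T):
            x = np.zeros((1, T, 1))
            x[0, T - 1 - back, 0] = 1.0
            out = model.features(x).data
            if abs(out[0, :, T - 1] - base[0, :, T - 1]).max() > 1e-12:
                span = back + 1
        assert span == tcn_receptive_field(2, [1, 2, 4])

    def test_causality_perturbation(self, rng):
        cfg = TcnConfig(n_filters=4, kernel=3, dilations=(1, 2), use_residual=True)
        model = TcnClassifier(input_dim=3, n_classes=2, config=cfg, seed=1)
        x = rng.normal(size=(1, 30, 3))
        base = model.features(x).data
        x2 = x.copy()
        x2[0, 20] += 5.0
        pert = model.features(x2).data
        assert np.allclose(pert[0, :, :20], base[0, :, :20])
        assert not np.allclose(pert[0, :, 20:], base[0, :, 20:])

    def test_all_zero_weights_give_zero_block(self):
        cfg = TcnConfig(n_filters=2, kernel=2, dilations=(1,))
        model = TcnClassifier(input_dim=2, n_classes=2, config=cfg, seed=0)
        for name, t in model.params().items():
            t.data[...] = 0.0
        out = model.features(np.random.default_rng(0).normal(size=(2, 10, 2)))
        assert np.allclose(out.data, 0.0)

    def test_hand_convolution(self):
        # 1 filter, k=2, dilation 1: y_t = w0*x_{t-1} + w1*x_t
        cfg = TcnConfig(n_filters=2, kernel=2, dilations=(1,))
        model = TcnClassifier(input_dim=1, n_classes=2, config=cfg, seed=0)
        W = model.params()["Wf0"]
        W.data[...] = 0.0
        W.data[0, 0, 0] = 2.0  # weight on x_{t-1}
        W.data[0, 0, 1] = 1.0  # weight on x_t
        model.params()["Wg0"].data[...] = 100.0  # gate saturates to ~1
        model.params()["bg0"].data[...] = 100.0
        x = np.array([1.0, 0.0, 0.0, 1.0]).reshape(1, 4, 1)
        out = model.features(x).data[0, 0]
        expected = np.tanh([1.0, 2.0, 0.0, 1.0])
        assert np.allclose(out, expected, atol=1e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TcnConfig(n_filters=1)
        with pytest.raises(ValueError):
            TcnConfig(dilations=(4, 2, 1))
        with pytest.raises(ValueError):
            TcnConfig(dilations=(3,))


class TestBonsai:
    def test_depth_one_is_a_single_node(self, rng):
        Z = rng.normal(size=(3, 5))
        W = rng.normal(size=(1, 3, 2))
        V = rng.normal(size=(1, 3, 2))
        p = BonsaiParams(Z=Z, W=W, V=V, T=np.zeros((0, 3)), sigma_b=1.0, depth=1)
        x = rng.normal(size=5)
        xh = Z @ x
        expected = (W[0].T @ xh) * np.tanh(1.0 * (V[0].T @ xh))
        assert np.allclose(bonsai_predict(x, p), expected)

    def test_large_sigma_saturates_to_sign(self, rng):
        Z = np.eye(3)
        W = rng.normal(size=(1, 3, 2))
        V = np.ones((1, 3, 2))
        p = BonsaiParams(Z=Z, W=W, V=V, T=np.zeros((0, 3)), sigma_b=1e6, depth=1)
        x = np.array([1.0, 2.0, 3.0])
        expected = W[0].T @ x  # tanh saturates to +1
        assert np.allclose(bonsai_predict(x, p), expected, atol=1e-6)

    def test_depth_two_path_matches_leaf_enumeration(self, rng):
        Z = np.eye(3)
        W = rng.normal(size=(3, 3, 2))
        V = rng.normal(size=(3, 3, 2))
        T = np.array([[1.0, 0.0, 0.0]])  # route on sign of x_hat[0]
        p = BonsaiParams(Z=Z, W=W, V=V, T=T, sigma_b=1.0, depth=2)
        for x0, leaf in [(2.0, 2), (-2.0, 1)]:
            x = np.array([x0, 0.5, -0.5])
            node_score = lambda k: (W[k].T @ x) * np.tanh(V[k].T @ x)
            expected = node_score(0) + node_score(leaf)
            assert np.allclose(bonsai_predict(x, p), expected)

    def test_classifier_hard_and_soft_routing_agree_on_confident_points(self, rng):
        model = BonsaiClassifier(input_dim=4, n_classes=2, depth=2, projection_dim=3, seed=3)
        X = rng.normal(size=(20, 4)) * 5
        soft = model.forward(X, soft=True).data
        hard = model.forward(X, soft=False).data
        # far from the boundary the soft indicator is ~0/1
        agree = np.mean(np.sign(soft[:, 0] - soft[:, 1]) == np.sign(hard[:, 0] - hard[:, 1]))
        assert agree >= 0.8


class TestProtoNn:
    def test_prototype_at_projection_scores_its_weight(self, rng):
        W = rng.normal(size=(3, 5))
        x = rng.normal(size=5)
        B = (W @ x).reshape(3, 1)
        Z = np.array([[2.5], [0.0]])
        p = ProtoNnParams(W=W, B=B, Z=Z, gamma=0.7)
        scores = protonn_predict(x, p)
        assert scores[0] == pytest.approx(2.5)
        assert scores[1] == pytest.approx(0.0)

    def test_flat_kernel_limit_sums_scores(self, rng):
        W = rng.normal(size=(3, 5))
        B = rng.normal(size=(3, 4))
        Z = rng.normal(size=(2, 4))
        p = ProtoNnParams(W=W, B=B, Z=Z, gamma=1e-9)
        scores = protonn_predict(rng.normal(size=5), p)
        assert np.allclose(scores, Z.sum(axis=1), atol=1e-6)

    def test_two_prototype_hand_values(self):
        W = np.eye(2)
        B = np.array([[0.0, 1.0], [0.0, 0.0]])
        Z = np.array([[1.0, 0.0], [0.0, 2.0]])
        p = ProtoNnParams(W=W, B=B, Z=Z, gamma=1.0)
        x = np.array([0.5, 0.0])
        k = np.exp(-np.array([0.25, 0.25]))
        assert np.allclose(protonn_predict(x, p), [k[0], 2 * k[1]])

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            ProtoNnParams(W=np.eye(2), B=np.zeros((2, 1)), Z=np.zeros((2, 1)), gamma=0.0)


class TestTraining:
    def test_separable_features_reach_perfect_train_accuracy(self, rng):
        Xa = rng.normal(size=(40, 10)) + 3
        Xb = rng.normal(size=(40, 10)) - 3
        X = np.vstack([Xa, Xb])
        y = np.array([0] * 40 + [1] * 40)
        for mid in ("bonsai", "protonn"):
            tm = train_model(mid, {"X": X, "y": y}, {"epochs": 30, "batch_size": 32}, seed=1)
            assert tm.accuracy(X, y) == 1.0

    def test_iht_enforces_sparsity_fractions(self, rng):
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 2, 60)
        tm = train_model(
            "bonsai",
            {"X": X, "y": y},
            {"epochs": 10, "batch_size": 32, "sparsity": {"Z": 0.3}},
            seed=0,
        )
        Z = tm.model.params()["Z"].data
        assert np.count_nonzero(Z) <= int(round(0.3 * Z.size)) + 1

    def test_training_is_seed_reproducible(self, rng):
        X = rng.normal(size=(50, 10))
        y = rng.integers(0, 3, 50)
        a = train_model("protonn", {"X": X, "y": y}, {"epochs": 5}, seed=7)
        b = train_model("protonn", {"X": X, "y": y}, {"epochs": 5}, seed=7)
        assert a.history[-1]["loss"] == b.history[-1]["loss"]
        for k in a.model.params():
            assert np.array_equal(a.model.params()[k].data, b.model.params()[k].data)

    def test_hinge_loss_zero_when_margins_are_met(self):
        scores = Tensor(np.array([[5.0, 0.0], [0.0, 5.0]]))
        y = np.array([0, 1])
        assert multiclass_hinge_loss(scores, y).data == 0.0

    def test_hinge_loss_hand_value(self):
        scores = Tensor(np.array([[1.0, 0.5]]))
        y = np.array([0])
        # violation = 1 + 0.5 - 1.0 = 0.5
        assert multiclass_hinge_loss(scores, y).data == pytest.approx(0.5)

    def test_iht_project_keeps_top_magnitudes(self):
        arr = np.array([3.0, -1.0, 0.5, -4.0])
        out = iht_project(arr, 0.5)
        assert np.array_equal(out != 0, np.array([True, False, False, True]))


class TestParameterAccounting:
    def test_low_rank_fastgrnn_stores_fewer_weights(self):
        m, n, r = 40, 30, 8  # r < mn/(m+n) ~ 17
        full = build_model("fastgrnn", (100, n), 4, {"hidden_dim": m}, seed=0)
        low = build_model("fastgrnn", (100, n), 4, {"hidden_dim": m, "rank": r}, seed=0)
        count = lambda model, keys: sum(model.params()[k].data.size for k in keys if k in model.params())
        assert count(low, ("W1", "W2")) < count(full, ("W1",))
        assert count(low, ("U1", "U2")) < count(full, ("U1",))
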