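"""Network construction, forward pass and the three trainers."""

import numpy as np
import pandas as pd
import pytest

from codmedia import ann, doe
from codmedia.ann import NeuralModel, TrainingConfig, init_network, train


def make_design(X, y, split="train"):
    k = X.shape[1]
    factors = [doe.FactorSpec(f"f{i}", 0.5, 0.25) for i in range(k)]
    df = pd.DataFrame(X, columns=[f.name for f in factors])
    df.insert(0, "run", np.arange(1, len(df) + 1))
    df["point_type"] = "factorial"
    df["split"] = split
    df["observed"] = y
    return doe.DesignTable(factors, df)


def identity_scaled(IW, b, LW, a):
    """A network whose input/output scalings are the identity on [-1, 1]."""
    IW = np.asarray(IW, dtype=float)
    k = IW.shape[1]
    return NeuralModel(
        IW=np.asarray(IW, dtype=float),
        b=np.asarray(b, dtype=float),
        LW=np.asarray(LW, dtype=float),
        a=float(a),
        norm_in=np.vstack([-np.ones(k), np.ones(k)]),
        norm_out=np.array([-1.0, 1.0]),
    )


class TestInit:
    def test_seed_determinism(self):
        a = init_network(15, seed=42)
        b = init_network(15, seed=42)
        np.testing.assert_array_equal(a.IW, b.IW)
        np.testing.assert_array_equal(a.LW, b.LW)

    def test_shapes_for_15_hidden_units(self):
        net = init_network(15, seed=0)
        assert net.IW.shape == (15, 5)
        assert net.b.shape == (15,)
        assert net.LW.shape == (15,)
        assert net.n_params == 15 * 5 + 15 + 15 + 1

    def test_different_seeds_differ(self):
        assert not np.array_equal(init_network(3, 0).IW, init_network(3, 1).IW)

    def test_rejects_empty_hidden_layer(self):
        with pytest.raises(ValueError):
            init_network(0, seed=0)


class TestForward:
    def test_tansig_equals_tanh(self):
        z = np.array([-2.0, -0.5, 0.0, 1.0, 3.0])
        np.testing.assert_allclose(
            ann.tansig(z), 2.0 / (1.0 + np.exp(-2.0 * z)) - 1.0, atol=1e-12
        )
        np.testing.assert_allclose(ann.tansig(z), np.tanh(z), atol=1e-15)

    def test_hand_built_single_unit_network(self):
        net = identity_scaled(IW=[[1, 0, 0, 0, 0]], b=[0.0], LW=[1.0], a=0.0)
        out = net.forward([0.5, 0.1, -0.3, 0.9, 0.0])
        assert out == pytest.approx(np.tanh(0.5), abs=1e-12)

    def test_constant_network(self):
        net = identity_scaled(IW=np.zeros((4, 5)), b=np.zeros(4), LW=np.zeros(4), a=0.25)
        X = np.random.default_rng(0).uniform(-1, 1, (10, 5))
        np.testing.assert_allclose(net.forward(X), 0.25)

    def test_unfitted_network_rejected(self):
        net = init_network(3, seed=0)
        with pytest.raises(ann.NotFittedError):
            net.forward(np.zeros(5))

    def test_predict_table_is_stateless_rowwise(self, paper_design):
        net0 = init_network(5, seed=3)
        net, _ = train(net0, paper_design, TrainingConfig(seed=3, max_epochs=5))
        pred = ann.predict_table(net, paper_design)
        perm = np.random.default_rng(1).permutation(36)
        shuffled = paper_design.df.iloc[perm].reset_index(drop=True)
        pred_perm = ann.predict_table(
            net, doe.DesignTable(paper_design.factors, shuffled)
        )
        np.testing.assert_allclose(pred_perm, pred[perm], atol=1e-12)


class TestTrain:
    def test_lm_accepted_sse_nonincreasing(self, paper_design):
        _, rep = train(
            init_network(15, seed=1), paper_design, TrainingConfig(seed=1, early_stop_patience=0)
        )
        assert len(rep.sse_trace) > 1
        assert np.all(np.diff(rep.sse_trace) <= 1e-15)

    def test_lm_fits_self_generated_data(self):
        """On noiseless data from a 3-hidden-unit teacher, LM drives the
        training SSE to (numerical) zero from at least one restart."""
        rng = np.random.default_rng(7)
        teacher = NeuralModel(
            IW=rng.normal(0, 1, (3, 5)),
            b=rng.normal(0, 1, 3),
            LW=rng.normal(0, 1, 3),
            a=0.3,
            norm_in=np.vstack([np.zeros(5), np.ones(5)]),
            norm_out=np.array([0.0, 1.0]),
        )
        X = rng.uniform(0, 1, (50, 5))
        design = make_design(X, np.asarray(teacher.forward(X)))
        best = np.inf
        for seed in range(5):
            _, rep = train(
                init_network(3, seed=seed),
                design,
                TrainingConfig(seed=seed, max_epochs=200, goal_sse=1e-6),
            )
            final = rep.sse_trace[-1] if rep.sse_trace else 0.0
            best = min(best, final)
            if best <= 1e-4:
                break
        assert best <= 1e-4

    def test_targets_equal_to_initial_outputs_stop_immediately(self):
        rng = np.random.default_rng(11)
        IW = rng.normal(0, 0.5, (4, 5))
        b = rng.normal(0, 0.5, 4)
        LW = rng.normal(0, 0.5, 4)
        a = 0.1
        X = rng.uniform(0, 1, (20, 5))
        # normalized-space outputs of the fixed hidden stack
        lo, hi = X.min(axis=0), X.max(axis=0)
        Z = 2 * (X - lo) / (hi - lo) - 1
        yn = np.tanh(Z @ IW.T + b) @ LW + a
        # rescale output weights so yn spans exactly [-1, 1]; then the
        # unscaled targets reproduce the network's own outputs
        mn, mx = yn.min(), yn.max()
        LW2 = 2 * LW / (mx - mn)
        a2 = 2 * (a - mn) / (mx - mn) - 1
        y = (yn - mn) / (mx - mn) * 3.0 + 1.0  # arbitrary range [1, 4]
        design = make_design(X, y)
        net0 = NeuralModel(IW=IW, b=b, LW=LW2, a=a2)
        net, rep = train(net0, design, TrainingConfig(seed=0))
        assert rep.stop_reason == "goal_reached"
        assert rep.epochs == 0
        np.testing.assert_allclose(np.asarray(net.forward(X)), y, atol=1e-9)

    @pytest.mark.parametrize("algorithm", ["gd", "gda"])
    def test_gradient_descent_reduces_sse(self, algorithm):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (30, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 1.5]) + 0.3
        design = make_design(X, y)
        _, rep = train(
            init_network(4, seed=2),
            design,
            TrainingConfig(algorithm=algorithm, seed=2, max_epochs=150),
        )
        accepted = [s for s in rep.step_trace if s[3]]
        assert accepted[-1][1] < accepted[0][1]
        if algorithm == "gda":
            # rejected steps never lower the stored SSE sequence
            assert np.all(np.diff(rep.sse_trace) <= 1e-15)

    def test_seeded_reproducibility(self, paper_design):
        cfg = TrainingConfig(seed=9)
        net_a, rep_a = train(init_network(15, seed=9), paper_design, cfg)
        net_b, rep_b = train(init_network(15, seed=9), paper_design, cfg)
        np.testing.assert_array_equal(net_a.IW, net_b.IW)
        assert rep_a.sse_trace == rep_b.sse_trace
        assert rep_a.r_validation == rep_b.r_validation

    def test_response_scale_consistency(self):
        """Multiplying the responses by 10 rescales predictions by exactly
        10: training operates on the normalized scale and is unchanged."""
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (25, 5))
        y = np.sin(X.sum(axis=1)) + 2.0
        net_1, _ = train(
            init_network(4, seed=4), make_design(X, y), TrainingConfig(seed=4, max_epochs=50)
        )
        net_10, _ = train(
            init_network(4, seed=4),
            make_design(X, 10 * y),
            TrainingConfig(seed=4, max_epochs=50),
        )
        np.testing.assert_allclose(
            np.asarray(net_10.forward(X)), 10 * np.asarray(net_1.forward(X)), rtol=1e-9
        )

    def test_training_splits_config(self, paper_design):
        cfg24 = TrainingConfig(seed=1, max_epochs=5, train_splits=("train",))
        cfg30 = TrainingConfig(seed=1, max_epochs=5)
        _, rep24 = train(init_network(3, seed=1), paper_design, cfg24)
        _, rep30 = train(init_network(3, seed=1), paper_design, cfg30)
        # different objective data -> different training trajectories
        assert rep24.sse_trace != rep30.sse_trace

    def test_json_roundtrip(self, paper_design, tmp_path):
        net, _ = train(
            init_network(3, seed=6), paper_design, TrainingConfig(seed=6, max_epochs=5)
        )
        path = tmp_path / "net.json"
        net.to_json(path)
        back = NeuralModel.from_json(path)
        np.testing.assert_allclose(
            np.asarray(back.forward(paper_design.uncoded)),
            np.asarray(net.forward(paper_design.uncoded)),
            atol=1e-12,
        )
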