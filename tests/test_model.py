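import numpy as np
import pytest

from hybrec.model import (
    Adam,
    TrainConfig,
    bigru_forward,
    direction_view,
    gru_step,
    init_params,
    load_checkpoint,
    loss,
    loss_and_grads,
    predict_probs,
    save_checkpoint,
    softmax,
    train,
)


class TestInitParams:
    def test_seed_determinism(self):
        a = init_params(11, 8, 5, seed=3)
        b = init_params(11, 8, 5, seed=3)
        assert all((a[k] == b[k]).all() for k in a)

    def test_shapes(self):
        p = init_params(11, 128, 5, seed=0)
        for d in ("f", "b"):
            assert p[f"{d}_Wxz"].shape == (11, 128)
            assert p[f"{d}_Whh"].shape == (128, 128)
            assert p[f"{d}_bz"].shape == (128,)
        assert p["Wyh"].shape == (256, 5) and p["by"].shape == (5,)

    def test_different_seeds_differ(self):
        a = init_params(11, 8, 5, seed=0)
        b = init_params(11, 8, 5, seed=1)
        assert (a["f_Wxz"] != b["f_Wxz"]).any()


class TestGruStep:
    def test_zero_params_zero_state(self):
        p = {k: np.zeros_like(v) for k, v in direction_view(init_params(4, 3, 5, 0), "f").items()}
        h = gru_step(p, np.zeros(4), np.zeros(3))
        assert np.allclose(h, 0.0)  # Z=R=0.5, candidate tanh(0)=0

    def test_saturated_update_gate_freezes_state(self):
        p = {k: np.zeros_like(v) for k, v in direction_view(init_params(4, 3, 5, 0), "f").items()}
        p["bz"] = np.full(3, 50.0)  # Z -> 1: H_t == H_{t-1}
        h_prev = np.array([0.3, -0.7, 0.1])
        h = gru_step(p, np.ones(4), h_prev)
        assert np.allclose(h, h_prev, atol=1e-12)

    def test_matches_elementwise_oracle(self):
        """Dense-matrix step equals a scalar-loop reimplementation."""
        rng = np.random.default_rng(5)
        d, H = 3, 4
        p = direction_view(init_params(d, H, 5, seed=5), "f")
        for k in ("bz", "br", "bh"):
            p[k] = rng.normal(size=H)
        x = rng.normal(size=d)
        h_prev = rng.normal(size=H)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        expected = np.zeros(H)
        for j in range(H):
            z = sig(sum(x[i] * p["Wxz"][i, j] for i in range(d))
                    + sum(h_prev[i] * p["Whz"][i, j] for i in range(H)) + p["bz"][j])
            r_row = [
                sig(sum(x[i] * p["Wxr"][i, jj] for i in range(d))
                    + sum(h_prev[i] * p["Whr"][i, jj] for i in range(H)) + p["br"][jj])
                for jj in range(H)
            ]
            hc = np.tanh(sum(x[i] * p["Wxh"][i, j] for i in range(d))
                         + sum(r_row[i] * h_prev[i] * p["Whh"][i, j] for i in range(H))
                         + p["bh"][j])
            expected[j] = z * h_prev[j] + (1 - z) * hc
        assert np.allclose(gru_step(p, x, h_prev), expected, atol=1e-10)

    def test_shape_mismatch_raises(self):
        p = direction_view(init_params(4, 3, 5, 0), "f")
        with pytest.raises(ValueError):
            gru_step(p, np.zeros(5), np.zeros(3))


class TestBigruForward:
    def test_single_position(self):
        p = init_params(4, 3, 5, seed=1)
        X = np.random.default_rng(0).normal(size=(1, 4))
        hidden = bigru_forward(p, X)
        assert hidden.shape == (1, 6)
        # T=1: both passes see the same single input from zero state
        pf, pb = direction_view(p, "f"), direction_view(p, "b")
        assert np.allclose(hidden[0, :3], gru_step(pf, X[0], np.zeros(3)))
        assert np.allclose(hidden[0, 3:], gru_step(pb, X[0], np.zeros(3)))

    def test_zero_params_all_zero_hidden(self):
        p = {k: np.zeros_like(v) for k, v in init_params(4, 3, 5, 0).items()}
        hidden = bigru_forward(p, np.ones((7, 4)))
        assert np.allclose(hidden, 0.0)

    def test_palindrome_symmetry_with_shared_directions(self):
        """If both directions share weights, a palindromic input yields a
        mirror-symmetric hidden sequence with the halves swapped."""
        p = init_params(4, 3, 5, seed=2)
        for k in ("Wxz", "Wxr", "Wxh", "Whz", "Whr", "Whh", "bz", "br", "bh"):
            p[f"b_{k}"] = p[f"f_{k}"].copy()
        rng = np.random.default_rng(3)
        half = rng.normal(size=(4, 4))
        X = np.concatenate([half, half[::-1]])
        hidden = bigru_forward(p, X)
        fwd, bwd = hidden[:, :3], hidden[:, 3:]
        assert np.allclose(fwd, bwd[::-1], atol=1e-12)

    def test_batch_matches_single(self):
        p = init_params(4, 3, 5, seed=4)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3, 6, 4))
        batched = bigru_forward(p, X)
        for b in range(3):
            assert np.allclose(batched[b], bigru_forward(p, X[b]))


class TestPredictProbsAndLoss:
    def test_rows_sum_to_one(self):
        p = init_params(4, 3, 5, seed=0)
        probs = predict_probs(p, np.random.default_rng(1).normal(size=(9, 4)))
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-9)
        assert ((probs > 0) & (probs < 1)).all()

    def test_zero_logits_uniform(self):
        assert np.allclose(softmax(np.zeros((2, 5))), 0.2)

    def test_closed_form_softmax(self):
        row = softmax(np.array([1.0, 0, 0, 0, 0]))
        e = np.e
        assert row[0] == pytest.approx(e / (e + 4), abs=1e-12)
        assert np.allclose(row[1:], 1 / (e + 4))
        assert row[0] == pytest.approx(0.4046, abs=5e-5)

    def test_shift_invariance(self):
        logits = np.random.default_rng(2).normal(size=(4, 5))
        assert np.allclose(softmax(logits), softmax(logits + 100.0))

    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(5)[np.array([0, 2, 4])]
        assert loss(probs, np.array([0, 2, 4])) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_ln5(self):
        probs = np.full((6, 5), 0.2)
        assert loss(probs, np.arange(6) % 5) == pytest.approx(np.log(5), abs=1e-12)

    def test_pad_positions_ignored(self):
        probs = np.full((4, 5), 0.2)
        labels = np.array([1, -1, 2, -1])
        assert loss(probs, labels) == pytest.approx(np.log(5))
        with pytest.raises(ValueError):
            loss(probs, np.full(4, -1))


class TestGradients:
    def test_gradcheck_all_tensors(self):
        """Analytic BPTT gradients match central finite differences."""
        rng = np.random.default_rng(0)
        params = init_params(4, 3, 5, seed=1)
        X = rng.normal(size=(2, 5, 4))
        y = rng.integers(0, 5, size=(2, 5))
        y[0, 2] = -1  # a PAD position
        _, grads = loss_and_grads(params, X, y)
        eps = 1e-6
        for key, W in params.items():
            numeric = np.zeros_like(W)
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = W[i]
                W[i] = orig + eps
                lp, _ = loss_and_grads(params, X, y)
                W[i] = orig - eps
                lm, _ = loss_and_grads(params, X, y)
                W[i] = orig
                numeric[i] = (lp - lm) / (2 * eps)
            scale = max(np.abs(numeric).max(), np.abs(grads[key]).max(), 1e-8)
            rel = np.abs(numeric - grads[key]).max() / scale
            assert rel < 1e-4, f"{key}: rel err {rel}"


class TestTraining:
    def test_adam_decreases_loss_on_toy_problem(self):
        rng = np.random.default_rng(0)
        params = init_params(3, 4, 5, seed=0)
        opt = Adam(params, lr=1e-2)
        X = rng.normal(size=(4, 6, 3))
        y = rng.integers(0, 5, size=(4, 6))
        first = None
        for _ in range(50):
            lval, grads = loss_and_grads(params, X, y)
            first = first if first is not None else lval
            opt.step(params, grads)
        assert lval < first * 0.5

    def test_patience_with_frozen_learning(self, small_sim):
        """With lr = 0 the monitored loss never improves after epoch 1, so
        training halts exactly patience epochs later."""
        from hybrec.windowing import segment

        windows = segment(small_sim["encoded"][0])
        cfg = TrainConfig(hidden=4, learning_rate=0.0, max_epochs=50, patience=5, seed=0)
        _, hist = train(windows, cfg)
        assert hist.epochs == 1 + cfg.patience

    def test_epoch_cap_respected(self, small_sim):
        from hybrec.windowing import segment

        windows = segment(small_sim["encoded"][0])
        cfg = TrainConfig(hidden=4, max_epochs=3, patience=5, seed=0)
        _, hist = train(windows, cfg)
        assert hist.epochs <= 3
        assert len(hist.val_loss) == hist.epochs

    def test_noise_free_task_is_learned_nearly_perfectly(self):
        """Labels on a noise-free dataset are a deterministic function of
        the feature vector, so training should drive train accuracy to
        >= 99.9%."""
        from hybrec.alignment_io import build_pileup
        from hybrec.encoding import encode_read
        from hybrec.synthetic_data import ErrorProfile
        from hybrec.windowing import segment
        from conftest import make_sim

        zero = ErrorProfile(0, 0, 0)
        sim = make_sim(seed=7, genome_length=6000, n_long=3, long_mean=1500,
                       long_profile=zero, short_profile=zero)
        by_t = {}
        for a in sim["alignments"]:
            by_t.setdefault(a.target_id, []).append(a)
        encoded = [
            encode_read(build_pileup(r, by_t.get(r.id, [])), None, r)
            for r in sim["long_reads"]
        ]
        windows = [w for e in encoded for w in segment(e)]
        cfg = TrainConfig(hidden=48, batch_size=2, max_epochs=60, seed=7)
        _, hist = train(windows, cfg)
        assert hist.train_acc[-1] >= 0.999

    def test_loss_improves_over_epochs(self, small_sim):
        from hybrec.windowing import segment

        windows = [w for e in small_sim["encoded"] for w in segment(e)]
        cfg = TrainConfig(hidden=8, batch_size=4, max_epochs=5, patience=5, seed=1)
        _, hist = train(windows, cfg)
        assert hist.train_loss[4] < hist.train_loss[0]

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = TrainConfig(hidden=6, seed=9)
        params = init_params(11, 6, 5, seed=9)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg)
        loaded, loaded_cfg = load_checkpoint(path)
        assert loaded_cfg.hidden == 6 and loaded_cfg.seed == 9
        assert all((loaded[k] == params[k]).all() for k in params)
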