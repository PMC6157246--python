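import numpy as np
import pytest

from sirnadeep import model as M
from sirnadeep.encoding import encode_window
from sirnadeep.model import (
    ModelConfig,
    TrainedModel,
    activate,
    convolve,
    pool,
    reference_config,
    select_kernel_set,
    train,
)
from sirnadeep.records_io import extract_window
from sirnadeep.synthetic_data import SyntheticSpec, generate

from conftest import make_record


def brute_force_convolve(S, kernel, scale):
    m = kernel.shape[0]
    out = []
    for p in range(S.shape[0] - m + 1):
        acc = 0.0
        for j in range(m):
            for i in range(4):
                acc += S[p + j, i] * kernel[j, i]
        out.append(scale * acc)
    return np.array(out)


class TestConvolve:
    def test_zero_kernel_gives_zero_map(self):
        enc = encode_window("AUGC" * 5 + "A", 0)
        np.testing.assert_array_equal(convolve(enc, np.zeros((4, 4))), np.zeros(18))

    def test_feature_map_length_is_22_minus_m_for_bare_21mer(self, rng):
        enc = encode_window("A" * 21, 0)
        out = convolve(enc, rng.normal(size=(15, 4)))
        assert out.shape == (7,)  # 22 - 15

    def test_matches_brute_force_sliding_window(self, rng):
        for _ in range(10):
            n = int(rng.integers(0, 4))
            window = "".join(rng.choice(list("AUGC"), size=21 + 2 * n))
            enc = encode_window(window, n)
            m = int(rng.integers(2, 9))
            kernel = rng.normal(size=(m, 4))
            scale = float(rng.uniform(0.5, 2.0))
            np.testing.assert_allclose(
                convolve(enc, kernel, scale),
                brute_force_convolve(enc.matrix, kernel, scale),
                rtol=1e-12,
            )

    def test_one_hot_kernel_peaks_at_planted_motif(self):
        motif = "GAUC"
        window = "A" * 8 + motif + "A" * 9  # motif at position 8
        enc = encode_window(window, 0)
        kernel = encode_window(motif + "A" * 17, 0).matrix[:4]  # one-hot motif kernel
        out = convolve(enc, kernel, scale=2.0)
        assert int(np.argmax(out)) == 8
        assert out[8] == pytest.approx(4 * 2.0)  # m * delta

    def test_kernel_taller_than_input_raises(self):
        enc = encode_window("A" * 21, 0)
        with pytest.raises(ValueError, match="exceeds"):
            convolve(enc, np.zeros((22, 4)))


class TestActivatePool:
    @pytest.mark.parametrize(
        "x,fn,expected", [(-3.0, "relu", 0.0), (2.5, "relu", 2.5), (0.0, "sigmoid", 0.5)]
    )
    def test_pointwise_values(self, x, fn, expected):
        assert activate(np.array([x]), fn)[0] == pytest.approx(expected)

    def test_pool_is_global_max_and_mean(self):
        assert pool(np.array([0.0, 1.0, 2.0, 3.0])) == (3.0, 1.5)
        assert pool(np.full(5, 2.5)) == (2.5, 2.5)

    def test_pool_rejects_empty_map(self):
        with pytest.raises(ValueError):
            pool(np.array([]))

    def test_post_relu_pool_ordering(self, rng):
        for _ in range(20):
            fm = activate(rng.normal(size=rng.integers(1, 30)), "relu")
            y_max, y_avg = pool(fm)
            assert y_max >= y_avg >= 0.0


class TestDimensions:
    def test_reference_config_dimensional_facts(self):
        cfg = reference_config()
        assert cfg.n_kernels == 15
        assert cfg.pooled_dim == 30
        assert cfg.merged_dim == 50

    @pytest.mark.parametrize("heights,per", [([2], 1), ([3, 5, 7], 2), (range(2, 21), 1)])
    def test_pooled_dim_is_twice_kernel_count(self, heights, per):
        cfg = ModelConfig(kernel_heights=heights, kernels_per_height=per)
        assert cfg.pooled_dim == 2 * cfg.n_kernels

    @pytest.mark.parametrize("m", [1, 21, 0])
    def test_kernel_height_outside_2_20_rejected(self, m):
        with pytest.raises(ValueError):
            ModelConfig(kernel_heights=[m])


def tiny_config(**overrides):
    kwargs = dict(
        kernel_heights=[3, 5],
        flank_n=3,
        dnn_units=4,
        max_iterations=60,
        learning_rate=0.1,
        seed=5,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture(scope="module")
def tiny_data(nn_params):
    spec = SyntheticSpec(n_records=40, flank_n=3, motif="GAU", seed=9)
    records, _ = generate(spec, nn_params)
    return records


class TestForward:
    def test_output_strictly_in_unit_interval(self, nn_params, tiny_data):
        model = train(tiny_data, tiny_config(max_iterations=10), nn_params)
        preds = M.predict(tiny_data, model, nn_params)
        assert np.all(preds > 0) and np.all(preds < 1)

    def test_zero_output_weights_predict_half(self, nn_params, tiny_data):
        model = train(tiny_data, tiny_config(max_iterations=1), nn_params)
        model.network.params["w2"][:] = 0.0
        assert M.forward(tiny_data[0], model, nn_params) == pytest.approx(0.5)

    def test_matches_step_by_step_hand_computation(self, nn_params, tiny_data):
        """Scalar-by-scalar oracle: one 3-high kernel, 2 hidden units."""
        cfg = tiny_config(kernel_heights=[3], dnn_units=2, max_iterations=3)
        batch = tiny_data[:3]
        model = train(batch, cfg, nn_params)
        net = model.network
        p = net.params
        from sirnadeep.thermo import featurize_thermo

        merged_rows = []
        for rec in batch:
            enc = encode_window(extract_window(rec, cfg.flank_n), cfg.flank_n)
            fm = brute_force_convolve(enc.matrix, p["M3"][:, 0].reshape(3, 4), p["delta3"][0])
            a = np.maximum(0.0, fm)
            merged_rows.append(
                np.concatenate(([a.max(), a.mean()], featurize_thermo(rec, nn_params).flatten()))
            )
        merged = np.array(merged_rows)
        xhat = (merged - net.bn_mean) / np.sqrt(net.bn_var + 1e-5)
        zbn = p["gamma"] * xhat + p["beta"]
        h = 1.0 / (1.0 + np.exp(-(zbn @ p["W1"] + p["b1"])))
        expected = 1.0 / (1.0 + np.exp(-(h @ p["w2"])))
        np.testing.assert_allclose(M.predict(batch, model, nn_params), expected, rtol=1e-10)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, nn_params, tiny_data):
        cfg = tiny_config(kernel_heights=[2, 4], dnn_units=3)
        batch = tiny_data[:8]
        windows, thermo = M._prepare_inputs(batch, cfg, nn_params)
        y = M._labels(batch)
        net = M._Network(cfg, np.random.default_rng(17))
        _, grads = net.loss_and_grads(windows, thermo, y)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for key, p in net.params.items():
            for i in rng.choice(p.size, size=min(6, p.size), replace=False):
                orig = p.flat[i]
                p.flat[i] = orig + eps
                lp, _ = net.loss_and_grads(windows, thermo, y)
                p.flat[i] = orig - eps
                lm, _ = net.loss_and_grads(windows, thermo, y)
                p.flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].flat[i]
                denom = max(1e-8, abs(numeric) + abs(analytic))
                assert abs(numeric - analytic) / denom <= 1e-4, key


class TestTraining:
    def test_same_seed_gives_bit_identical_training_log(self, nn_params, tiny_data):
        cfg = tiny_config(max_iterations=20)
        a = train(tiny_data, cfg, nn_params)
        b = train(tiny_data, cfg, nn_params)
        assert a.training_log == b.training_log

    def test_loss_decreases_over_training(self, nn_params, tiny_data):
        model = train(tiny_data, tiny_config(), nn_params)
        assert model.training_log[-1] < model.training_log[0]

    def test_constant_target_converges_below_tolerance(self, nn_params, tiny_data):
        from dataclasses import replace

        records = [replace(r, efficacy=0.62) for r in tiny_data[:6]]
        model = train(records, tiny_config(max_iterations=800), nn_params)
        assert model.training_log[-1] < model.config.error_tolerance
        preds = M.predict(records, model, nn_params)
        np.testing.assert_allclose(preds, 0.62, atol=0.05)

    def test_unlabeled_records_rejected(self, nn_params):
        records = [make_record("u", efficacy=None), make_record("v", efficacy=None)]
        with pytest.raises(ValueError, match="efficacy"):
            train(records, tiny_config(), nn_params)

    def test_tiny_learning_rate_converges_slower(self, nn_params):
        """At a fixed iteration budget, lr 0.001 ends at a higher training
        loss than lr 0.1 — the slow-convergence side of the learning-rate
        trade-off — as a tendency over seeds."""
        wins = 0
        for seed in range(5):
            spec = SyntheticSpec(n_records=60, flank_n=3, motif="GAU", seed=100 + seed)
            records, _ = generate(spec, load_params_cached())
            losses = {}
            for lr in (0.1, 0.001):
                cfg = tiny_config(learning_rate=lr, seed=seed, max_iterations=80)
                losses[lr] = train(records, cfg, load_params_cached()).training_log[-1]
            wins += losses[0.001] >= losses[0.1]
        assert wins >= 4


_params_cache = {}


def load_params_cached():
    if "p" not in _params_cache:
        from sirnadeep.thermo import load_default_params

        _params_cache["p"] = load_default_params()
    return _params_cache["p"]


class TestSerialization:
    def test_save_load_round_trip_preserves_predictions(self, nn_params, tiny_data, tmp_path):
        model = train(tiny_data, tiny_config(max_iterations=15), nn_params)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(
            M.predict(tiny_data, model, nn_params), M.predict(tiny_data, loaded, nn_params)
        )
        assert loaded.config == model.config


class TestKernelSetSelection:
    def test_threshold_extremes(self, nn_params, tiny_data):
        base = tiny_config(max_iterations=5)
        common = dict(base_config=base, k=2, seed=0)
        assert select_kernel_set(tiny_data, [3, 5], nn_params, threshold=1.1, **common) == []
        assert select_kernel_set(tiny_data, [3, 5], nn_params, threshold=-1.1, **common) == [3, 5]

    def test_empty_candidates_rejected(self, nn_params, tiny_data):
        with pytest.raises(ValueError):
            select_kernel_set(tiny_data, [], nn_params)
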