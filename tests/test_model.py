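import numpy as np
import pytest

from explainn.model import (ModelConfig, build_model,
                            build_global_maxpool_variant, conv_geometry,
                            plug_unit, ConstantSubmodel, LinearSubmodel,
                            ConfigurationError, ShapeError, ExplaiNNModel)
from explainn.train import mse_loss
from explainn._nn import Adam

from conftest import random_onehot


# -- geometry ---------------------------------------------------------------

@pytest.mark.parametrize("args, expected", [
    ((200, 19, 7, 7), (182, 26)),
    ((201, 19, 7, 7), (183, 26)),
    ((600, 19, 7, 7), (582, 83)),
    ((19, 19, 1, 1), (1, 1)),
])
def test_conv_geometry_examples(args, expected):
    assert conv_geometry(*args) == expected


def test_conv_geometry_rejects_short_input():
    with pytest.raises(ConfigurationError, match="pool_size"):
        conv_geometry(19, 19, 7, 7)
    with pytest.raises(ConfigurationError):
        ModelConfig(num_units=1, input_length=19, num_tasks=1).validate()


def test_geometry_matches_observed_shapes():
    gen = np.random.default_rng(3)
    for _ in range(20):
        W = int(gen.integers(4, 20))
        L = int(gen.integers(W + 7, W + 60))
        conv_len, pooled_len = conv_geometry(L, W, 7, 7)
        cfg = ModelConfig(num_units=2, input_length=L, num_tasks=1,
                          filter_width=W, fc_hidden=4)
        model = build_model(cfg, seed=0)
        act = model.conv_activations(random_onehot(3, L, seed=1))
        assert act.shape == (3, conv_len, 2)
        assert model.params["fc1_w"].shape == (2, pooled_len, 4)


def test_fc_input_width_for_default_config():
    cfg = ModelConfig(num_units=100, input_length=200, num_tasks=50)
    assert cfg.pooled_len == 26
    cfg = ModelConfig(num_units=400, input_length=600, num_tasks=12)
    assert cfg.pooled_len == 83


# -- forward contract -------------------------------------------------------

def test_additivity_and_determinism(tiny_model):
    x = random_onehot(16, 40, seed=2)
    pred, units = tiny_model.forward(x)
    recon = units @ tiny_model.params["final_w"] + tiny_model.params["final_b"]
    assert np.abs(pred - recon).max() <= 1e-5
    pred2, units2 = tiny_model.forward(x)
    assert np.array_equal(pred, pred2) and np.array_equal(units, units2)


def test_zero_weights_give_bias(tiny_model):
    tiny_model.params["final_w"][:] = 0.0
    tiny_model.params["final_b"][:] = [0.5, -1.5]
    pred, _ = tiny_model.forward(random_onehot(5, 40, seed=3))
    assert np.allclose(pred, [0.5, -1.5])


def test_seed_reproducibility():
    cfg = ModelConfig(num_units=4, input_length=50, num_tasks=2)
    a, b = build_model(cfg, seed=9), build_model(cfg, seed=9)
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    c = build_model(cfg, seed=10)
    assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


def test_unit_outputs_are_rectified(tiny_model):
    _, units = tiny_model.forward(random_onehot(20, 40, seed=4))
    assert (units >= 0).all()


def test_unit_independence(tiny_model):
    """Perturbing one unit's parameters leaves every other unit's output
    unchanged on a probe batch."""
    x = random_onehot(100, 40, seed=5)
    # an untrained model's rectified unit outputs can be identically zero;
    # shift the last batch-norm so every unit is alive before perturbing
    tiny_model.bn2.beta += 1.0
    _, before = tiny_model.forward(x)
    tiny_model.params["filters"][1] += 0.37
    tiny_model.params["fc1_w"][1] -= 0.11
    _, after = tiny_model.forward(x)
    others = [0, 2]
    assert np.abs(after[:, others] - before[:, others]).max() == 0.0
    assert np.abs(after[:, 1] - before[:, 1]).max() > 0.0


def test_shape_error_names_sequence(tiny_model):
    with pytest.raises(ShapeError, match="length 39"):
        tiny_model.forward(random_onehot(2, 39, seed=0))


# -- global max pool variant ------------------------------------------------

def test_gmp_unit_equals_bruteforce_window_scan():
    cfg = ModelConfig(num_units=1, input_length=30, num_tasks=1,
                      filter_width=5)
    model = build_global_maxpool_variant(cfg, seed=1)
    x = random_onehot(5, 30, seed=6)
    _, units = model.forward(x)
    # brute force: per window, conv score -> eval-mode BN -> exp -> max
    filt = model.params["filters"][0]
    bn = model.bn0
    for n in range(5):
        scores = [np.sum(x[n, p:p + 5, :].T * filt) for p in range(26)]
        z = (np.array(scores) - bn.running_mean[0]) / np.sqrt(
            bn.running_var[0] + 1e-5)
        z = bn.gamma[0] * z + bn.beta[0]
        expected = np.exp(np.minimum(z, 20.0)).max()
        assert units[n, 0] == pytest.approx(expected, rel=1e-12)


def test_gmp_constant_for_zero_filter():
    cfg = ModelConfig(num_units=1, input_length=40, num_tasks=1)
    model = build_global_maxpool_variant(cfg, seed=2)
    model.params["filters"][:] = 0.0
    _, units = model.forward(random_onehot(6, 40, seed=7))
    assert np.ptp(units[:, 0]) == 0.0


# -- pluggable units --------------------------------------------------------

def test_plugged_stub_arithmetic():
    cfg = ModelConfig(num_units=2, input_length=40, num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=0)
    model = plug_unit(model, 0, ConstantSubmodel(1.0), head="none")
    model = plug_unit(model, 1, ConstantSubmodel(2.0), head="none")
    model.params["final_w"][:, 0] = [0.5, -1.0]
    model.params["final_b"][:] = 0.1
    pred, units = model.forward(random_onehot(3, 40, seed=8))
    assert np.allclose(units, [1.0, 2.0])
    assert np.allclose(pred, -1.4)


def test_plug_freeze_contract():
    from explainn.data import LabeledDataset
    from explainn.train import TrainConfig, train
    from conftest import random_sequences

    cfg = ModelConfig(num_units=2, input_length=30, num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=0)
    sub = LinearSubmodel(np.full((30, 4), 0.1), bias=0.2)
    model = plug_unit(model, 0, sub, freeze=True, head="none")
    plugged_sub = model.plugged[0].submodel
    weights_before = plugged_sub.weights.copy()
    final_before = model.params["final_w"].copy()

    seqs = random_sequences(40, 30, seed=1)
    labels = np.random.default_rng(2).normal(size=(40, 1))
    ds = LabeledDataset(ids=[f"s{i}" for i in range(40)], sequences=seqs,
                        labels=labels, task_type="regression")
    tcfg = TrainConfig(max_epochs=5, patience=10, batch_size=10,
                       rc_augment=False, seed=0)
    model, _ = train(model, ds, ds, tcfg)
    assert np.array_equal(model.plugged[0].submodel.weights, weights_before)
    assert np.abs(model.params["final_w"] - final_before).max() > 0.0


def test_plug_head_changes_output():
    cfg = ModelConfig(num_units=1, input_length=40, num_tasks=1, fc_hidden=4)
    model = plug_unit(build_model(cfg, seed=0), 0, ConstantSubmodel(3.0),
                      head="fc_head_200")
    _, units = model.forward(random_onehot(4, 40, seed=9))
    assert not np.allclose(units, 3.0)
    assert np.ptp(units[:, 0]) == 0.0  # constant input -> constant output


def test_plugged_predictions_recoverable_as_linear_map():
    """With two linear stub units and head=none the model's prediction is an
    exact linear map of the stub scores."""
    gen = np.random.default_rng(10)
    w1, w2 = gen.normal(size=(30, 4)), gen.normal(size=(30, 4))
    cfg = ModelConfig(num_units=2, input_length=30, num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=0)
    model = plug_unit(model, 0, LinearSubmodel(w1), head="none")
    model = plug_unit(model, 1, LinearSubmodel(w2), head="none")
    x = random_onehot(10, 30, seed=11)
    pred, _ = model.forward(x)
    s1 = np.einsum("nla,la->n", x, w1)
    s2 = np.einsum("nla,la->n", x, w2)
    design = np.column_stack([s1, s2, np.ones(10)])
    coef, res, *_ = np.linalg.lstsq(design, pred[:, 0], rcond=None)
    fitted = design @ coef
    assert np.abs(fitted - pred[:, 0]).max() < 1e-8


def test_plug_rejects_wrong_input_length(tiny_model):
    with pytest.raises(ShapeError):
        plug_unit(tiny_model, 0, ConstantSubmodel(1.0, input_length=99))
    with pytest.raises(IndexError):
        plug_unit(tiny_model, 5, ConstantSubmodel(1.0))


# -- gradients and training step -------------------------------------------

def test_backward_matches_finite_differences():
    cfg = ModelConfig(num_units=2, input_length=30, num_tasks=1, fc_hidden=5,
                      dropout_rate=0.0)
    model = build_model(cfg, seed=3)
    x = random_onehot(6, 30, seed=1)
    y = np.random.default_rng(2).normal(size=(6, 1))

    def loss():
        pred, _ = model.forward(x, training=True,
                                rng=np.random.default_rng(0))
        return mse_loss(pred, y)

    _, dpred = loss()
    grads = model.backward(dpred)
    params = model.trainable_parameters()
    gen = np.random.default_rng(5)
    for name in ["filters", "fc1_w", "fc2_w", "final_w", "bn0_gamma",
                 "bn1_beta", "bn2_gamma"]:
        p = params[name]
        for _ in range(3):
            idx = tuple(gen.integers(0, s) for s in p.shape)
            orig = p[idx]
            eps = 1e-5
            p[idx] = orig + eps
            lp, _ = loss()
            p[idx] = orig - eps
            lm, _ = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name][idx]
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7), name


def test_frozen_filters_receive_zero_gradient():
    cfg = ModelConfig(num_units=2, input_length=30, num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=0)
    model.frozen_filter_mask[0] = True
    x = random_onehot(6, 30, seed=1)
    y = np.zeros((6, 1))
    pred, _ = model.forward(x, training=True, rng=np.random.default_rng(0))
    _, dpred = mse_loss(pred, y)
    grads = model.backward(dpred)
    assert np.all(grads["filters"][0] == 0.0)
    assert np.any(grads["filters"][1] != 0.0)


# -- persistence -------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path, tiny_model):
    x = random_onehot(4, 40, seed=12)
    pred, _ = tiny_model.forward(x)
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = ExplaiNNModel.load(path)
    pred2, _ = loaded.forward(x)
    assert np.array_equal(pred, pred2)
    assert loaded.config == tiny_model.config
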