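import numpy as np
import pytest

from explainn.model import (ModelConfig, build_model, plug_unit,
                            ConstantSubmodel)
from explainn.interpret import (collect_activations, filter_to_pfm,
                                unit_importance, final_layer_weights,
                                nullify_unit, annotate_units,
                                correctness_matrix, parse_tomtom,
                                visualize_filters)
from explainn.motifs import pfm_to_pwm, PWM
from explainn.benchmarks import make_pwm
from explainn.filters_init import profile_to_filter
from explainn.encoding import one_hot_encode

from conftest import random_onehot, random_sequences


def motif_detector_model(consensus="GATTACAG", length=40, num_units=1,
                         seed=0):
    """A model whose first filter is an exact detector of the consensus
    (background-subtracted one-hot weights) with pass-through batch norm."""
    cfg = ModelConfig(num_units=num_units, input_length=length, num_tasks=1,
                      filter_width=len(consensus), fc_hidden=4)
    model = build_model(cfg, seed=seed)
    model.params["filters"][0] = profile_to_filter(
        make_pwm(consensus, dominance=0.97).probs)
    return model


# -- activation collection ----------------------------------------------------

def test_activations_match_bruteforce_windows():
    model = motif_detector_model()
    x = random_onehot(5, 40, seed=3)
    table = collect_activations(model, x)
    act = model.conv_activations(x)
    for n in range(5):
        for u in range(model.config.num_units):
            scores = act[n, :, u]
            assert table.values[n, u] == pytest.approx(scores.max())
            assert table.positions[n, u] == scores.argmax()
    assert np.allclose(table.unit_max, table.values.max(axis=0))
    assert (table.unit_max >= table.values).all()


def test_argmax_tie_resolves_to_lowest_position():
    model = motif_detector_model(consensus="AAAA", length=20)
    x = one_hot_encode("A" * 20).matrix[None]
    table = collect_activations(model, x)
    assert table.positions[0, 0] == 0


# -- filter -> PFM ------------------------------------------------------------

def planted_batch(consensus, n, length, seed=0):
    """Sequences with the consensus planted at known positions."""
    seqs = random_sequences(n, length, seed=seed)
    gen = np.random.default_rng(seed + 1)
    starts = gen.integers(0, length - len(consensus) + 1, size=n)
    seqs = [s[:p] + consensus + s[p + len(consensus):]
            for s, p in zip(seqs, starts)]
    x = np.stack([one_hot_encode(s).matrix for s in seqs])
    return x, starts


def test_filter_to_pfm_counts_argmax_windows():
    model = motif_detector_model(consensus="GATTACAG", length=40)
    x, starts = planted_batch("GATTACAG", 30, 40, seed=2)
    labels = np.ones((30, 1))
    preds = np.full((30, 1), 10.0)  # all correctly predicted positive
    pfm = filter_to_pfm(model, 0, x, preds, labels, fraction=0.5)
    assert pfm.n_sites > 0
    assert np.allclose(pfm.counts.sum(axis=0), pfm.n_sites)
    consensus_of_pfm = pfm_to_pwm(pfm).consensus()
    assert consensus_of_pfm == "GATTACAG"


def test_filter_to_pfm_hand_counts():
    """Three qualifying windows 'AAAA', 'AAAA', 'CAAA' -> first column
    counts (A:2, C:1)."""
    model = motif_detector_model(consensus="AAAA", length=12)
    seqs = ["AAAAGGGGGGGG", "GGGGAAAAGGGG", "CAAAGGGGGGGG"]
    # make "CAAA" the argmax window of sequence 3 by keeping it the only
    # A-rich window
    x = np.stack([one_hot_encode(s).matrix for s in seqs])
    labels = np.ones((3, 1))
    preds = np.full((3, 1), 5.0)
    pfm = filter_to_pfm(model, 0, x, preds, labels, fraction=0.0)
    assert pfm.n_sites == 3
    assert pfm.counts[0, 0] == 2 and pfm.counts[1, 0] == 1


def test_fraction_one_keeps_only_global_max():
    model = motif_detector_model(consensus="GATTACAG", length=40)
    x, _ = planted_batch("GATTACAG", 10, 40, seed=4)
    # weaken sequence activations by mutating one base in all but one
    x[1:, :, :] = random_onehot(9, 40, seed=5)
    labels = np.ones((10, 1))
    preds = np.full((10, 1), 5.0)
    pfm = filter_to_pfm(model, 0, x, preds, labels, fraction=1.0)
    assert pfm.n_sites == 1


def test_all_incorrect_gives_empty_pfm():
    model = motif_detector_model()
    x, _ = planted_batch("GATTACAG", 5, 40)
    labels = np.ones((5, 1))
    preds = np.full((5, 1), -10.0)  # all predicted negative -> all wrong
    pfm = filter_to_pfm(model, 0, x, preds, labels)
    assert pfm.is_empty


def test_raising_fraction_never_increases_sites():
    model = motif_detector_model()
    x, _ = planted_batch("GATTACAG", 40, 40, seed=6)
    labels = np.ones((40, 1))
    preds = np.full((40, 1), 5.0)
    sites = [filter_to_pfm(model, 0, x, preds, labels, fraction=f).n_sites
             for f in (0.0, 0.3, 0.5, 0.8, 1.0)]
    assert sites == sorted(sites, reverse=True)


# -- correctness predicates ---------------------------------------------------

def test_binary_correctness():
    preds = np.array([[5.0, -5.0], [-5.0, -5.0]])
    labels = np.array([[1.0, 0.0], [1.0, 0.0]])
    correct = correctness_matrix(preds, labels, "binary_multitask")
    assert correct.tolist() == [[True, True], [False, True]]


def test_multiclass_correctness():
    preds = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 2.0]])
    labels = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    correct = correctness_matrix(preds, labels, "multiclass")
    assert correct[0].all() and not correct[1].any()


def test_regression_correctness_multitask():
    preds = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    labels = np.array([[1.1, 2.1, 3.1], [3.0, 2.0, 1.0]])
    correct = correctness_matrix(preds, labels, "regression")
    assert correct[0].all() and not correct[1].any()


# -- importance and nullification ---------------------------------------------

def stub_model(values, weights, bias=0.0, length=40):
    """A model whose unit outputs are fixed constants via plugged stubs."""
    cfg = ModelConfig(num_units=len(values), input_length=length,
                      num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=0)
    for u, v in enumerate(values):
        model = plug_unit(model, u, ConstantSubmodel(v), head="none")
    model.params["final_w"][:, 0] = weights
    model.params["final_b"][:] = bias
    return model


def test_importance_single_product():
    model = stub_model([2.0], [0.5])
    x = random_onehot(1, 40, seed=0)
    preds, _ = model.forward(x)
    labels = (preds > 0).astype(float)
    imp = unit_importance(model, x, preds, labels)
    assert imp.medians[0, 0] == pytest.approx(1.0)


def test_importance_sign_follows_weight():
    model = stub_model([2.0, 3.0], [-0.5, 1.0])
    x = random_onehot(6, 40, seed=1)
    preds, _ = model.forward(x)
    labels = (preds > 0).astype(float)
    imp = unit_importance(model, x, preds, labels)
    assert imp.medians[0, 0] == pytest.approx(-1.0)
    assert imp.medians[1, 0] == pytest.approx(3.0)


def test_importance_median_of_hand_pairs():
    """Five activation values x one weight: the median product equals the
    hand-sorted middle value."""
    cfg = ModelConfig(num_units=1, input_length=40, num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=0)

    class Cycler(ConstantSubmodel):
        def __init__(self, values):
            super().__init__(0.0)
            self.values = np.asarray(values, dtype=float)

        def forward(self, x, training):
            return self.values[: x.shape[0]]

    model = plug_unit(model, 0, Cycler([1.0, 5.0, 2.0, 4.0, 3.0]),
                      head="none")
    model.params["final_w"][:, 0] = 2.0
    model.params["final_b"][:] = 0.0
    x = random_onehot(5, 40, seed=2)
    preds, _ = model.forward(x)
    labels = (preds > 0).astype(float)
    imp = unit_importance(model, x, preds, labels, fraction=0.0)
    assert imp.medians[0, 0] == pytest.approx(6.0)  # median(2,10,4,8,6)


def test_importance_empty_set_flagged_not_zero():
    model = stub_model([2.0], [0.5])
    x = random_onehot(4, 40, seed=3)
    preds, _ = model.forward(x)
    labels = 1.0 - (preds > 0).astype(float)  # all incorrect
    imp = unit_importance(model, x, preds, labels)
    assert not imp.defined[0, 0]
    assert np.isnan(imp.medians[0, 0])


def test_nullify_single_unit_model_leaves_bias(tiny_model):
    cfg = ModelConfig(num_units=1, input_length=40, num_tasks=1, fc_hidden=4)
    model = build_model(cfg, seed=1)
    model.params["final_b"][:] = 0.7
    nulled = nullify_unit(model, 0)
    pred, _ = nulled.forward(random_onehot(5, 40, seed=4))
    assert np.allclose(pred, 0.7)
    # the original is untouched
    assert np.any(model.params["final_w"] != 0)


def test_nullification_delta_identity(tiny_model):
    x = random_onehot(20, 40, seed=5)
    base, units = tiny_model.forward(x)
    w, _ = final_layer_weights(tiny_model)
    for u in range(3):
        null_pred, _ = nullify_unit(tiny_model, u).forward(x)
        expected = -units[:, u:u + 1] * w[u][None, :]
        assert np.abs((null_pred - base) - expected).max() < 1e-12


def test_nullify_rejects_bad_index(tiny_model):
    with pytest.raises(IndexError):
        nullify_unit(tiny_model, 3)


# -- annotation ----------------------------------------------------------------

def test_annotation_self_match():
    db = [make_pwm("GATTACAG", id="M1"), make_pwm("CCACGTGA", id="M2")]
    anns = annotate_units([db[0]], db, threshold=0.8)
    assert anns[0].motif_ids[0] == "M1"
    assert anns[0].scores[0] == pytest.approx(1.0)


def test_annotation_strand_symmetric():
    db = [make_pwm("GATTACAG", id="M1")]
    query = db[0].reverse_complement()
    anns = annotate_units([query], db, threshold=0.8)
    assert anns[0].motif_ids == ["M1"]
    assert anns[0].scores[0] == pytest.approx(1.0)


def test_uniform_query_unannotated():
    db = [make_pwm("GATTACAG", id="M1")]
    uniform = PWM(np.full((4, 8), 0.25))
    anns = annotate_units([uniform], db, threshold=0.8)
    assert anns[0].motif_ids == []


def test_tomtom_backend_missing_binary_is_actionable(monkeypatch):
    import shutil
    monkeypatch.setattr(shutil, "which", lambda name: None)
    with pytest.raises(RuntimeError, match="internal_similarity"):
        annotate_units([make_pwm("GATTACAG")], [], backend="tomtom_external")


def test_parse_tomtom_fixture():
    pwms = [make_pwm("GATTACAG", id="unit0"), make_pwm("CCACGTGA", id="unit1")]
    table = ("Query_ID\tTarget_ID\tOptimal_offset\tp-value\tE-value\tq-value\n"
             "unit0\tMA0001.1\t0\t1e-8\t1e-6\t0.001\n"
             "unit0\tMA0002.1\t1\t1e-3\t0.1\t0.2\n"
             "unit1\tMA0003.1\t0\t1e-5\t1e-3\t0.04\n")
    anns = parse_tomtom(table, pwms, qvalue_threshold=0.05)
    assert anns[0].motif_ids == ["MA0001.1"]  # 0.2 filtered out
    assert anns[1].motif_ids == ["MA0003.1"]
    assert anns[1].qvalues == [0.04]


# -- final layer ---------------------------------------------------------------

def test_final_layer_weights_shape_and_copy(tiny_model):
    w, b = final_layer_weights(tiny_model)
    assert w.shape == (3, 2) and b.shape == (2,)
    w[:] = 99.0
    assert not np.any(tiny_model.params["final_w"] == 99.0)
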