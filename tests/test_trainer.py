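"""Multitask optimization: reproducibility, contracts, and guards."""

import numpy as np
import pytest

from erfusion.graph import ERGraph
from erfusion.model import ERModel
from erfusion.synth import SyntheticSpec, generate_dti
from erfusion.trainer import TrainConfig, TrainError, evaluate, fit


def _small_dataset():
    spec = SyntheticSpec(n_drugs=60, n_proteins=50, n_cells=600, bias_scale=6.0)
    return generate_dti(spec, seed=21)


def _graph(ds):
    g = ERGraph()
    g.add_entity("drug", ds.spec.n_drugs)
    g.add_entity("protein", ds.spec.n_proteins, module_width=20)
    g.add_relation("dti", "drug", "protein", ds.cells, ds.values,
                   task="binary", main=True)
    return g


def test_training_reduces_loss_and_predictions_track_labels():
    ds = _small_dataset()
    m, h = fit(_graph(ds), config=TrainConfig(seed=1, epochs=50, patience=50))
    assert h.global_loss[-1] < h.global_loss[0]
    scores, probs, _ = m.predict("dti", ds.cells[:, 0], ds.cells[:, 1])
    pos = scores[ds.values == 1].mean()
    neg = scores[ds.values == 0].mean()
    assert pos > neg  # fitted scores separate the training labels


def test_loss_history_bit_identical_under_fixed_seed():
    ds = _small_dataset()
    _, h1 = fit(_graph(ds), config=TrainConfig(seed=7, epochs=20, patience=20))
    _, h2 = fit(_graph(ds), config=TrainConfig(seed=7, epochs=20, patience=20))
    assert h1.global_loss == h2.global_loss
    for r in h1.per_relation:
        assert h1.per_relation[r] == h2.per_relation[r]
    _, h3 = fit(_graph(ds), config=TrainConfig(seed=8, epochs=20, patience=20))
    assert h1.global_loss != h3.global_loss


def test_zero_epochs_is_a_no_op():
    ds = _small_dataset()
    m, h = fit(_graph(ds), config=TrainConfig(seed=5, epochs=0))
    fresh = ERModel(_graph(ds), seed=5)
    assert h.global_loss == []
    for p, q in zip(m.params(), fresh.params()):
        np.testing.assert_array_equal(p.value, q.value)


def test_empty_main_relation_is_an_error():
    ds = _small_dataset()
    with pytest.raises(TrainError):
        fit(_graph(ds), {"dti": np.array([], dtype=int)}, TrainConfig(epochs=1))


def test_diverging_loss_aborts_naming_the_relation():
    g = ERGraph()
    g.add_entity("drug", 10)
    g.add_entity("protein", 10, module_width=20)
    rng = np.random.default_rng(0)
    cells = np.column_stack([rng.integers(0, 10, 40), rng.integers(0, 10, 40)])
    cells = np.unique(cells, axis=0)
    g.add_relation("affinity", "drug", "protein", cells,
                   rng.normal(size=len(cells)), task="regression",
                   loss_id="mse", main=True)
    with pytest.raises(TrainError, match="affinity"):
        fit(g, config=TrainConfig(seed=0, epochs=50, learning_rate=1e200,
                                  weight_decay=0.0))


def test_predict_flags_untrained_instances():
    ds = _small_dataset()
    # hold out every cell touching drug 0
    mask = ds.cells[:, 0] != 0
    train_idx = np.flatnonzero(mask)
    m, _ = fit(_graph(ds), {"dti": train_idx}, TrainConfig(seed=2, epochs=5))
    scores, probs, untrained = m.predict("dti", [0, int(ds.cells[train_idx[0], 0])],
                                         [0, int(ds.cells[train_idx[0], 1])])
    assert untrained[0] and not untrained[1]
    assert np.isfinite(scores).all()
    assert (probs >= 0).all() and (probs <= 1).all()
    again, _, _ = m.predict("dti", [0, int(ds.cells[train_idx[0], 0])],
                            [0, int(ds.cells[train_idx[0], 1])])
    np.testing.assert_array_equal(scores, again)


def test_evaluate_guards_against_leakage():
    ds = _small_dataset()
    idx = np.arange(len(ds.cells))
    m, _ = fit(_graph(ds), {"dti": idx[:500]}, TrainConfig(seed=3, epochs=5))
    rep = evaluate(m, "dti", idx[500:])
    assert set(rep.folds[0]) == {"auc", "auprc", "precision", "recall"}
    with pytest.raises(TrainError, match="leakage"):
        evaluate(m, "dti", idx[499:])


def test_frozen_auxiliary_relation_is_skipped():
    ds = _small_dataset()
    g = _graph(ds)
    n = ds.spec.n_drugs
    r, c = np.divmod(np.arange(n * n), n)
    g.add_relation("dsim", "drug", "drug", np.column_stack([r, c]),
                   np.full(n * n, 0.5), task="regression", loss_id="mse")
    m, h = fit(g, {"dti": None, "dsim": np.array([], dtype=int)},
               TrainConfig(seed=1, epochs=3, patience=10))
    assert set(h.per_relation) == {"dti"}


def test_global_loss_weighting_and_masking(tiny_graph):
    m = ERModel(tiny_graph, seed=0)
    dti = tiny_graph.relations["dti"]
    dsim = tiny_graph.relations["dsim"]
    batch_dti = (dti.cells[:, 0], dti.cells[:, 1], dti.values)
    batch_sim = (dsim.cells[:, 0], dsim.cells[:, 1], dsim.values)
    a = m.relation_loss("dti", *batch_dti)
    b = m.relation_loss("dsim", *batch_sim)
    total = m.global_loss({"dti": batch_dti, "dsim": batch_sim})
    assert total == pytest.approx(1.0 * a + 0.7 * b)
    # permuting observed cells leaves the loss unchanged
    perm = np.array([3, 0, 2, 1])
    b_perm = m.relation_loss("dsim", dsim.cells[perm, 0], dsim.cells[perm, 1],
                             dsim.values[perm])
    assert b_perm == pytest.approx(b)
    # scaling one omega scales its contribution exactly
    dsim.weight = 1.4
    assert m.global_loss({"dti": batch_dti, "dsim": batch_sim}) == \
        pytest.approx(a + 1.4 * b)
    dsim.weight = 0.7
    with pytest.raises(ValueError, match="unobserved"):
        m.relation_loss("dti", [5], [5], [1.0])


def test_model_archive_round_trip(tmp_path):
    ds = _small_dataset()
    g = _graph(ds)
    m, _ = fit(g, config=TrainConfig(seed=6, epochs=3))
    path = tmp_path / "model.zip"
    m.save(path)
    m2 = ERModel.load(path, _graph(ds))
    np.testing.assert_array_equal(
        m.relation_score("dti", ds.cells[:10, 0], ds.cells[:10, 1]),
        m2.relation_score("dti", ds.cells[:10, 0], ds.cells[:10, 1]))
    assert m2.pos_weight == m.pos_weight
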