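"""Training harness: config validation, memorization oracle, plateau rule,
MCCV integration and determinism."""

import numpy as np
import pandas as pd
import pytest

from leakaudit.classifier import (TrainingConfig, NoduleClassifier,
                                  TrainingResults, train, evaluate_accuracy,
                                  TrainingError)
from leakaudit.splitting import mccv_schedule


def _blob_dataset(n=16, size=32, seed=0):
    """Tiny separable dataset: class 1 images carry a bright square."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.4, (n, size, size)).astype(np.float32)
    y = np.arange(n) % 2
    for i in np.flatnonzero(y == 1):
        r, c = rng.integers(4, size - 10, 2)
        x[i, r:r + 6, c:c + 6] += 0.5
    return np.clip(x, 0, 1), y


def _quick_config(**overrides):
    defaults = dict(learning_rate=1e-3, batch_size=8, n_epochs=8,
                    conv_channels=(4, 6, 8), hidden_units=8, seed=0)
    defaults.update(overrides)
    return TrainingConfig(**defaults)


# ------------------------------------------------------------------- config

def test_config_yaml_round_trip(tmp_path):
    cfg = _quick_config(learning_rate=5e-4, plateau_patience=7)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert TrainingConfig.from_yaml(path) == cfg


def test_config_from_empty_yaml_is_default(tmp_path):
    path = tmp_path / "empty.yaml"
    path.write_text("")
    assert TrainingConfig.from_yaml(path) == TrainingConfig()


@pytest.mark.parametrize("kwargs", [
    dict(learning_rate=0.0), dict(learning_rate=-1e-3),
    dict(plateau_factor=0.0), dict(plateau_factor=1.0),
    dict(batch_size=0), dict(n_epochs=0),
])
def test_invalid_config_raises(kwargs):
    with pytest.raises(TrainingError):
        TrainingConfig(**kwargs)


# ------------------------------------------------------------- construction

def test_requires_exactly_one_validation_source():
    x, y = _blob_dataset()
    with pytest.raises(TrainingError, match="exactly one"):
        NoduleClassifier(x, y, config=_quick_config())
    sched = mccv_schedule([f"P{i}" for i in range(4)], 0.25, 4, seed=0)
    with pytest.raises(TrainingError, match="exactly one"):
        NoduleClassifier(x, y, validation=(x, y), mccv_schedule=sched,
                         config=_quick_config())


def test_single_class_pool_rejected():
    x, y = _blob_dataset()
    with pytest.raises(TrainingError, match="single class"):
        NoduleClassifier(x, np.zeros(len(x), dtype=int),
                         validation=(x, y), config=_quick_config())


def test_empty_validation_rejected():
    x, y = _blob_dataset()
    with pytest.raises(TrainingError, match="validation"):
        NoduleClassifier(x, y, validation=(x[:0], y[:0]),
                         config=_quick_config())


def test_string_labels_accepted_and_unknown_rejected():
    x, y = _blob_dataset()
    names = np.where(y == 0, "benign", "malignant")
    clf = NoduleClassifier(x, names, validation=(x, names),
                           config=_quick_config())
    assert np.array_equal(clf.labels, y)
    with pytest.raises(TrainingError, match="nodule"):
        NoduleClassifier(x, ["nodule"] * len(x), validation=(x, y),
                         config=_quick_config())


# -------------------------------------------------------------------- oracle

@pytest.fixture(scope="module")
def fitted():
    x, y = _blob_dataset(n=16)
    # plateau off (long patience): the oracle probes raw memorization capacity
    cfg = _quick_config(n_epochs=25, plateau_patience=100)
    return x, y, NoduleClassifier(x, y, validation=(x, y), config=cfg).fit()


def test_memorization_oracle(fitted):
    """A capacity-rich net must drive training accuracy to 1.0 on a tiny
    separable set: the memorization channel the study relies on exists."""
    x, y, results = fitted
    assert results.final_train_accuracy == 1.0
    assert evaluate_accuracy(results, x, y) == 1.0


def test_history_layout_and_summary(fitted):
    _, _, results = fitted
    h = results.history
    assert list(h.columns) == ["epoch", "train_acc", "val_acc", "lr",
                               "train_loss"]
    assert len(h) == results.config.n_epochs
    assert (h.lr > 0).all()
    assert h.train_acc.between(0, 1).all()
    text = results.summary()
    assert "final train acc" in text and "mccv" in text.lower()


def test_plateau_rule_reproducible_from_history(fitted):
    """Re-derive the learning-rate trace from the recorded validation
    accuracies with the documented plateau rule; it must match exactly."""
    _, _, results = fitted
    cfg = results.config
    lr, best, wait = cfg.learning_rate, -np.inf, 0
    for _, row in results.history.iterrows():
        assert row.lr == lr
        if row.val_acc > best + cfg.plateau_min_delta:
            best, wait = row.val_acc, 0
        else:
            wait += 1
            if wait >= cfg.plateau_patience:
                lr *= cfg.plateau_factor
                wait = 0


def test_plateau_fires_on_constant_validation():
    x, y = _blob_dataset(n=8)
    cfg = _quick_config(n_epochs=7, plateau_patience=2, learning_rate=1e-9)
    res = NoduleClassifier(x, y, validation=(x[:2], y[:2]),
                           config=cfg).fit()
    # lr 1e-9 cannot move val accuracy; after the first epoch sets the best,
    # the rate must be cut every `patience` epochs.
    lrs = res.history.lr.to_numpy()
    assert lrs[0] == 1e-9
    assert (np.diff(lrs) <= 0).all()
    assert lrs[-1] < lrs[0]


def test_predictions_match_accuracy(fitted):
    x, y, results = fitted
    preds = results.predict(x)
    proba = results.predict_proba(x)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    assert (preds == proba.argmax(axis=1)).all()
    assert evaluate_accuracy(results, x, y) == float((preds == y).mean())


# ------------------------------------------------------------------- MCCV

def test_mccv_training_runs_and_respects_schedule():
    x, y = _blob_dataset(n=16)
    pids = np.array([f"P{i % 4}" for i in range(16)])
    classes = {f"P{i}": ("benign" if i % 2 == 0 else "malignant")
               for i in range(4)}
    sched = mccv_schedule(classes, val_fraction=0.5, n_epochs=6, seed=1)
    y = np.array([0 if classes[p] == "benign" else 1 for p in pids])
    cfg = _quick_config(n_epochs=6, mccv=True)
    res = train(x, y, sched, config=cfg, patient_ids=pids)
    assert len(res.history) == 6
    assert res.config.mccv


def test_mccv_requires_patient_ids():
    x, y = _blob_dataset()
    sched = mccv_schedule([f"P{i}" for i in range(4)], 0.25, 4, seed=0)
    with pytest.raises(TrainingError, match="patient_ids"):
        NoduleClassifier(x, y, mccv_schedule=sched, config=_quick_config())


# -------------------------------------------------------------- determinism

def test_fit_is_deterministic():
    x, y = _blob_dataset(n=8)
    cfg = _quick_config(n_epochs=3)
    a = NoduleClassifier(x, y, validation=(x, y), config=cfg).fit()
    b = NoduleClassifier(x, y, validation=(x, y), config=cfg).fit()
    assert a.history.equals(b.history)
    for key in a.model.params:
        assert np.array_equal(a.model.params[key], b.model.params[key])


def test_seed_changes_trajectory():
    x, y = _blob_dataset(n=8)
    a = NoduleClassifier(x, y, validation=(x, y),
                         config=_quick_config(n_epochs=3, seed=0)).fit()
    b = NoduleClassifier(x, y, validation=(x, y),
                         config=_quick_config(n_epochs=3, seed=1)).fit()
    assert not all(np.array_equal(a.model.params[k], b.model.params[k])
                   for k in a.model.params)


# -------------------------------------------------------------- persistence

def test_model_save_load_round_trip(tmp_path, fitted):
    x, _, results = fitted
    path = tmp_path / "model.npz"
    results.model.save(path)
    from leakaudit.classifier import SmallConvNet
    back = SmallConvNet.load(path)
    assert np.allclose(back.forward_batch(x), results.predict_proba(x))
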