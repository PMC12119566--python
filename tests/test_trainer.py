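"""Mean-teacher loop: EMA algebra, determinism, resumability, guards."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cardseg.io import Volume
from cardseg.network import CBAPVNet, NetworkConfig
from cardseg.nn import SGD
from cardseg.phantom import PhantomSpec, generate_dataset, generate_phantom
from cardseg.trainer import (
    TrainConfig, TrainState, ema_update, items_from_arrays, load_checkpoint,
    load_items, predict_volume, train, training_step,
)

NET = NetworkConfig(base_channels=2, num_levels=2, pyramid_scales=2,
                    cbam_positions=("down1",), input_attention=True)
SPEC = PhantomSpec(grid_shape=(24, 24, 20), chamber_semi_axes=(6, 5, 4),
                   n_appendages=1, appendage_radius=1.5,
                   noise_sigma=0.05, bias_field_strength=0.1)


def tiny_cfg(**kw):
    base = dict(max_iterations=3, patch_shape=(16, 16, 8), seed=0,
                cutmix_prob=0.5, noise_sigma=0.05)
    base.update(kw)
    return TrainConfig(**base)


# ----------------------------------------------------------------------
# EMA
# ----------------------------------------------------------------------

def test_ema_closed_form_matches_iterated_updates():
    """k updates against a constant student equal
    decay^k·θ₀ + (1 − decay^k)·θ_s."""
    rng = np.random.default_rng(0)
    theta0 = rng.standard_normal(50)
    student = rng.standard_normal(50)
    decay = 0.9
    teacher = {"w": theta0.copy()}
    for k in range(1, 8):
        ema_update(teacher, {"w": student}, decay)
        closed = decay ** k * theta0 + (1 - decay ** k) * student
        np.testing.assert_allclose(teacher["w"], closed, atol=1e-12)


def test_ema_edge_decays():
    t = {"w": np.array([1.0, 2.0])}
    s = {"w": np.array([5.0, -1.0])}
    ema_update(t, s, 0.0)
    np.testing.assert_array_equal(t["w"], s["w"])
    t2 = {"w": np.array([1.0, 2.0])}
    ema_update(t2, s, 1.0)
    np.testing.assert_array_equal(t2["w"], [1.0, 2.0])


def test_ema_rejects_mismatches():
    with pytest.raises(ValueError, match="decay"):
        ema_update({"w": np.zeros(2)}, {"w": np.zeros(2)}, 1.5)
    with pytest.raises(ValueError, match="shape"):
        ema_update({"w": np.zeros(2)}, {"w": np.zeros(3)}, 0.5)
    with pytest.raises(ValueError, match="counts"):
        ema_update({"w": np.zeros(2)}, {"w": np.zeros(2), "b": np.zeros(1)}, 0.5)


def test_teacher_stays_on_segment_between_old_value_and_student():
    rng = np.random.default_rng(1)
    old = rng.standard_normal(20)
    student = rng.standard_normal(20)
    teacher = {"w": old.copy()}
    ema_update(teacher, {"w": student}, 0.7)
    lo = np.minimum(old, student) - 1e-12
    hi = np.maximum(old, student) + 1e-12
    assert ((teacher["w"] >= lo) & (teacher["w"] <= hi)).all()


# ----------------------------------------------------------------------
# steps and runs
# ----------------------------------------------------------------------

def _make_state(cfg, net_cfg=NET):
    student = CBAPVNet(net_cfg, seed=cfg.seed)
    teacher = CBAPVNet(net_cfg, seed=cfg.seed)
    teacher.load_state_dict(student.state_dict())
    opt = SGD(student.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    return TrainState(student=student, teacher=teacher, optimizer=opt,
                      rng=np.random.default_rng(cfg.seed))


def _items(cfg, n_labeled=1, n_unlabeled=1, noise=0.05):
    spec = dataclasses.replace(SPEC, noise_sigma=noise)
    vols, labs = [], []
    for i in range(n_labeled + n_unlabeled):
        v, l = generate_phantom(dataclasses.replace(spec, seed=20 + i))
        vols.append(v.data)
        labs.append(l.data if i < n_labeled else None)
    return items_from_arrays(vols, labs, cfg)


def test_identical_seeded_steps_are_bit_identical():
    cfg = tiny_cfg(max_iterations=3)
    losses = []
    for _ in range(2):
        state = _make_state(cfg)
        items = _items(cfg)
        for _ in range(3):
            training_step(state, items, cfg)
        losses.append([row["total"] for row in state.history])
    assert losses[0] == losses[1]


def test_history_grows_one_row_per_iteration():
    cfg = tiny_cfg(max_iterations=4)
    state = _make_state(cfg)
    items = _items(cfg)
    for k in range(4):
        training_step(state, items, cfg)
        assert state.iteration == k + 1
        assert len(state.history) == k + 1
    for key in ("iteration", "l_sup", "l_semi", "l_unsup", "lambda", "total"):
        assert key in state.history[0]


def test_supervised_loss_decreases_over_fifty_steps():
    """Pure supervised overfitting on one noiseless phantom must reduce
    L_sup between the first and the fiftieth step."""
    cfg = tiny_cfg(max_iterations=50, semi_enabled=False, cutmix_enabled=False,
                   noise_sigma=0.0, lr=0.02)
    state = _make_state(cfg)
    items = _items(cfg, n_labeled=1, n_unlabeled=0, noise=0.0)
    for _ in range(50):
        training_step(state, items, cfg)
    assert state.history[-1]["l_sup"] < state.history[0]["l_sup"]


def test_degenerate_self_training_uses_student_argmax():
    """With zero teacher noise and teacher = student, the pseudo-labels
    equal the student's own argmax."""
    from cardseg.trainer import _teacher_probs

    cfg = tiny_cfg(noise_sigma=0.0)
    state = _make_state(cfg)
    x = np.random.default_rng(0).standard_normal(cfg.patch_shape).astype(np.float32)
    teacher_pl = _teacher_probs(state.teacher, x, 0.0, state.rng).argmax(axis=0)
    student_pl = state.student(x[None, None]).p_scales[0].data[0].argmax(axis=0)
    np.testing.assert_array_equal(teacher_pl, student_pl)


def test_training_requires_labeled_and_unlabeled_pools():
    cfg = tiny_cfg()
    state = _make_state(cfg)
    with pytest.raises(ValueError, match="labeled"):
        training_step(state, _items(cfg, n_labeled=0, n_unlabeled=2), cfg)
    with pytest.raises(ValueError, match="unlabeled"):
        training_step(state, _items(cfg, n_labeled=1, n_unlabeled=0), cfg)


# ----------------------------------------------------------------------
# full runs on disk
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    return generate_dataset(1, 2, SPEC, seed=9, out_dir=out / "d")


def test_train_writes_log_and_checkpoint(dataset, tmp_path):
    cfg = tiny_cfg(max_iterations=3)
    state, ckpt, log = train(dataset, cfg, NET, tmp_path / "run")
    table = pd.read_csv(log)
    assert len(table) == 3
    assert list(table.columns) == ["iteration", "l_sup", "l_semi", "l_unsup",
                                   "lambda", "total"]
    assert ckpt.exists() and ckpt.with_suffix(".npz.json").exists()


def test_two_runs_same_seed_identical_teacher(dataset, tmp_path):
    cfg = tiny_cfg(max_iterations=3)
    _, ckpt1, _ = train(dataset, cfg, NET, tmp_path / "a")
    _, ckpt2, _ = train(dataset, cfg, NET, tmp_path / "b")
    s1, _, _ = load_checkpoint(ckpt1)
    s2, _, _ = load_checkpoint(ckpt2)
    for (n1, p1), (n2, p2) in zip(s1.teacher.named_parameters(),
                                  s2.teacher.named_parameters()):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)


def test_resume_continues_from_next_row(dataset, tmp_path):
    cfg3 = tiny_cfg(max_iterations=3)
    _, ckpt, _ = train(dataset, cfg3, NET, tmp_path / "run")
    cfg5 = tiny_cfg(max_iterations=5)
    state, _, log = train(dataset, cfg5, NET, tmp_path / "run", resume_from=ckpt)
    table = pd.read_csv(log)
    assert list(table.iteration) == [1, 2, 3, 4, 5]
    assert state.iteration == 5


def test_unlabeled_rows_never_supply_labels(dataset, tmp_path):
    """Poisoned manifest: unlabeled rows that name a (bogus) label file
    must still load with no label attached."""
    manifest = dataset
    poisoned = tmp_path / "manifest.csv"
    lines = manifest.read_text().strip().split("\n")
    header, rows = lines[0], [l.split(",") for l in lines[1:]]
    for r in rows:
        if r[3] == "unlabeled":
            r[2] = rows[0][2]  # point at the labeled case's label file
    # copy volumes next to the poisoned manifest
    import shutil
    for r in rows:
        shutil.copy(manifest.parent / r[1], tmp_path / r[1])
    shutil.copy(manifest.parent / rows[0][2], tmp_path / rows[0][2])
    poisoned.write_text("\n".join([header] + [",".join(r) for r in rows]) + "\n")

    items = load_items(poisoned, tiny_cfg())
    for item in items:
        if item["split"] == "unlabeled":
            assert item["label"] is None


def test_predict_single_patch_equals_single_forward(dataset):
    cfg = tiny_cfg()
    state = _make_state(cfg)
    vol, _ = generate_phantom(dataclasses.replace(SPEC, grid_shape=(16, 16, 16),
                                                  chamber_semi_axes=(4, 4, 3),
                                                  appendage_radius=1.0,
                                                  n_appendages=0))
    pred = predict_volume(state.teacher, vol, (16, 16, 16))
    data = (vol.data - vol.data.mean()) / vol.data.std()
    direct = state.teacher(data[None, None]).p_scales[0].data[0].argmax(axis=0)
    np.testing.assert_array_equal(pred.data, direct)


def test_non_finite_loss_aborts_with_term_name(dataset):
    cfg = tiny_cfg()
    state = _make_state(cfg)
    items = _items(cfg)
    items[0]["image"][:] = np.inf  # poison the labeled volume
    with pytest.raises(RuntimeError, match="l_sup|total"):
        training_step(state, items, cfg)
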