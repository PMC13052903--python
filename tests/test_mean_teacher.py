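"""Teacher-student coupling, schedules, and the training step."""

import numpy as np
import pytest

from cardiosemi.augment import AugmentationConfig
from cardiosemi.backbone import NetworkConfig, UNet
from cardiosemi.dptm import ThresholdMapState
from cardiosemi.losses import LossWeights, RobustLossConfig
from cardiosemi.mean_teacher import (ComponentToggles, ScheduleConfig,
                                     TeacherStudentState, Trainer, cosine_lr,
                                     ema_update_params, sigmoid_rampup, train_step)
from cardiosemi.phantom import PhantomConfig, generate_dataset


TINY_NET = NetworkConfig(base_width=4, depth=2, seed=0)


def _state(beta):
    return TeacherStudentState.initialize(UNet(TINY_NET), ema_coefficient=beta)


# ---- EMA parameter coupling ---------------------------------------------

def test_ema_beta_one_freezes_teacher():
    st = _state(1.0)
    frozen = {k: v.data.copy() for k, v in st.teacher.parameters().items()}
    for p in st.student.parameters().values():
        p.data += 1.0
    ema_update_params(st)
    for k, v in st.teacher.parameters().items():
        np.testing.assert_array_equal(v.data, frozen[k])
    assert st.step == 1


def test_ema_beta_zero_copies_student():
    st = _state(0.0)
    for p in st.student.parameters().values():
        p.data += 0.5
    ema_update_params(st)
    s = st.student.parameters()
    for k, v in st.teacher.parameters().items():
        np.testing.assert_array_equal(v.data, s[k].data)


def test_ema_hand_value():
    st = _state(0.9)
    name = "head.b"
    st.teacher.parameters()[name].data[:] = 1.0
    st.student.parameters()[name].data[:] = 2.0
    ema_update_params(st)
    np.testing.assert_allclose(st.teacher.parameters()[name].data, 1.1, atol=1e-6)


def test_ema_rejects_invalid_beta():
    with pytest.raises(ValueError):
        TeacherStudentState.initialize(UNet(TINY_NET), ema_coefficient=1.5)


def test_teacher_is_convex_combination_of_student_history():
    # closed-form EMA on a 2-parameter toy trajectory
    beta = 0.8
    st = _state(beta)
    name = "head.b"
    st.teacher.parameters()[name].data[:] = 0.0
    history = []
    for t in range(5):
        st.student.parameters()[name].data[:] = float(t + 1)
        history.append(float(t + 1))
        ema_update_params(st)
    expected = 0.0
    for v in history:
        expected = beta * expected + (1 - beta) * v
    np.testing.assert_allclose(st.teacher.parameters()[name].data, expected, atol=1e-6)
    lo, hi = min([0.0] + history), max([0.0] + history)
    assert lo <= st.teacher.parameters()[name].data[0] <= hi


# ---- schedules -----------------------------------------------------------

def test_cosine_lr_endpoints_and_midpoint():
    sch = ScheduleConfig()
    assert cosine_lr(0, 100, sch) == pytest.approx(1e-2)
    assert cosine_lr(100, 100, sch) == pytest.approx(1e-3)
    assert cosine_lr(50, 100, sch) == pytest.approx(5.5e-3)
    with pytest.raises(ValueError):
        cosine_lr(0, 0, sch)
    with pytest.raises(ValueError):
        cosine_lr(101, 100, sch)


def test_schedule_validation():
    with pytest.raises(ValueError):
        ScheduleConfig(initial_lr=1e-4, final_lr=1e-3)


def test_sigmoid_rampup_limits():
    assert sigmoid_rampup(0, 100) == pytest.approx(np.exp(-5.0))
    assert sigmoid_rampup(100, 100) == 1.0
    assert sigmoid_rampup(500, 100) == 1.0
    assert sigmoid_rampup(5, 0) == 1.0
    assert sigmoid_rampup(50, 100) < sigmoid_rampup(80, 100)


# ---- the training step ---------------------------------------------------

def _step_ingredients(seed=0, n_lab=2, n_unl=4):
    cfg = PhantomConfig(image_size=16, seed=seed)
    imgs, labs = generate_dataset(cfg, n_lab + n_unl)
    state = _state(0.95)
    from cardiosemi.autodiff import SGD
    opt = SGD(list(state.student.parameters().values()), lr=1e-2, momentum=0.9)
    thr = ThresholdMapState.initial(16, 16, 4, momentum=0.9)
    return imgs[:n_lab], labs[:n_lab], imgs[n_lab:], state, opt, thr


def test_step_without_unlabeled_is_purely_supervised():
    lx, ly, _, state, opt, thr = _step_ingredients()
    _, breakdown = train_step(
        lx, ly, None, state, thr, opt, 1e-2, LossWeights(),
        ComponentToggles(False, False, False), RobustLossConfig(),
        AugmentationConfig(), np.random.default_rng(0))
    assert breakdown["l_unl"] == 0.0 and breakdown["l_con"] == 0.0
    assert breakdown["l_sup"] > 0.0
    assert breakdown["total"] == pytest.approx(breakdown["l_sup"])


def test_step_with_zero_weights_changes_params_only_via_supervised():
    lx, ly, ux, state, opt, thr = _step_ingredients()
    before = {k: v.data.copy() for k, v in state.student.parameters().items()}
    _, breakdown = train_step(
        lx, ly, ux, state, thr, opt, 1e-2, LossWeights(0.0, 0.0),
        ComponentToggles(True, True, True), RobustLossConfig(),
        AugmentationConfig(), np.random.default_rng(0))
    assert breakdown["l_unl"] == 0.0 and breakdown["l_con"] == 0.0
    changed = any(not np.array_equal(v.data, before[k])
                  for k, v in state.student.parameters().items())
    assert changed


def test_identical_seeded_steps_are_bitwise_identical():
    results = []
    for _ in range(2):
        lx, ly, ux, state, opt, thr = _step_ingredients(seed=3)
        _, breakdown = train_step(
            lx, ly, ux, state, thr, opt, 1e-2, LossWeights(),
            ComponentToggles(True, True, True), RobustLossConfig(),
            AugmentationConfig(), np.random.default_rng(7))
        results.append(breakdown)
    assert results[0] == results[1]


def test_dptm_toggle_off_uses_fixed_threshold_and_keeps_map():
    lx, ly, ux, state, opt, thr = _step_ingredients()
    new_thr, _ = train_step(
        lx, ly, ux, state, thr, opt, 1e-2, LossWeights(),
        ComponentToggles(False, True, False), RobustLossConfig(),
        AugmentationConfig(), np.random.default_rng(0))
    np.testing.assert_array_equal(new_thr.map, thr.map)  # untouched
    assert new_thr.batch_index == 0


def test_dptm_toggle_on_advances_threshold_map():
    lx, ly, ux, state, opt, thr = _step_ingredients()
    new_thr, _ = train_step(
        lx, ly, ux, state, thr, opt, 1e-2, LossWeights(),
        ComponentToggles(True, True, False), RobustLossConfig(),
        AugmentationConfig(), np.random.default_rng(0))
    assert new_thr.batch_index == 1
    assert not np.array_equal(new_thr.map, thr.map)


# ---- the trainer loop ----------------------------------------------------

def _tiny_trainer(toggles, seed=0, epochs=2):
    return Trainer(
        network=NetworkConfig(base_width=4, depth=2, seed=0),
        schedule=ScheduleConfig(total_epochs=epochs, batch_size=4),
        weights=LossWeights(1.0, 0.1),
        toggles=toggles,
        ema_coefficient=0.9,
        dptm_momentum=0.9,
        seed=seed,
    )


@pytest.fixture(scope="module")
def tiny_data():
    cfg = PhantomConfig(image_size=16, seed=4)
    return generate_dataset(cfg, 16)


def test_all_off_trainer_matches_supervised_baseline_exactly(tiny_data):
    imgs, labs = tiny_data
    runs = []
    for _ in range(2):
        tr = _tiny_trainer(ComponentToggles(False, False, False))
        tr.fit(imgs[:4], labs[:4], imgs[4:12])
        runs.append([h["total"] for h in tr.history])
    assert runs[0] == runs[1]
    # unlabeled/contrastive components identically zero in the log
    tr = _tiny_trainer(ComponentToggles(False, False, False))
    tr.fit(imgs[:4], labs[:4], imgs[4:12])
    assert all(h["l_unl"] == 0.0 and h["l_con"] == 0.0 for h in tr.history)


def test_full_trainer_deterministic_under_fixed_seed(tiny_data):
    imgs, labs = tiny_data
    logs = []
    for _ in range(2):
        tr = _tiny_trainer(ComponentToggles(True, True, True))
        tr.fit(imgs[:4], labs[:4], imgs[4:12])
        logs.append(tr.history)
    assert logs[0] == logs[1]


def test_trainer_history_and_lr_schedule(tiny_data):
    imgs, labs = tiny_data
    tr = _tiny_trainer(ComponentToggles(True, True, True), epochs=2)
    hist = tr.fit(imgs[:4], labs[:4], imgs[4:12])
    assert len(hist) == 2 * 2  # 8 unlabeled / batch 4 = 2 steps per epoch
    lrs = [h["lr"] for h in hist]
    assert lrs[0] == pytest.approx(1e-2)
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))


def test_checkpoint_contents(tiny_data, tmp_path):
    imgs, labs = tiny_data
    tr = _tiny_trainer(ComponentToggles(True, True, True))
    tr.fit(imgs[:4], labs[:4], imgs[4:12])
    tr.save_checkpoint(tmp_path)
    for f in ("student.npz", "teacher.npz", "threshold_map.npz",
              "optimizer.npz", "trainer_state.json"):
        assert (tmp_path / f).exists(), f
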