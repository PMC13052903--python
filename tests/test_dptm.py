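"""Dynamic pseudo-label threshold map: equation oracles, EMA identities and
selection invariants."""

import numpy as np
import pytest

from cardiosemi.dptm import (ProbabilityMap, ThresholdMapState, batch_avg_confidence,
                             class_confidence, class_modulated_thresholds,
                             class_scaling, confidence_weight_map, dptm_step,
                             ema_update_threshold, load_threshold_state,
                             save_threshold_state)

from conftest import random_prob_maps


# ---- independent scalar-loop oracles ------------------------------------

def _oracle_batch_avg(batch):
    b, h, w, c = batch.shape
    out = np.zeros((h, w))
    for i in range(b):
        for y in range(h):
            for x in range(w):
                m = 0.0
                for k in range(c):
                    m = max(m, batch[i, y, x, k])
                out[y, x] += m
    return out / b


def _oracle_class_confidence(batch, xi):
    b, h, w, c = batch.shape
    num = np.zeros(c)
    den = np.zeros(c)
    for i in range(b):
        for y in range(h):
            for x in range(w):
                k = int(np.argmax(batch[i, y, x]))
                num[k] += batch[i, y, x].max()
                den[k] += 1
    return num / (den + xi)


def _oracle_gamma(pmap, thr):
    h, w, c = pmap.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            k = int(np.argmax(pmap[y, x]))
            if pmap[y, x, k] > thr[y, x, k]:
                out[y, x] = pmap[y, x, k]
    return out


def test_batch_avg_matches_loop_oracle(rng):
    for _ in range(20):
        batch = random_prob_maps(rng)
        np.testing.assert_allclose(batch_avg_confidence(batch),
                                   _oracle_batch_avg(batch), atol=1e-6)


def test_batch_avg_uniform_map_gives_inverse_class_count():
    uniform = np.full((1, 4, 4, 4), 0.25)
    np.testing.assert_allclose(batch_avg_confidence(uniform), 0.25)


def test_batch_avg_is_mean_of_maxima():
    m1 = np.full((1, 1, 4), 0.05)
    m1[0, 0, 0] = 0.85
    m2 = np.full((1, 1, 4), 0.4 / 3)
    m2[0, 0, 0] = 0.6
    # per-pixel maxima 0.85 and 0.6 -> averaged 0.725
    out = batch_avg_confidence([m1, m2])
    np.testing.assert_allclose(out, 0.725)


def test_batch_avg_rejects_empty_and_mismatched_batches(rng):
    with pytest.raises(ValueError):
        batch_avg_confidence([])
    maps = [random_prob_maps(rng)[0], random_prob_maps(rng, height=6)[0]]
    with pytest.raises(ValueError):
        batch_avg_confidence(maps)


def test_batch_avg_bounded_by_class_count(rng):
    batch = random_prob_maps(rng, batch=6)
    out = batch_avg_confidence(batch)
    assert out.min() >= 1.0 / 4 - 1e-12 and out.max() <= 1.0 + 1e-12


# ---- EMA updates ---------------------------------------------------------

@pytest.mark.parametrize("alpha,expected", [(1.0, 0.25), (0.0, 0.75), (0.9, 0.30)])
def test_ema_update_identities(alpha, expected):
    state = ThresholdMapState(map=np.full((4, 4), 0.25), num_classes=4, momentum=alpha)
    new = ema_update_threshold(state, np.full((4, 4), 0.75))
    np.testing.assert_allclose(new.map, expected, atol=1e-12)
    assert new.batch_index == 1
    np.testing.assert_allclose(state.map, 0.25)  # input state untouched


def test_ema_momentum_validation():
    with pytest.raises(ValueError):
        ThresholdMapState(map=np.full((2, 2), 0.25), num_classes=4, momentum=1.5)


def test_initial_state_is_uniform_uncertainty():
    state = ThresholdMapState.initial(5, 7, 4)
    np.testing.assert_allclose(state.map, 0.25)
    assert state.epoch_index == 0 and state.batch_index == 0


def test_threshold_map_stays_bounded_over_random_updates(rng):
    state = ThresholdMapState.initial(8, 8, 4, momentum=float(rng.uniform()))
    for _ in range(100):
        batch = random_prob_maps(rng, batch=2)
        state = ema_update_threshold(state, batch_avg_confidence(batch))
        assert state.map.min() >= 0.25 - 1e-9
        assert state.map.max() <= 1.0 + 1e-9


# ---- class confidence and scaling ---------------------------------------

def test_class_confidence_matches_loop_oracle(rng):
    for _ in range(20):
        batch = random_prob_maps(rng)
        np.testing.assert_allclose(class_confidence(batch, 1e-8),
                                   _oracle_class_confidence(batch, 1e-8), atol=1e-6)


def test_class_confidence_concentrated_predictions():
    batch = np.zeros((1, 4, 4, 4))
    batch[..., 0] = 1.0  # every pixel: class 0 with certainty
    eps = class_confidence(batch, 1e-8)
    assert eps[0] == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_allclose(eps[1:], 0.0)


def test_class_confidence_two_class_means():
    batch = np.zeros((1, 2, 2, 4))
    batch[0, 0, :, 0] = 0.9
    batch[0, 0, :, 1:] = 0.1 / 3
    batch[0, 1, :, 1] = 0.6
    batch[0, 1, :, [0, 2, 3]] = 0.4 / 3
    eps = class_confidence(batch, 1e-8)
    assert eps[0] == pytest.approx(0.9, abs=1e-6)
    assert eps[1] == pytest.approx(0.6, abs=1e-6)


@pytest.mark.parametrize("eps,expected", [
    ((0.9, 0.6), (1.0, 2 / 3)),
    ((0.4, 0.4, 0.4), (1.0, 1.0, 1.0)),
    ((0.5, 0.25, 0.1, 0.05), (1.0, 0.5, 0.2, 0.1)),
])
def test_class_scaling_normalizes_by_max(eps, expected):
    np.testing.assert_allclose(class_scaling(np.array(eps)), expected, atol=1e-9)


def test_class_scaling_rejects_all_zero():
    with pytest.raises(ValueError):
        class_scaling(np.zeros(4))


def test_modulated_thresholds_elementwise_product(rng):
    state = ThresholdMapState(map=rng.uniform(0.25, 1.0, (8, 8)), num_classes=4)
    eta = rng.uniform(0.1, 1.0, 4)
    eta[rng.integers(4)] = 1.0
    out = class_modulated_thresholds(state, eta)
    for c in range(4):
        np.testing.assert_allclose(out[:, :, c], eta[c] * state.map, atol=1e-7)
    assert (out <= state.map[:, :, None] + 1e-12).all()


# ---- confidence weighting map -------------------------------------------

def test_gamma_selects_above_threshold_and_zeroes_below():
    pmap = np.full((1, 1, 4), 0.1 / 3)
    pmap[0, 0, 2] = 0.9
    cw = confidence_weight_map(pmap, np.full((1, 1, 4), 0.5))
    assert cw.weights[0, 0] == pytest.approx(0.9)
    assert cw.predicted_class[0, 0] == 2
    pmap[0, 0] = [0.2, 0.2, 0.4, 0.2]
    cw = confidence_weight_map(pmap, np.full((1, 1, 4), 0.5))
    assert cw.weights[0, 0] == 0.0


def test_gamma_strict_inequality_at_threshold():
    pmap = np.full((2, 2, 4), 0.1)
    pmap[..., 0] = 0.7
    thresholds = np.full((2, 2, 4), 0.7)  # equal, not exceeded
    cw = confidence_weight_map(pmap, thresholds)
    np.testing.assert_allclose(cw.weights, 0.0)


def test_gamma_identically_zero_when_thresholds_one(rng):
    pmap = random_prob_maps(rng, batch=1)[0]
    cw = confidence_weight_map(pmap, np.ones_like(pmap))
    np.testing.assert_allclose(cw.weights, 0.0)


def test_gamma_matches_loop_oracle(rng):
    for _ in range(20):
        pmap = random_prob_maps(rng, batch=1)[0]
        thr = rng.uniform(0.2, 0.8, pmap.shape)
        cw = confidence_weight_map(pmap, thr)
        np.testing.assert_allclose(cw.weights, _oracle_gamma(pmap, thr), atol=1e-6)
        np.testing.assert_array_equal(cw.predicted_class, pmap.argmax(axis=-1))


def test_raising_thresholds_never_selects_more(rng):
    for _ in range(100):
        pmap = random_prob_maps(rng, batch=1, height=6, width=6)[0]
        thr = rng.uniform(0.0, 1.0, pmap.shape)
        low = confidence_weight_map(pmap, thr)
        bump = thr + rng.uniform(0.0, 0.3, thr.shape)
        high = confidence_weight_map(pmap, bump)
        assert (high.weights > 0).sum() <= (low.weights > 0).sum()


def test_tied_maxima_break_deterministically():
    pmap = np.full((3, 3, 4), 0.25)  # four-way tie everywhere
    thr = np.full((3, 3, 4), 0.2)
    first = confidence_weight_map(pmap, thr)
    second = confidence_weight_map(pmap, thr)
    np.testing.assert_array_equal(first.predicted_class, 0)  # lowest index wins
    np.testing.assert_array_equal(first.predicted_class, second.predicted_class)
    np.testing.assert_array_equal(first.weights, second.weights)


# ---- pipeline + serialization -------------------------------------------

def test_dptm_step_runs_pipeline_and_advances_state(rng):
    state = ThresholdMapState.initial(8, 8, 4, momentum=0.9)
    batch = random_prob_maps(rng)
    new_state, gamma, scaling = dptm_step(state, batch)
    assert new_state.batch_index == 1
    assert gamma.shape == (4, 8, 8)
    assert scaling.scaling.max() == pytest.approx(1.0)
    np.testing.assert_allclose(
        scaling.scaling, scaling.confidence / scaling.confidence.max(), atol=1e-6)


def test_epoch_rollover_continues_or_resets():
    state = ThresholdMapState(map=np.full((4, 4), 0.8), num_classes=4)
    cont = state.next_epoch(reset=False)
    assert cont.epoch_index == 1 and cont.batch_index == 0
    np.testing.assert_allclose(cont.map, 0.8)
    fresh = state.next_epoch(reset=True)
    np.testing.assert_allclose(fresh.map, 0.25)


def test_threshold_state_round_trips_through_npz(tmp_path, rng):
    state = ThresholdMapState(map=rng.uniform(0.25, 1, (6, 6)), num_classes=4,
                              momentum=0.97, epoch_index=3, batch_index=11)
    save_threshold_state(state, tmp_path / "thr.npz")
    back = load_threshold_state(tmp_path / "thr.npz")
    np.testing.assert_array_equal(back.map, state.map)
    assert (back.num_classes, back.momentum, back.epoch_index, back.batch_index) == \
        (4, 0.97, 3, 11)


def test_probability_map_validation(rng):
    good = random_prob_maps(rng, batch=1)[0]
    ProbabilityMap(good)
    with pytest.raises(ValueError):
        ProbabilityMap(good * 0.5)  # sums to 0.5
    bad = good.copy()
    bad[0, 0, 0] = 1.5
    with pytest.raises(ValueError):
        ProbabilityMap(bad)
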