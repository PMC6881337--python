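"""Residual network: shape/parameter contracts, training behaviour, determinism."""

import numpy as np
import pytest

from deepvnc import (
    BrainMask,
    DECTPair,
    HUImage,
    NetworkConfig,
    build_network,
    make_training_samples,
    predict_difference,
    train_model,
)
from deepvnc.model import TrainingSample, masked_rmse_loss

TINY = NetworkConfig(
    channels=8, input_size=16, learning_rate=1e-2, dropout_rate=0.0,
    weight_decay=0.0, batch_size=4, norm="batch",
)


def _sample(rng, size=16, target=None, subject="S0"):
    x = rng.random((3, size, size)).astype(np.float32)
    t = (rng.standard_normal((1, size, size)).astype(np.float32)
         if target is None else np.full((1, size, size), target, np.float32))
    mask = np.ones((size, size), bool)
    return TrainingSample(input=x, target=t, mask=mask, subject_id=subject)


def test_output_shape_contract():
    cfg = NetworkConfig(channels=8, input_size=64)
    model = build_network(cfg, seed=0)
    out = model.forward(np.zeros((2, 3, 64, 64), np.float32))
    assert out.shape == (2, 1, 64, 64)


def test_parameter_count_closed_form():
    # projection: 3*c*k^2 + c; per block: 2*(c^2*k^2 + c) + 2*2c (batch norm);
    # head: c*1*1 + 1; blocks total = groups * blocks_per_group
    c, k = 8, 3
    cfg = NetworkConfig(channels=c, kernel=k, input_size=16)
    model = build_network(cfg, seed=0)
    n_blocks = cfg.groups * cfg.blocks_per_group
    expected = (
        (3 * c * k * k + c)
        + n_blocks * (2 * (c * c * k * k + c) + 2 * 2 * c)
        + (c * 1 * 1 + 1)
    )
    assert model.n_parameters == expected


def test_zeroed_head_gives_zero_output(rng):
    model = build_network(TINY, seed=1)
    model.zero_head()
    out = model.forward(rng.random((3, 3, 16, 16)).astype(np.float32))
    np.testing.assert_array_equal(out, 0.0)


def test_residual_branches_zeroed_reduces_to_projection_plus_head(rng):
    model = build_network(TINY, seed=2)
    x = rng.random((1, 3, 16, 16)).astype(np.float32)
    full = model.forward(x)
    for block in model.blocks:
        block.conv2.W[:] = 0.0
        block.conv2.b[:] = 0.0
        if block.bn2 is not None:
            block.bn2.gamma[:] = 0.0
            block.bn2.beta[:] = 0.0
    reduced = model.forward(x)
    # with every residual branch silenced the blocks are identity maps
    h = model.proj.forward(
        np.ascontiguousarray(np.transpose(x, (1, 0, 2, 3)), dtype=np.float32), False
    )
    h = np.maximum(h, 0.0)
    direct = np.transpose(model.head.forward(h, False), (1, 0, 2, 3))
    np.testing.assert_allclose(reduced, direct, atol=1e-6)
    assert not np.allclose(full, reduced)


def test_masked_loss_ignores_outside_pixels(rng):
    pred = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)
    target = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)
    mask = rng.random((2, 1, 8, 8)) > 0.5
    loss1, _ = masked_rmse_loss(pred, target, mask)
    corrupted = target.copy()
    corrupted[~mask] += 1000.0
    loss2, _ = masked_rmse_loss(pred, corrupted, mask)
    assert loss1 == loss2


def test_zero_targets_with_zero_head_stop_at_loss_zero(rng):
    model = build_network(TINY, seed=3)
    model.zero_head()
    train = [_sample(rng, target=0.0, subject=f"S{i}") for i in range(4)]
    val = [_sample(rng, target=0.0, subject="V0")]
    model, history = train_model(model, train, val, TINY, patience=2, max_epochs=10, seed=0)
    assert history.val_loss[0] == pytest.approx(0.0, abs=1e-6)
    assert history.stop_reason == "plateau"
    assert history.best_val_loss == pytest.approx(0.0, abs=1e-6)


def test_overfit_small_noiseless_set(rng):
    model = build_network(TINY, seed=4)
    train = [_sample(rng, subject=f"S{i}") for i in range(4)]
    # smooth, learnable targets: scaled channel sums
    for s in train:
        s.target = s.input.mean(axis=0, keepdims=True) * 10.0
    model, history = train_model(model, train, train, TINY, patience=60,
                                 max_epochs=60, seed=1, min_delta=1e-4)
    assert history.train_loss[-1] < 0.1 * history.train_loss[0]
    # prediction on a training input is close to its target
    pred = predict_difference(model, train[0])
    rmse = np.sqrt(np.mean((pred.pixels - train[0].target[0]) ** 2))
    assert rmse < 2.0


def test_training_determinism(rng):
    samples = [_sample(rng, subject=f"S{i}") for i in range(6)]
    val = [_sample(rng, subject="V0")]

    def run():
        model = build_network(TINY, seed=5)
        _, history = train_model(model, samples, val, TINY, patience=3,
                                 max_epochs=4, seed=7)
        return history, model.get_weights()

    h1, w1 = run()
    h2, w2 = run()
    assert h1.train_loss == h2.train_loss
    assert h1.val_loss == h2.val_loss
    for a, b in zip(w1, w2):
        np.testing.assert_array_equal(a, b)


def test_inference_deterministic_dropout_disabled(rng):
    cfg = NetworkConfig(channels=8, input_size=16, dropout_rate=0.5)
    model = build_network(cfg, seed=6)
    s = _sample(rng)
    a = predict_difference(model, s)
    b = predict_difference(model, s)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_training_errors(rng):
    model = build_network(TINY, seed=0)
    with pytest.raises(ValueError):
        train_model(model, [], [_sample(rng)], TINY)
    with pytest.raises(ValueError):
        train_model(model, [_sample(rng)], [_sample(rng)], TINY, patience=0)


def test_model_serialization_roundtrip(tmp_path, rng):
    from deepvnc.model import TrainingHistory, load_model, save_model

    model = build_network(TINY, seed=8)
    history = TrainingHistory(train_loss=[1.0], val_loss=[2.0], epochs_run=1,
                              stop_reason="max_epochs", seed=8)
    save_model(model, history, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert back.config == model.config
    x = rng.random((1, 3, 16, 16)).astype(np.float32)
    np.testing.assert_array_equal(back.forward(x), model.forward(x))


def _images(rng, shape=(32, 32)):
    low = HUImage(rng.uniform(0, 100, shape), subject_id="P1")
    high = HUImage(rng.uniform(0, 100, shape), subject_id="P1")
    pair = DECTPair(low=low, high=high)
    lvnc = HUImage(rng.uniform(0, 100, shape), subject_id="P1")
    tnc = HUImage(lvnc.pixels + 7.0, subject_id="P1")
    mask = BrainMask(np.ones(shape, bool))
    return pair, lvnc, tnc, mask


def test_training_sample_construction_identity(rng):
    pair, lvnc, tnc, mask = _images(rng)
    s = make_training_samples(pair, lvnc, tnc, mask, size=32)
    # identity resample: channels are the normalized originals
    np.testing.assert_allclose(s.input[0], (pair.low.pixels + 100) / 400, atol=1e-6)
    np.testing.assert_allclose(s.target[0], 7.0, atol=1e-6)
    np.testing.assert_allclose(s.tnc_hu, tnc.pixels, atol=1e-4)
    np.testing.assert_allclose(s.lvnc_hu, lvnc.pixels, atol=1e-4)

    # lvnc == tnc gives an identically-zero target
    s0 = make_training_samples(pair, tnc, tnc, mask, size=32)
    np.testing.assert_array_equal(s0.target, 0.0)


def test_training_sample_downsampling(rng):
    pair, lvnc, tnc, mask = _images(rng, shape=(32, 32))
    s = make_training_samples(pair, lvnc, tnc, mask, size=16)
    assert s.input.shape == (3, 16, 16)
    # constant difference survives area averaging
    np.testing.assert_allclose(s.target[0], 7.0, atol=1e-5)
    block = pair.low.pixels.reshape(16, 2, 16, 2).mean(axis=(1, 3))
    np.testing.assert_allclose(s.input[0], (block + 100) / 400, atol=1e-6)
    with pytest.raises(ValueError):
        make_training_samples(pair, lvnc, tnc, mask, size=10)


def test_training_sample_empty_mask_rejected(rng):
    pair, lvnc, tnc, _ = _images(rng)
    empty = BrainMask(np.zeros((32, 32), bool))
    with pytest.raises(ValueError):
        make_training_samples(pair, lvnc, tnc, empty, size=32)
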