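"""DNC composition and masked similarity metrics against brute-force oracles."""

import numpy as np
import pytest

from deepvnc import (
    BrainMask,
    HUImage,
    batched_metrics,
    compose_dnc,
    masked_rmse,
    masked_spearman,
    records_frame,
    summarize,
)


def _img(arr, subject="S0"):
    return HUImage(np.asarray(arr, float), subject_id=subject)


def _full(shape):
    return BrainMask(np.ones(shape, bool))


def test_compose_dnc_identities(rng):
    lvnc = _img(rng.uniform(0, 100, (8, 8)))
    zero = _img(np.zeros((8, 8)))
    np.testing.assert_array_equal(compose_dnc(lvnc, zero).pixels, lvnc.pixels)
    tnc = _img(rng.uniform(0, 100, (8, 8)))
    diff = _img(tnc.pixels - lvnc.pixels)
    # exact up to one floating-point rounding of the subtraction
    np.testing.assert_allclose(compose_dnc(lvnc, diff).pixels, tnc.pixels, rtol=0, atol=1e-12)
    assert compose_dnc(_img([[30.0]]), _img([[-7.5]])).pixels[0, 0] == 22.5


def test_masked_rmse_hand_values():
    mask = _full((1, 3))
    a = _img([[0.0, 3.0, 4.0]])
    b = _img([[0.0, 0.0, 0.0]])
    assert masked_rmse(a, b, mask) == pytest.approx(5.0 / np.sqrt(3.0), rel=1e-12)
    assert masked_rmse(a, a, mask) == 0.0
    c = _img(a.pixels + 5.0)
    assert masked_rmse(a, c, mask) == pytest.approx(5.0)


def test_masked_rmse_is_a_metric(rng):
    mask = BrainMask(rng.random((10, 10)) > 0.4)
    for _ in range(20):
        a = _img(rng.normal(0, 30, (10, 10)))
        b = _img(rng.normal(0, 30, (10, 10)))
        c = _img(rng.normal(0, 30, (10, 10)))
        dab = masked_rmse(a, b, mask)
        assert dab == pytest.approx(masked_rmse(b, a, mask))
        assert dab <= masked_rmse(a, c, mask) + masked_rmse(c, b, mask) + 1e-12


def _brute_spearman(x, y):
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def test_masked_spearman_small_cases():
    mask = _full((1, 4))
    a = _img([[1.0, 2.0, 2.0, 4.0]])
    b = _img([[1.0, 3.0, 2.0, 4.0]])
    assert masked_spearman(a, b, mask) == pytest.approx(
        _brute_spearman([1, 2, 2, 4], [1, 3, 2, 4]), abs=1e-12
    )
    distinct = _img([[4.0, 1.0, 3.0, 2.0]])
    assert masked_spearman(distinct, distinct, mask) == pytest.approx(1.0)
    neg = _img(-distinct.pixels)
    assert masked_spearman(distinct, neg, mask) == pytest.approx(-1.0)


def test_masked_spearman_matches_oracle_with_ties(rng):
    mask = BrainMask(rng.random((6, 6)) > 0.3)
    for _ in range(30):
        a = _img(rng.integers(0, 5, (6, 6)).astype(float))
        b = _img(rng.integers(0, 5, (6, 6)).astype(float))
        va, vb = a.pixels[mask.pixels], b.pixels[mask.pixels]
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            continue
        assert masked_spearman(a, b, mask) == pytest.approx(
            _brute_spearman(va, vb), abs=1e-12
        )


def test_masked_spearman_monotone_invariance(rng):
    mask = _full((8, 8))
    a = _img(rng.normal(0, 10, (8, 8)))
    b = _img(rng.normal(0, 10, (8, 8)))
    rho = masked_spearman(a, b, mask)
    assert masked_spearman(_img(a.pixels**3), b, mask) == pytest.approx(rho, abs=1e-12)
    assert masked_spearman(a, _img(np.exp(b.pixels / 10)), mask) == pytest.approx(rho, abs=1e-12)


def test_metric_degenerate_inputs():
    mask = _full((1, 3))
    const = _img([[1.0, 1.0, 1.0]])
    other = _img([[1.0, 2.0, 3.0]])
    with pytest.raises(ValueError):
        masked_spearman(const, other, mask)
    with pytest.raises(ValueError):
        masked_rmse(const, other, BrainMask(np.zeros((1, 3), bool)))


def test_batched_metrics_partition_arithmetic(rng):
    n = 64
    preds = [_img(rng.normal(0, 10, (6, 6)), subject=f"S{i}") for i in range(n)]
    refs = [_img(p.pixels + rng.normal(0, 1, (6, 6))) for p in preds]
    masks = [_full((6, 6)) for _ in range(n)]
    records = batched_metrics(preds, refs, masks, batch_size=32, seed=1)
    assert len(records) == 2
    assert all(r.n_voxels == 32 * 36 for r in records)
    # identical lists give rmse 0 and rho 1 in every batch
    perfect = batched_metrics(preds, preds, masks, batch_size=32, seed=1)
    assert all(r.rmse == 0.0 and r.spearman_rho == pytest.approx(1.0) for r in perfect)


def test_batched_metrics_recomputation_oracle(rng):
    n = 10
    preds = [_img(rng.normal(0, 10, (5, 5)), subject=f"S{i}") for i in range(n)]
    refs = [_img(rng.normal(0, 10, (5, 5))) for _ in range(n)]
    masks = [BrainMask(rng.random((5, 5)) > 0.3) for _ in range(n)]
    records = batched_metrics(preds, refs, masks, batch_size=4, seed=3)
    order = np.random.default_rng(3).permutation(n)
    for rec in records:
        idx = order[rec.batch_id * 4 : rec.batch_id * 4 + 4]
        vp = np.concatenate([preds[i].pixels[masks[i].pixels] for i in idx])
        vr = np.concatenate([refs[i].pixels[masks[i].pixels] for i in idx])
        assert rec.rmse == pytest.approx(np.sqrt(np.mean((vp - vr) ** 2)), rel=1e-12)
        assert rec.spearman_rho == pytest.approx(_brute_spearman(vp, vr), abs=1e-12)
        assert rec.n_voxels == vp.size


def test_batched_metrics_drops_partial_batch(rng):
    preds = [_img(rng.normal(0, 10, (4, 4)), subject=f"S{i}") for i in range(10)]
    masks = [_full((4, 4))] * 10
    records = batched_metrics(preds, preds, masks, batch_size=4, seed=0)
    assert len(records) == 2
    kept = batched_metrics(preds, preds, masks, batch_size=4, seed=0, keep_partial=True)
    assert len(kept) == 3


def test_batched_metrics_deterministic(rng):
    preds = [_img(rng.normal(0, 10, (4, 4)), subject=f"S{i}") for i in range(8)]
    refs = [_img(rng.normal(0, 10, (4, 4))) for _ in range(8)]
    masks = [_full((4, 4))] * 8
    r1 = batched_metrics(preds, refs, masks, batch_size=4, seed=5)
    r2 = batched_metrics(preds, refs, masks, batch_size=4, seed=5)
    assert [(r.rmse, r.spearman_rho, r.image_ids) for r in r1] == [
        (r.rmse, r.spearman_rho, r.image_ids) for r in r2
    ]


def test_rmse_ordering_invariant_under_global_offset(rng):
    n = 8
    refs = [_img(rng.normal(40, 10, (6, 6)), subject=f"S{i}") for i in range(n)]
    m1 = [_img(r.pixels + rng.normal(0, 3, (6, 6))) for r in refs]
    m2 = [_img(r.pixels + rng.normal(0, 8, (6, 6))) for r in refs]
    masks = [_full((6, 6))] * n

    def mean_rmse(preds, refs):
        recs = batched_metrics(preds, refs, masks, batch_size=4, seed=0)
        return summarize(recs)["rmse_mean"]

    base_order = mean_rmse(m1, refs) < mean_rmse(m2, refs)
    off = 37.0
    shifted = lambda imgs: [_img(i.pixels + off) for i in imgs]
    shifted_order = mean_rmse(shifted(m1), shifted(refs)) < mean_rmse(shifted(m2), shifted(refs))
    assert base_order == shifted_order


def test_summary_and_frame(rng):
    preds = [_img(rng.normal(0, 10, (4, 4)), subject=f"S{i}") for i in range(8)]
    refs = [_img(p.pixels + 2.0) for p in preds]
    masks = [_full((4, 4))] * 8
    records = batched_metrics(preds, refs, masks, batch_size=4, seed=0, comparison="X-vs-Y")
    frame = records_frame(records)
    assert list(frame.columns) == ["batch_id", "comparison", "rmse", "spearman_rho", "n_voxels"]
    s = summarize(records)
    assert s["rmse_mean"] == pytest.approx(2.0)
    assert s["n_batches"] == 2
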