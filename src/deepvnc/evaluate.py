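"""DNC composition and brain-masked similarity metrics.

The deep non-contrast (DNC) image is the L-VNC plus the network-predicted
difference. Similarity to the true non-contrast reference is quantified by
RMSE and Spearman's rank-order correlation over brain-mask voxels, computed
for batches of randomly grouped images (pooling each batch's masked voxels)
to stratify for the number of brain voxels per measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import BrainMask, HUImage


def compose_dnc(lvnc: HUImage, diff: HUImage) -> HUImage:
    """DNC = L-VNC + predicted difference, pixelwise and unclipped."""
    if lvnc.shape != diff.shape:
        raise ValueError("lvnc and diff shapes must agree")
    return lvnc.with_pixels(lvnc.pixels + diff.pixels)


def _masked_values(a: HUImage, b: HUImage, mask: BrainMask) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("images and mask must share one shape")
    if mask.n_true == 0:
        raise ValueError("mask has no true pixels")
    return a.pixels[mask.pixels], b.pixels[mask.pixels]


def masked_rmse(a: HUImage, b: HUImage, mask: BrainMask) -> float:
    """Root mean squared HU difference over masked pixels."""
    va, vb = _masked_values(a, b, mask)
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def masked_spearman(a: HUImage, b: HUImage, mask: BrainMask) -> float:
    """Spearman rank correlation of masked pixels (average ranks for ties)."""
    va, vb = _masked_values(a, b, mask)
    if va.size < 3:
        raise ValueError("Spearman correlation requires >= 3 masked pixels")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)


@dataclass
class MetricRecord:
    """Metrics of one batch of pooled masked voxels."""

    batch_id: int
    image_ids: list[str]
    rmse: float
    spearman_rho: float
    comparison: str
    n_voxels: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or not -1.0 <= self.spearman_rho <= 1.0 or self.n_voxels <= 0:
            raise ValueError("invalid metric record")


def _pooled(images: list[HUImage], masks: list[BrainMask]) -> np.ndarray:
    return np.concatenate([img.pixels[m.pixels] for img, m in zip(images, masks)])


def batched_metrics(
    preds: list[HUImage],
    refs: list[HUImage],
    masks: list[BrainMask],
    batch_size: int = 32,
    seed: int = 0,
    comparison: str = "",
    keep_partial: bool = False,
) -> list[MetricRecord]:
    """Shuffle images, group into batches, and score each batch's pooled voxels.

    The last incomplete batch is dropped unless ``keep_partial`` is set (the
    equal-size batches stratify for brain-voxel count). Deterministic given
    ``seed``.
    """
    if not preds or len(preds) != len(refs) or len(preds) != len(masks):
        raise ValueError("preds, refs and masks must be non-empty aligned lists")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    order = np.random.default_rng(seed).permutation(len(preds))
    records = []
    for batch_id, start in enumerate(range(0, len(order), batch_size)):
        idx = order[start : start + batch_size]
        if len(idx) < batch_size and not keep_partial:
            break
        p = [preds[i] for i in idx]
        r = [refs[i] for i in idx]
        m = [masks[i] for i in idx]
        vp, vr = _pooled(p, m), _pooled(r, m)
        rmse = float(np.sqrt(np.mean((vp - vr) ** 2)))
        rho = float(stats.spearmanr(vp, vr).statistic)
        records.append(
            MetricRecord(
                batch_id=batch_id,
                image_ids=[f"{preds[i].subject_id}/{preds[i].slice_id}" for i in idx],
                rmse=rmse,
                spearman_rho=rho,
                comparison=comparison,
                n_voxels=int(vp.size),
            )
        )
    if not records:
        raise ValueError("fewer images than one batch; reduce batch_size or keep_partial=True")
    return records


def records_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "batch_id": [r.batch_id for r in records],
            "comparison": [r.comparison for r in records],
            "rmse": [r.rmse for r in records],
            "spearman_rho": [r.spearman_rho for r in records],
            "n_voxels": [r.n_voxels for r in records],
        }
    )


def summarize(records: list[MetricRecord]) -> dict:
    """Mean and normal-approximation 95% CI half-width per metric."""
    rmse = np.array([r.rmse for r in records])
    rho = np.array([r.spearman_rho for r in records])

    def ci(x: np.ndarray) -> float:
        if x.size < 2:
            return float("nan")
        return float(1.96 * x.std(ddof=1) / np.sqrt(x.size))

    return {
        "n_batches": len(records),
        "rmse_mean": float(rmse.mean()),
        "rmse_ci95": ci(rmse),
        "spearman_mean": float(rho.mean()),
        "spearman_ci95": ci(rho),
    }
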