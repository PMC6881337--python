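"""End-to-end orchestration: simulate -> decompose -> lookup -> train -> score.

``prepare_data`` runs every physics stage (dataset simulation, three-material
decomposition, lookup construction on the training partition, L-VNC
generation, training-sample assembly); ``train_and_evaluate`` trains the
residual network on the prepared data and scores DNC, L-VNC and S-VNC against
the true non-contrast reference on the held-out test partition;
``run_pipeline`` chains the two and optionally writes the per-batch report
(CSV) and summary (JSON). Any stage failure aborts with the stage name and a
machine-readable code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .decomp import decompose
from .images import BrainMask, HUImage, erode_mask
from .lookup import LookupTable, build_lookup, inpaint_lookup, lookup_vnc, save_lookup
from .model import (
    NetworkConfig,
    TrainingHistory,
    TrainingSample,
    _block_mean,
    build_network,
    get_profile,
    make_training_samples,
    predict_difference,
    train_model,
)
from .phantom import (
    PhysicsConfig,
    SceneParams,
    SceneRecord,
    make_dataset,
    noiseless,
    physics_preset,
    with_class_bias,
)

COMPARISONS = ("DNC-vs-TNC", "L-VNC-vs-TNC", "S-VNC-vs-TNC")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs.

    ``seed`` drives dataset simulation and evaluation batching;
    ``train_seed`` drives network initialization and training, so several
    training replicates can share one dataset.
    """

    n_scenes: int = 200
    height: int = 64
    width: int = 64
    physics_name: str = "80/150Sn"
    inject_bias: bool = True
    vnc_bias: dict[int, float] | None = None
    zero_noise: bool = False  # strip acquisition noise and spectral tilt
    split_fractions: tuple[float, float, float] = (0.745, 0.145, 0.110)
    tnc_noise_sigma: float = 2.0
    scene_params: SceneParams = field(default_factory=SceneParams)
    profile: str = "desk"
    seed: int = 0
    train_seed: int = 0
    max_epochs: int = 30
    patience: int = 5
    eval_batch_size: int = 8
    keep_partial_batch: bool = False
    erode_diameter: int = 5
    median_kernel: int = 5
    lookup_iterations: int = 100
    out_dir: str | None = None

    def physics(self) -> PhysicsConfig:
        physics = physics_preset(self.physics_name)
        if self.zero_noise:
            physics = noiseless(physics)
        if self.inject_bias:
            physics = with_class_bias(physics, self.vnc_bias)
        return physics

    def network(self) -> NetworkConfig:
        profile = get_profile(self.profile)
        # work at native resolution when scenes are smaller than the profile's
        # input size (the network only ever downsamples, never upsamples)
        if min(self.height, self.width) < profile.input_size:
            from dataclasses import replace

            if self.height != self.width:
                raise ValueError("scenes smaller than the profile input size must be square")
            profile = replace(profile, input_size=self.height)
        return profile


@dataclass
class PipelineRecord:
    """One scene with every derived image the pipeline produced."""

    base: SceneRecord
    eroded_mask: BrainMask
    svnc: HUImage
    iodine: HUImage
    lvnc: HUImage | None = None
    sample: TrainingSample | None = None

    @property
    def partition(self) -> str:
        return self.base.partition


@dataclass
class PreparedData:
    config: PipelineConfig
    manifest: pd.DataFrame
    records: list[PipelineRecord]
    table: LookupTable

    def partition(self, name: str) -> list[PipelineRecord]:
        return [r for r in self.records if r.partition == name]


@dataclass
class PipelineReport:
    table: pd.DataFrame
    summaries: dict[str, dict]
    history: TrainingHistory
    partition_sizes: dict[str, int]


def _stage(name: str, code: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, code, str(exc)) from exc

    return wrap


def prepare_data(config: PipelineConfig) -> PreparedData:
    """Run the physics stages: simulate, decompose, lookup, L-VNC, samples."""
    physics = config.physics()
    net = config.network()

    run = _stage("simulate", "SIM")
    manifest, scenes = run(
        make_dataset,
        config.n_scenes,
        config.split_fractions,
        physics,
        config.seed,
        height=config.height,
        width=config.width,
        scene_params=config.scene_params,
        tnc_noise_sigma=config.tnc_noise_sigma,
        out_dir=config.out_dir,
    )

    records: list[PipelineRecord] = []
    run = _stage("decompose", "DECOMP")
    for rec in scenes:
        vnc, iod = run(decompose, rec.pair, physics.basis)
        eroded = _stage("mask", "ERODE")(erode_mask, rec.mask, config.erode_diameter)
        if eroded.n_true == 0:
            raise StageError("mask", "EMPTY", f"mask of {rec.subject_id} empty after erosion")
        records.append(PipelineRecord(base=rec, eroded_mask=eroded, svnc=vnc, iodine=iod))

    train_recs = [r for r in records if r.partition == "train"]
    run = _stage("build_lookup", "LOOKUP")
    table = run(
        build_lookup,
        [r.base.pair for r in train_recs],
        [r.svnc for r in train_recs],
        [r.eroded_mask for r in train_recs],
    )
    table = run(inpaint_lookup, table, config.lookup_iterations)

    run = _stage("lvnc", "APPLY")
    for rec in records:
        rec.lvnc = run(lookup_vnc, table, rec.base.pair, config.median_kernel)
        rec.sample = _stage("samples", "RESAMPLE")(
            make_training_samples,
            rec.base.pair, rec.lvnc, rec.base.tnc, rec.eroded_mask, net.input_size,
        )
    return PreparedData(config=config, manifest=manifest, records=records, table=table)


def train_and_evaluate(
    data: PreparedData, train_seed: int | None = None
) -> PipelineReport:
    """Train the residual network and score the held-out test partition."""
    config = data.config
    net_cfg = config.network()
    seed = config.train_seed if train_seed is None else train_seed

    train = [r.sample for r in data.partition("train")]
    val = [r.sample for r in data.partition("val")]
    test = data.partition("test")
    if not train or not val or not test:
        raise StageError("train", "EMPTY", "a partition is empty")

    run = _stage("train", "FIT")
    model = run(build_network, net_cfg, seed)
    model, history = run(
        train_model, model, train, val, net_cfg,
        patience=config.patience, max_epochs=config.max_epochs, seed=seed,
    )

    run = _stage("predict", "INFER")
    dnc, lvnc_r, svnc_r, tnc_r, masks = [], [], [], [], []
    for rec in test:
        diff = run(predict_difference, model, rec.sample)
        lvnc_img = HUImage(rec.sample.lvnc_hu, subject_id=rec.base.subject_id,
                           slice_id=rec.base.slice_id)
        dnc.append(ev.compose_dnc(lvnc_img, diff))
        lvnc_r.append(lvnc_img)
        svnc_r.append(lvnc_img.with_pixels(_block_mean(rec.svnc.pixels, net_cfg.input_size)))
        tnc_r.append(lvnc_img.with_pixels(rec.sample.tnc_hu))
        masks.append(BrainMask(rec.sample.mask))

    run = _stage("evaluate", "METRICS")
    frames, summaries = [], {}
    for name, preds in zip(COMPARISONS, (dnc, lvnc_r, svnc_r)):
        records = run(
            ev.batched_metrics, preds, tnc_r, masks,
            batch_size=config.eval_batch_size, seed=config.seed,
            comparison=name, keep_partial=config.keep_partial_batch,
        )
        frames.append(ev.records_frame(records))
        summaries[name] = ev.summarize(records)

    return PipelineReport(
        table=pd.concat(frames, ignore_index=True),
        summaries=summaries,
        history=history,
        partition_sizes={p: len(data.partition(p)) for p in ("train", "val", "test")},
    )


def write_report(data: PreparedData, report: PipelineReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "report.csv", index=False)
    payload = {
        "summaries": report.summaries,
        "partition_sizes": report.partition_sizes,
        "history": {
            "train_loss": report.history.train_loss,
            "val_loss": report.history.val_loss,
            "epochs_run": report.history.epochs_run,
            "stop_reason": report.history.stop_reason,
        },
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=2))
    save_lookup(data.table, out / "lookup.npz")
    data.manifest.to_csv(out / "manifest.csv", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """The full framework: physics stages, training, held-out evaluation."""
    data = prepare_data(config)
    report = train_and_evaluate(data)
    if config.out_dir is not None:
        write_report(data, report, config.out_dir)
    return report
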