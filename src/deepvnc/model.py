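"""Residual dilated CNN predicting the TNC - L-VNC difference image.

The network is a ResNet-style image-to-image regressor operating at constant
spatial resolution: a 3x3 projection lifts the 3-channel input (low-energy,
high-energy, median-filtered L-VNC) to the working width, three groups of
three residual blocks follow with per-group dilation 1, 2 and 4 (growing the
receptive field without downsampling), and a final 1x1 convolution maps back
to one channel — the predicted difference in HU. Each residual block is
conv -> norm -> ReLU -> dropout -> conv -> norm added to its input.

Training minimizes the RMSE between predicted and target difference over
brain-mask pixels only (pooled per batch), with Adam, L2 weight regularization
and early stopping once the validation loss plateaus.

Everything — convolution forward/backward (im2col), batch normalization,
inverted dropout, Adam — is implemented directly on NumPy arrays, which keeps
the desk-scale profile fully deterministic and dependency-light; the
paper-faithful profile (64 channels, 256x256, lr 1e-5, dropout 0.5, L2 0.02)
is expressed by the same code.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .images import BrainMask, HUImage
from .phantom_types import DECTPair

#: Affine HU window mapped to [0, 1] for the network's input channels.
HU_WINDOW = (-100.0, 300.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimization settings.

    The defaults are the published configuration (64 channels at 256x256 with
    lr 1e-5, dropout 0.5, L2 0.02, batch 8); ``DESK_PROFILE`` is a small CPU
    profile for synthetic experiments.
    """

    groups: int = 3
    blocks_per_group: int = 3
    dilations: tuple[int, ...] = (1, 2, 4)
    channels: int = 64
    kernel: int = 3
    dropout_rate: float = 0.5
    weight_decay: float = 0.02
    learning_rate: float = 1e-5
    batch_size: int = 8
    input_size: int = 256
    norm: str = "batch"  # "batch" | "none"
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.groups != len(self.dilations):
            raise ValueError("groups must equal len(dilations)")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        if self.norm not in ("batch", "none"):
            raise ValueError("norm must be 'batch' or 'none'")


PAPER_PROFILE = NetworkConfig()
DESK_PROFILE = NetworkConfig(
    channels=8, input_size=64, learning_rate=1e-3, dropout_rate=0.1, weight_decay=1e-4
)


def get_profile(name: str) -> NetworkConfig:
    profiles = {"paper": PAPER_PROFILE, "desk": DESK_PROFILE}
    try:
        return profiles[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(profiles)}")


# ---------------------------------------------------------------------------
# Layers


class Conv2d:
    """Same-padded 2-D convolution with dilation, via im2col and one GEMM.

    Activations use a channel-major (C, B, H, W) layout internally: the GEMM
    output is then directly contiguous and per-channel reductions are cheap.
    The weight matrix has shape (cout, cin*k*k) with tap index c*k*k + i*k + j.
    """

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int, rng: np.random.Generator):
        self.cin, self.cout, self.k, self.d = cin, cout, kernel, dilation
        fan_in = cin * kernel * kernel
        self.W = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(C, B, H, W) -> (C*k*k, B*H*W) patch matrix."""
        C, B, H, W = x.shape
        k, d = self.k, self.d
        if k == 1:
            return x.reshape(C, B * H * W)
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((C, k * k, B, H, W), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, i * k + j] = xp[:, :, i * d : i * d + H, j * d : j * d + W]
        return cols.reshape(C * k * k, B * H * W)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        C, B, H, W = x.shape
        cols = self._im2col(x)
        out = self.W @ cols + self.b[:, None]
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(self.cout, B, H, W)

    def backward(self, g: np.ndarray) -> np.ndarray:
        C, B, H, W = self._shape
        k, d = self.k, self.d
        gf = g.reshape(self.cout, B * H * W)
        self.gW = gf @ self._cols.T
        self.gb = gf.sum(axis=1)
        self._cols = None
        if k == 1:
            return (self.W.T @ gf).reshape(C, B, H, W)
        dcols = (self.W.T @ gf).reshape(C, k * k, B, H, W)
        p = d * (k // 2)
        dxp = np.zeros((C, B, H + 2 * p, W + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d : i * d + H, j * d : j * d + W] += dcols[:, i * k + j]
        return dxp[:, :, p : p + H, p : p + W]

    def params(self):
        return [(self, "W", "gW", True), (self, "b", "gb", False)]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._xhat = None
        self._ivar = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # channel-major (C, B, H, W): per-channel reductions are contiguous
        sh = (-1, 1, 1, 1)
        if train:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
            ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (x - mu.astype(np.float32).reshape(sh)) * ivar.reshape(sh)
            self._xhat, self._ivar = xhat, ivar
        else:
            ivar = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(sh)) * ivar.reshape(sh)
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, g: np.ndarray) -> np.ndarray:
        sh = (-1, 1, 1, 1)
        xhat, ivar = self._xhat, self._ivar
        C = g.shape[0]
        n = g.size // C
        self.ggamma = (g * xhat).sum(axis=(1, 2, 3))
        self.gbeta = g.sum(axis=(1, 2, 3))
        dx = (self.gamma * ivar).reshape(sh) / n * (
            n * g - self.gbeta.reshape(sh) - xhat * self.ggamma.reshape(sh)
        )
        self._xhat = None
        return dx.astype(g.dtype)

    def params(self):
        return [(self, "gamma", "ggamma", False), (self, "beta", "gbeta", False)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._pos
        self._pos = None
        return out

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate
        self._scale_mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = rng.random(x.shape, dtype=np.float32) >= self.rate
        self._scale_mask = keep.astype(np.float32) / (1.0 - self.rate)
        return x * self._scale_mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._scale_mask is None:
            return g
        out = g * self._scale_mask
        self._scale_mask = None
        return out

    def params(self):
        return []


class ResidualBlock:
    """conv -> norm -> ReLU -> dropout -> conv -> norm, added to the input."""

    def __init__(self, channels: int, kernel: int, dilation: int, dropout: float,
                 norm: str, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, kernel, dilation, rng)
        self.conv2 = Conv2d(channels, channels, kernel, dilation, rng)
        self.bn1 = BatchNorm2d(channels) if norm == "batch" else None
        self.bn2 = BatchNorm2d(channels) if norm == "batch" else None
        self.relu = ReLU()
        self.drop = Dropout(dropout)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        h = self.conv1.forward(x, train)
        if self.bn1 is not None:
            h = self.bn1.forward(h, train)
        h = self.relu.forward(h, train)
        h = self.drop.forward(h, train, rng)
        h = self.conv2.forward(h, train)
        if self.bn2 is not None:
            h = self.bn2.forward(h, train)
        return x + h

    def backward(self, g: np.ndarray) -> np.ndarray:
        h = self.bn2.backward(g) if self.bn2 is not None else g
        h = self.conv2.backward(h)
        h = self.drop.backward(h)
        h = self.relu.backward(h)
        if self.bn1 is not None:
            h = self.bn1.backward(h)
        return g + self.conv1.backward(h)

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.bn1 is not None:
            out += self.bn1.params() + self.bn2.params()
        return out


class ResidualNet:
    """Projection -> grouped dilated residual blocks -> 1x1 head."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        c = config.channels
        self.proj = Conv2d(config.in_channels, c, config.kernel, 1, rng)
        self.proj_relu = ReLU()
        self.blocks = [
            ResidualBlock(c, config.kernel, dilation, config.dropout_rate, config.norm, rng)
            for dilation in config.dilations
            for _ in range(config.blocks_per_group)
        ]
        self.head = Conv2d(c, config.out_channels, 1, 1, rng)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        # public interface is batch-first (B, C, H, W); internals channel-major
        h = np.ascontiguousarray(np.transpose(x, (1, 0, 2, 3)), dtype=np.float32)
        h = self.proj.forward(h, train)
        h = self.proj_relu.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train, rng)
        out = self.head.forward(h, train)
        return np.transpose(out, (1, 0, 2, 3))

    def backward(self, g: np.ndarray) -> None:
        h = np.ascontiguousarray(np.transpose(g, (1, 0, 2, 3)), dtype=np.float32)
        h = self.head.backward(h)
        for block in reversed(self.blocks):
            h = block.backward(h)
        h = self.proj_relu.backward(h)
        self.proj.backward(h)

    def params(self):
        out = self.proj.params()
        for block in self.blocks:
            out += block.params()
        return out + self.head.params()

    @property
    def n_parameters(self) -> int:
        return sum(getattr(layer, name).size for layer, name, _, _ in self.params())

    def get_weights(self) -> list[np.ndarray]:
        state = [getattr(layer, name).copy() for layer, name, _, _ in self.params()]
        for block in self.blocks:
            for bn in (block.bn1, block.bn2):
                if bn is not None:
                    state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer, name, _, _ in self.params():
            setattr(layer, name, state[i].copy())
            i += 1
        for block in self.blocks:
            for bn in (block.bn1, block.bn2):
                if bn is not None:
                    bn.running_mean = state[i].copy()
                    bn.running_var = state[i + 1].copy()
                    i += 2

    def zero_head(self) -> None:
        """Force the final 1x1 convolution to the zero map (for diagnostics)."""
        self.head.W[:] = 0.0
        self.head.b[:] = 0.0


def build_network(config: NetworkConfig, seed: int) -> ResidualNet:
    """Construct the network with He-normal initialization, seeded."""
    return ResidualNet(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Training samples


@dataclass
class TrainingSample:
    """One network example: 3-channel normalized input, HU difference target.

    ``input`` stacks the window-normalized low, high and (median-filtered)
    L-VNC channels; ``target`` is TNC - L-VNC in raw HU at the working
    resolution, so that target + L-VNC reconstructs TNC exactly.
    """

    input: np.ndarray  # (3, size, size) float32
    target: np.ndarray  # (1, size, size) float32
    mask: np.ndarray  # (size, size) bool
    subject_id: str = ""
    slice_id: str = "0"

    @property
    def lvnc_hu(self) -> np.ndarray:
        lo, hi = HU_WINDOW
        return self.input[2].astype(np.float64) * (hi - lo) + lo

    @property
    def tnc_hu(self) -> np.ndarray:
        return self.target[0].astype(np.float64) + self.lvnc_hu


def _block_mean(arr: np.ndarray, size: int) -> np.ndarray:
    H, W = arr.shape
    if H == size and W == size:
        return arr.astype(float)
    if H % size or W % size:
        raise ValueError(f"cannot area-average {arr.shape} down to {size}x{size}")
    return arr.reshape(size, H // size, size, W // size).mean(axis=(1, 3))


def normalize_hu(pixels: np.ndarray) -> np.ndarray:
    """Affine map of the HU window [-100, 300] onto [0, 1]."""
    lo, hi = HU_WINDOW
    return (np.asarray(pixels, dtype=float) - lo) / (hi - lo)


def make_training_samples(
    pair: DECTPair, lvnc: HUImage, tnc: HUImage, mask: BrainMask, size: int
) -> TrainingSample:
    """Resample to the working resolution and assemble one training sample.

    Images are area-average downsampled; the mask keeps pixels with > 0.5
    source coverage. The L-VNC channel is expected to be median filtered
    already (the pipeline filters before samples are formed).
    """
    shapes = {pair.shape, lvnc.shape, tnc.shape, mask.shape}
    if len(shapes) != 1:
        raise ValueError("pair, lvnc, tnc and mask must share one shape")
    low = _block_mean(pair.low.pixels, size)
    high = _block_mean(pair.high.pixels, size)
    lvnc_r = _block_mean(lvnc.pixels, size)
    tnc_r = _block_mean(tnc.pixels, size)
    mask_r = _block_mean(mask.pixels.astype(float), size) > 0.5
    if not mask_r.any():
        raise ValueError("mask is empty after resampling")
    x = np.stack([normalize_hu(low), normalize_hu(high), normalize_hu(lvnc_r)]).astype(np.float32)
    target = (tnc_r - lvnc_r)[None].astype(np.float32)
    return TrainingSample(
        input=x, target=target, mask=mask_r,
        subject_id=pair.low.subject_id, slice_id=pair.low.slice_id,
    )


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainingHistory:
    """Per-epoch masked-RMSE losses (HU) and the stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epochs_run: int = 0
    stop_reason: str = ""
    seed: int = 0

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss)


class Adam:
    def __init__(self, model: ResidualNet, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n, _, _ in model.params()]
        self.v = [np.zeros_like(getattr(l, n)) for l, n, _, _ in model.params()]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (layer, name, gname, decay) in enumerate(self.model.params()):
            w = getattr(layer, name)
            g = getattr(layer, gname).astype(np.float32)
            if decay and self.wd:
                g = g + self.wd * w
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            w -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


def masked_rmse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    """RMSE over the pooled masked pixels of a batch, and its gradient."""
    m = mask.astype(pred.dtype)
    diff = (pred - target) * m
    n = m.sum()
    if n == 0:
        raise ValueError("masked loss requires at least one masked pixel")
    loss = float(np.sqrt((diff**2).sum() / n))
    grad = diff / (n * max(loss, 1e-12))
    return loss, grad.astype(np.float32)


def _stack(samples: list[TrainingSample]):
    x = np.stack([s.input for s in samples])
    t = np.stack([s.target for s in samples])
    m = np.stack([s.mask[None] for s in samples])
    return x, t, m


def _eval_loss(model: ResidualNet, samples: list[TrainingSample], batch_size: int) -> float:
    losses = []
    for start in range(0, len(samples), batch_size):
        x, t, m = _stack(samples[start : start + batch_size])
        pred = model.forward(x, train=False)
        loss, _ = masked_rmse_loss(pred, t, m)
        losses.append(loss)
    return float(np.mean(losses))


def train_model(
    model: ResidualNet,
    train: list[TrainingSample],
    val: list[TrainingSample],
    config: NetworkConfig,
    patience: int = 5,
    max_epochs: int = 30,
    seed: int = 0,
    min_delta: float = 0.01,
) -> tuple[ResidualNet, TrainingHistory]:
    """Train until the validation loss plateaus or ``max_epochs`` is reached.

    The plateau rule is early stopping: no improvement of the validation
    masked RMSE by more than ``min_delta`` HU for ``patience`` consecutive
    epochs. The returned model carries the best-validation weights. Fully
    seeded: data order, dropout masks and (via build_network) initialization.
    """
    if not train or not val:
        raise ValueError("train and val sample lists must be non-empty")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    rng = np.random.default_rng(seed)
    opt = Adam(model, lr=config.learning_rate, weight_decay=config.weight_decay)
    history = TrainingHistory(seed=seed)
    best_val = np.inf
    best_state = model.get_weights()
    stale = 0
    stop_reason = "max_epochs"
    for epoch in range(max_epochs):
        order = rng.permutation(len(train))
        batch_losses = []
        for start in range(0, len(train), config.batch_size):
            batch = [train[i] for i in order[start : start + config.batch_size]]
            x, t, m = _stack(batch)
            pred = model.forward(x, train=True, rng=rng)
            loss, grad = masked_rmse_loss(pred, t, m)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            batch_losses.append(loss)
        val_loss = _eval_loss(model, val, config.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val_loss)
        history.epochs_run = epoch + 1
        if best_val - val_loss > min_delta:
            best_val = val_loss
            best_state = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                stop_reason = "plateau"
                break
    history.stop_reason = stop_reason
    model.set_weights(best_state)
    return model, history


def save_model(model: ResidualNet, history: TrainingHistory | None, out_dir) -> None:
    """Serialize weights (npz), configuration (YAML) and training history (JSON)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = model.get_weights()
    np.savez_compressed(out / "weights.npz", **{f"p{i}": w for i, w in enumerate(state)})
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(model.config)))
    if history is not None:
        (out / "history.json").write_text(json.dumps(asdict(history), indent=2))


def load_model(model_dir) -> ResidualNet:
    from pathlib import Path

    import yaml

    d = Path(model_dir)
    raw = yaml.safe_load((d / "config.yaml").read_text())
    raw["dilations"] = tuple(raw["dilations"])
    config = NetworkConfig(**raw)
    model = build_network(config, seed=0)
    with np.load(d / "weights.npz") as archive:
        state = [archive[f"p{i}"] for i in range(len(archive.files))]
    model.set_weights(state)
    return model


def predict_difference(model: ResidualNet, sample: TrainingSample) -> HUImage:
    """Predicted TNC - L-VNC difference map (HU), dropout disabled."""
    size = model.config.input_size
    if sample.input.shape[1:] != (size, size):
        raise ValueError(
            f"sample spatial shape {sample.input.shape[1:]} != model input size {size}"
        )
    out = model.forward(sample.input[None], train=False)
    return HUImage(pixels=out[0, 0].astype(float), subject_id=sample.subject_id,
                   slice_id=sample.slice_id)
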