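"""Synthetic brain DECT phantoms: scenes, forward simulation, dataset assembly.

The generator stands in for a clinical stroke cohort. Each "patient" is an
elliptical brain section partitioned into CSF, white matter and gray matter by
a smooth random field, optionally carrying elliptical hemorrhagic lesions, plus
a smooth non-negative iodine enhancement map confined to the brain mask.

The dual-energy forward model is linear in iodine concentration and places
unenhanced tissues on the water-hemorrhage spectral line of the decomposition
basis: a tissue whose non-contrast value is B maps to the (low, high) point
``w + (B - vnc_w)/(vnc_b - vnc_w) * (b - w)`` so that three-material
decomposition recovers B exactly in the noiseless case. Iodine adds
``r*g*concentration`` HU at low energy and ``g*concentration`` at high energy
(ratio r, default 2.12, the protocol's iodine ratio), a per-class spectral tilt
models deviations from the two-material mixture assumption (this is what makes
vendor-style VNC images systematically biased against true non-contrast scans),
and independent Gaussian HU noise is added per energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .decomp import MaterialBasis
from .images import BrainMask, HUImage, write_image
from .phantom_types import DECTPair

# Tissue class codes.
BACKGROUND, CSF, WHITE, GRAY, HEMORRHAGE = 0, 1, 2, 3, 4

DEFAULT_BASE_HU: dict[int, float] = {
    BACKGROUND: -1000.0,
    CSF: 8.0,
    WHITE: 25.0,
    GRAY: 38.0,
    HEMORRHAGE: 65.0,
}

#: Default per-class VNC bias (HU) used to emulate anatomy-dependent vendor
#: decomposition error; applied through `with_class_bias`.
DEFAULT_VNC_BIAS: dict[int, float] = {CSF: 4.0, WHITE: -8.0, GRAY: 10.0, HEMORRHAGE: -15.0}


@dataclass(frozen=True)
class SceneParams:
    """Geometry and texture parameters of a synthetic brain section."""

    axis_frac: tuple[float, float] = (0.30, 0.42)  # ellipse semi-axes / image size
    csf_fraction: float = 0.10
    gray_fraction: float = 0.42
    field_smoothness: float = 0.12  # Gaussian sigma / min(image size)
    lesion_probability: float = 0.6
    max_lesions: int = 2
    lesion_axis_frac: tuple[float, float] = (0.04, 0.10)
    iodine_fill: float = 0.4  # fraction of brain receiving enhancement
    iodine_max: float = 1.0  # peak concentration, arbitrary units


@dataclass
class PhantomScene:
    """Ground truth for one synthetic slice: labels, iodine map, brain mask."""

    labels: np.ndarray
    base_hu: dict[int, float]
    iodine_map: np.ndarray
    mask: BrainMask
    seed: int

    def __post_init__(self) -> None:
        if self.labels.shape != self.iodine_map.shape or self.labels.shape != self.mask.shape:
            raise ValueError("labels, iodine_map and mask must share one shape")
        if np.any(self.iodine_map[~self.mask.pixels] != 0):
            raise ValueError("iodine_map must be zero outside the brain mask")
        if not np.array_equal(self.mask.pixels, self.labels != BACKGROUND):
            raise ValueError("mask must equal labels != background")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class PhysicsConfig:
    """A named acquisition physics: spectra, iodine behaviour and noise.

    ``iodine_ratio`` is the low/high-energy enhancement ratio r;
    ``iodine_high_gain`` g converts concentration units to high-energy HU.
    ``tissue_energy_tilt`` maps tissue class -> (low, high) HU offsets from the
    two-material spectral line; ``basis`` is the decomposition geometry the
    tissues are simulated against.
    """

    name: str = "80/150Sn"
    iodine_ratio: float = 2.12
    iodine_high_gain: float = 25.0
    tissue_energy_tilt: dict[int, tuple[float, float]] = field(default_factory=dict)
    noise_sigma_low: float = 3.0
    noise_sigma_high: float = 2.0
    basis: MaterialBasis | None = None

    def __post_init__(self) -> None:
        if self.iodine_ratio <= 0 or self.iodine_high_gain <= 0:
            raise ValueError("iodine_ratio and iodine_high_gain must be positive")
        if self.noise_sigma_low < 0 or self.noise_sigma_high < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.basis is None:
            object.__setattr__(self, "basis", MaterialBasis(iodine_ratio=self.iodine_ratio))

    def tilt_arrays(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tl = np.zeros(labels.shape)
        th = np.zeros(labels.shape)
        for cls, (lo, hi) in self.tissue_energy_tilt.items():
            sel = labels == cls
            tl[sel] = lo
            th[sel] = hi
        return tl, th


#: Small default tilts (<= 3 HU) so the (low, high) -> VNC relation is a
#: genuinely 2-D surface rather than a single line.
_DEFAULT_TILT = {CSF: (-1.0, 1.0), WHITE: (1.0, -1.0), GRAY: (2.0, -1.0), HEMORRHAGE: (3.0, -3.0)}

PHYSICS_PRESETS: dict[str, PhysicsConfig] = {
    # Dual-source 80 kVp / 150 kVp-Sn protocol: noisier low-energy channel.
    "80/150Sn": PhysicsConfig(
        name="80/150Sn",
        tissue_energy_tilt=dict(_DEFAULT_TILT),
        noise_sigma_low=3.0,
        noise_sigma_high=2.0,
    ),
    # 100 kVp / 150 kVp-Sn: less spectral separation, slightly less noise.
    "100/150Sn": PhysicsConfig(
        name="100/150Sn",
        tissue_energy_tilt={c: (0.8 * l, 0.8 * h) for c, (l, h) in _DEFAULT_TILT.items()},
        noise_sigma_low=2.4,
        noise_sigma_high=1.8,
    ),
}


def physics_preset(name: str) -> PhysicsConfig:
    try:
        return PHYSICS_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown physics preset {name!r}; available: {sorted(PHYSICS_PRESETS)}")


def with_class_bias(
    physics: PhysicsConfig, vnc_bias: dict[int, float] | None = None
) -> PhysicsConfig:
    """Add per-class spectral tilt that biases the decomposed VNC by ``vnc_bias`` HU.

    The tilt is taken along the water-hemorrhage axis, so the decomposition's
    VNC output shifts by exactly the requested amount per class while the
    iodine estimate is untouched. This emulates anatomy-dependent systematic
    error of vendor VNC images relative to true non-contrast scans.
    """
    if vnc_bias is None:
        vnc_bias = DEFAULT_VNC_BIAS
    basis = physics.basis
    ul, uh = basis.base_axis
    span = basis.hemorrhage_vnc - (
        basis.vnc_mix * basis.water_point[0] + (1 - basis.vnc_mix) * basis.water_point[1]
    )
    tilt = dict(physics.tissue_energy_tilt)
    for cls, bias in vnc_bias.items():
        tl, th = tilt.get(cls, (0.0, 0.0))
        tilt[cls] = (tl + bias * ul / span, th + bias * uh / span)
    return replace(physics, tissue_energy_tilt=tilt)


def noiseless(physics: PhysicsConfig, keep_tilt: bool = False) -> PhysicsConfig:
    """Copy of ``physics`` with zero noise (and, by default, zero tilt)."""
    tilt = physics.tissue_energy_tilt if keep_tilt else {}
    return replace(physics, noise_sigma_low=0.0, noise_sigma_high=0.0, tissue_energy_tilt=tilt)


def _ellipse(shape, center, semi_axes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / semi_axes[0]) ** 2 + ((xx - center[1]) / semi_axes[1]) ** 2 <= 1.0


def make_scene(
    height: int,
    width: int,
    seed: int,
    params: SceneParams = SceneParams(),
    base_hu: dict[int, float] | None = None,
) -> PhantomScene:
    """Generate one synthetic brain slice; deterministic given the seed."""
    if height < 16 or width < 16:
        raise ValueError("scene dimensions must be at least 16x16")
    rng = np.random.default_rng(seed)
    base_hu = dict(DEFAULT_BASE_HU if base_hu is None else base_hu)

    center = (
        height / 2 + rng.uniform(-0.03, 0.03) * height,
        width / 2 + rng.uniform(-0.03, 0.03) * width,
    )
    semi = (rng.uniform(*params.axis_frac) * height, rng.uniform(*params.axis_frac) * width)
    inside = _ellipse((height, width), center, semi)

    sigma = params.field_smoothness * min(height, width)
    tissue_field = gaussian_filter(rng.standard_normal((height, width)), sigma)
    labels = np.full((height, width), BACKGROUND, dtype=np.int64)
    vals = tissue_field[inside]
    q_csf = np.quantile(vals, params.csf_fraction)
    q_gray = np.quantile(vals, 1.0 - params.gray_fraction)
    labels[inside] = WHITE
    labels[inside & (tissue_field <= q_csf)] = CSF
    labels[inside & (tissue_field > q_gray)] = GRAY

    if rng.random() < params.lesion_probability:
        n_lesions = int(rng.integers(1, params.max_lesions + 1))
        rows, cols = np.nonzero(inside)
        for _ in range(n_lesions):
            k = int(rng.integers(rows.size))
            axes = (
                rng.uniform(*params.lesion_axis_frac) * min(height, width),
                rng.uniform(*params.lesion_axis_frac) * min(height, width),
            )
            lesion = _ellipse((height, width), (rows[k], cols[k]), axes)
            labels[lesion & inside] = HEMORRHAGE

    iodine_field = gaussian_filter(rng.standard_normal((height, width)), sigma)
    thr = np.quantile(iodine_field[inside], 1.0 - params.iodine_fill)
    iodine = np.clip(iodine_field - thr, 0.0, None)
    iodine[~inside] = 0.0
    peak = iodine.max()
    if peak > 0:
        iodine *= params.iodine_max / peak

    return PhantomScene(
        labels=labels,
        base_hu=base_hu,
        iodine_map=iodine,
        mask=BrainMask(pixels=inside),
        seed=seed,
    )


def _base_image(scene: PhantomScene) -> np.ndarray:
    out = np.empty(scene.shape)
    for cls, hu in scene.base_hu.items():
        out[scene.labels == cls] = hu
    return out


def render_tnc(scene: PhantomScene, noise_sigma: float, seed: int,
               subject_id: str = "", slice_id: str = "0") -> HUImage:
    """Render the ground-truth non-contrast image: class base HU plus noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    pixels = _base_image(scene)
    if noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, noise_sigma, scene.shape)
    return HUImage(pixels=pixels, subject_id=subject_id, slice_id=slice_id)


def simulate_dect(scene: PhantomScene, physics: PhysicsConfig, seed: int,
                  subject_id: str = "", slice_id: str = "0") -> DECTPair:
    """Simulate an aligned low/high-energy pair from a phantom scene.

    Unenhanced tissues lie on the basis's water-hemorrhage spectral line (so
    noiseless zero-tilt decomposition returns the non-contrast values
    exactly); iodine enhancement obeys the configured low/high ratio exactly
    in the noiseless model.
    """
    rng = np.random.default_rng(seed)
    basis = physics.basis
    base = _base_image(scene)
    mu = basis.vnc_mix
    vnc_w = mu * basis.water_point[0] + (1 - mu) * basis.water_point[1]
    a = (base - vnc_w) / (basis.hemorrhage_vnc - vnc_w)
    ul, uh = basis.base_axis
    tl, th = physics.tilt_arrays(scene.labels)
    r, g = physics.iodine_ratio, physics.iodine_high_gain
    low = basis.water_point[0] + a * ul + tl + r * g * scene.iodine_map
    high = basis.water_point[1] + a * uh + th + g * scene.iodine_map
    if physics.noise_sigma_low > 0:
        low = low + rng.normal(0.0, physics.noise_sigma_low, scene.shape)
    if physics.noise_sigma_high > 0:
        high = high + rng.normal(0.0, physics.noise_sigma_high, scene.shape)
    return DECTPair(
        low=HUImage(pixels=low, subject_id=subject_id, slice_id=slice_id),
        high=HUImage(pixels=high, subject_id=subject_id, slice_id=slice_id),
        physics_name=physics.name,
    )


def apportion(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of ``n`` items; every share >= 1.

    Ties in fractional remainder break toward the earlier partition.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0):
        raise ValueError("all split fractions must be positive")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions.sum()!r}")
    if n < fractions.size:
        raise ValueError(f"{n} scenes cannot populate {fractions.size} partitions")
    quotas = n * fractions
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    while np.any(counts == 0):
        counts[int(np.argmin(counts))] += 1
        counts[int(np.argmax(counts))] -= 1
    return counts.tolist()


@dataclass
class SceneRecord:
    """One generated slice with every image the pipeline consumes."""

    subject_id: str
    slice_id: str
    partition: str
    scene: PhantomScene
    tnc: HUImage
    pair: DECTPair
    mask: BrainMask


PARTITIONS = ("train", "val", "test")


def make_dataset(
    n_scenes: int,
    split_fractions: tuple[float, float, float],
    physics: PhysicsConfig,
    seed: int,
    height: int = 64,
    width: int = 64,
    scene_params: SceneParams = SceneParams(),
    tnc_noise_sigma: float = 2.0,
    out_dir=None,
) -> tuple[pd.DataFrame, list[SceneRecord]]:
    """Generate a patient-partitioned synthetic dataset.

    Each scene is one synthetic patient assigned to exactly one of
    train/val/test by largest-remainder apportionment of ``split_fractions``.
    Returns the manifest (subject_id, slice_id, partition and, when
    ``out_dir`` is given, file paths of the written low/high/TNC archives)
    together with the in-memory records. Deterministic given ``seed``.
    """
    if n_scenes < 3:
        raise ValueError("need at least 3 scenes to populate train/val/test")
    counts = apportion(n_scenes, split_fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_scenes)
    partition_of = {}
    start = 0
    for part, cnt in zip(PARTITIONS, counts):
        for idx in order[start : start + cnt]:
            partition_of[int(idx)] = part
        start += cnt

    records: list[SceneRecord] = []
    rows = []
    for i in range(n_scenes):
        subject = f"S{i:04d}"
        scene_seed, tnc_seed, dect_seed = (int(s) for s in rng.integers(0, 2**31, size=3))
        scene = make_scene(height, width, scene_seed, scene_params)
        tnc = render_tnc(scene, tnc_noise_sigma, tnc_seed, subject_id=subject)
        pair = simulate_dect(scene, physics, dect_seed, subject_id=subject)
        rec = SceneRecord(
            subject_id=subject,
            slice_id="0",
            partition=partition_of[i],
            scene=scene,
            tnc=tnc,
            pair=pair,
            mask=scene.mask,
        )
        records.append(rec)
        row = {"subject_id": subject, "slice_id": "0", "partition": rec.partition}
        if out_dir is not None:
            from pathlib import Path

            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            for tag, img in (("low", pair.low), ("high", pair.high), ("tnc", tnc)):
                p = d / f"{subject}_{tag}.npz"
                write_image(img, p, mask=scene.mask)
                row[f"path_{tag}"] = str(p)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest, records
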