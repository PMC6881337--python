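"""The 2-D intensity lookup: (low HU, high HU) -> VNC value.

This is the physics-informed stage of the framework. Every masked pixel of the
training images contributes its decomposed VNC value to the bin containing its
(low, high) pair; observed cells hold the mean of their contributions. Cells
never hit by data are imputed with an iterative penalized-least-squares
smoother: a discrete-cosine-transform filter whose smoothing parameter decays
geometrically over a fixed number of iterations, with observed cells re-imposed
each pass; anything still undefined afterwards is filled with zeros. The
finished table is applied pixelwise (nearest cell, edges clamped) to produce
lookup-VNC (L-VNC) images, which are then median filtered to suppress noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn
from scipy.ndimage import median_filter

from .images import BrainMask, HUImage
from .phantom_types import DECTPair

logger = logging.getLogger(__name__)


def hu_bin_edges(lo: float = -200.0, hi: float = 400.0, width: float = 1.0) -> np.ndarray:
    """Uniform HU bin edges; the default is 1-HU bins over [-200, 400]."""
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


@dataclass
class LookupTable:
    """2-D grid over binned (low, high) HU pairs holding a VNC value per cell."""

    values: np.ndarray
    observed: np.ndarray
    counts: np.ndarray
    low_edges: np.ndarray
    high_edges: np.ndarray
    fill_value_policy: str = "zero"

    def __post_init__(self) -> None:
        expected = (len(self.low_edges) - 1, len(self.high_edges) - 1)
        for name in ("values", "observed", "counts"):
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ValueError(f"{name} shape {arr.shape} != bin grid {expected}")
        for edges in (self.low_edges, self.high_edges):
            if len(edges) < 2 or np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing with >= 2 entries")
        if not np.array_equal(self.observed, self.counts > 0):
            raise ValueError("observed flags must equal counts > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def fully_imputed(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


def _bin_index(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, int]:
    """Cell index per value, clamping out-of-range values to the edge bins."""
    idx = np.searchsorted(edges, values, side="right") - 1
    n_out = int(np.count_nonzero((idx < 0) | (idx > len(edges) - 2)))
    return np.clip(idx, 0, len(edges) - 2), n_out


def build_lookup(
    pairs: list[DECTPair],
    vncs: list[HUImage],
    masks: list[BrainMask],
    low_edges: np.ndarray | None = None,
    high_edges: np.ndarray | None = None,
) -> LookupTable:
    """Accumulate masked (low, high, VNC) samples into the lookup grid.

    Cell values are running means of their accumulated samples; out-of-range
    (low, high) pairs are clamped to the edge bins and counted in the log.
    Cells with no samples are flagged unobserved (value NaN until imputation).
    """
    if not pairs or len(pairs) != len(vncs) or len(pairs) != len(masks):
        raise ValueError("pairs, vncs and masks must be non-empty aligned lists")
    low_edges = hu_bin_edges() if low_edges is None else np.asarray(low_edges, dtype=float)
    high_edges = hu_bin_edges() if high_edges is None else np.asarray(high_edges, dtype=float)
    n_low, n_high = len(low_edges) - 1, len(high_edges) - 1

    sums = np.zeros(n_low * n_high)
    counts = np.zeros(n_low * n_high, dtype=np.int64)
    total_clamped = 0
    total_pixels = 0
    for pair, vnc, mask in zip(pairs, vncs, masks):
        if pair.shape != vnc.shape or pair.shape != mask.shape:
            raise ValueError("pair, vnc and mask shapes must agree")
        m = mask.pixels
        total_pixels += int(m.sum())
        li, out_l = _bin_index(pair.low.pixels[m], low_edges)
        hi, out_h = _bin_index(pair.high.pixels[m], high_edges)
        total_clamped += out_l + out_h
        flat = li * n_high + hi
        sums += np.bincount(flat, weights=vnc.pixels[m], minlength=sums.size)
        counts += np.bincount(flat, minlength=counts.size)
    if total_pixels == 0:
        raise ValueError("no masked pixels to build the lookup from")
    if total_clamped:
        logger.warning("%d coordinate(s) outside the bin range; clamped to edge bins", total_clamped)

    counts = counts.reshape(n_low, n_high)
    sums = sums.reshape(n_low, n_high)
    observed = counts > 0
    values = np.full((n_low, n_high), np.nan)
    values[observed] = sums[observed] / counts[observed]
    return LookupTable(
        values=values, observed=observed, counts=counts,
        low_edges=low_edges, high_edges=high_edges,
    )


def inpaint_lookup(
    table: LookupTable,
    n_iter: int = 100,
    s_start: float = 1e3,
    s_end: float = 1e-3,
) -> LookupTable:
    """Impute unobserved cells by iterative DCT-penalized least squares.

    Each iteration re-imposes the observed cells and applies a DCT low-pass
    smoother ``1 / (1 + s * Lambda^2)`` (Lambda: Laplacian eigenvalues under
    reflective boundaries) with ``s`` decaying geometrically from ``s_start``
    to ``s_end`` over ``n_iter`` iterations, so early passes extrapolate
    smoothly into empty regions and late passes restore detail near data.
    Observed cells are returned unchanged; a fully empty table comes back all
    zeros (the zero-fill rule for relations no data ever constrains).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    observed = table.observed
    n_low, n_high = table.shape
    if not observed.any():
        return LookupTable(
            values=np.zeros(table.shape), observed=observed.copy(),
            counts=table.counts.copy(), low_edges=table.low_edges,
            high_edges=table.high_edges, fill_value_policy=table.fill_value_policy,
        )
    # The lookup surface is dominated by a linear trend (the decomposition map
    # is affine in (low, high)); the DCT smoother's reflective boundaries bias
    # linear trends near the grid edges, so fit and remove a least-squares
    # plane first and smooth only the residual.
    ii, jj = np.nonzero(observed)
    design = np.column_stack([np.ones(ii.size), ii, jj])
    coef, *_ = np.linalg.lstsq(design, table.values[observed], rcond=None)
    gi, gj = np.mgrid[0:n_low, 0:n_high]
    trend = coef[0] + coef[1] * gi + coef[2] * gj
    y = np.where(observed, table.values - trend, 0.0)
    z = np.where(observed, y, y[observed].mean())

    li = 2.0 - 2.0 * np.cos(np.pi * np.arange(n_low) / n_low)
    hj = 2.0 - 2.0 * np.cos(np.pi * np.arange(n_high) / n_high)
    lam2 = (li[:, None] + hj[None, :]) ** 2
    for s in np.geomspace(s_start, s_end, n_iter):
        z[observed] = y[observed]
        z = idctn(dctn(z, norm="ortho") / (1.0 + s * lam2), norm="ortho")
    z = z + trend
    z[observed] = table.values[observed]
    z[~np.isfinite(z)] = 0.0
    return LookupTable(
        values=z, observed=observed.copy(), counts=table.counts.copy(),
        low_edges=table.low_edges, high_edges=table.high_edges,
        fill_value_policy=table.fill_value_policy,
    )


def apply_lookup(table: LookupTable, pair: DECTPair, interpolation: str = "nearest") -> HUImage:
    """Map every (low, high) pixel pair through the lookup table.

    ``nearest`` (default) reads the containing cell; ``bilinear`` interpolates
    between cell centers. Out-of-range coordinates are clamped to edge bins.
    """
    if not table.fully_imputed:
        raise ValueError("lookup table has non-finite cells; run inpaint_lookup first")
    low, high = pair.low.pixels, pair.high.pixels
    if interpolation == "nearest":
        li, _ = _bin_index(low, table.low_edges)
        hi, _ = _bin_index(high, table.high_edges)
        out = table.values[li, hi]
    elif interpolation == "bilinear":
        from scipy.ndimage import map_coordinates

        lc = 0.5 * (table.low_edges[:-1] + table.low_edges[1:])
        hc = 0.5 * (table.high_edges[:-1] + table.high_edges[1:])
        fi = np.interp(low, lc, np.arange(lc.size))
        fj = np.interp(high, hc, np.arange(hc.size))
        out = map_coordinates(table.values, [fi.ravel(), fj.ravel()], order=1, mode="nearest")
        out = out.reshape(low.shape)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return pair.low.with_pixels(out)


def median_filter_image(image: HUImage, kernel: int = 5) -> HUImage:
    """Median filter with a square kernel and reflect border padding."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be a positive odd integer, got {kernel}")
    return image.with_pixels(median_filter(image.pixels, size=kernel, mode="reflect"))


def lookup_vnc(table: LookupTable, pair: DECTPair, median_kernel: int = 5) -> HUImage:
    """The full L-VNC: lookup application followed by median filtering."""
    return median_filter_image(apply_lookup(table, pair), kernel=median_kernel)


def save_lookup(table: LookupTable, path) -> None:
    np.savez_compressed(
        path, values=table.values, observed=table.observed, counts=table.counts,
        low_edges=table.low_edges, high_edges=table.high_edges,
        fill_value_policy=np.str_(table.fill_value_policy),
    )


def load_lookup(path) -> LookupTable:
    with np.load(path, allow_pickle=False) as a:
        return LookupTable(
            values=a["values"], observed=a["observed"], counts=a["counts"],
            low_edges=a["low_edges"], high_edges=a["high_edges"],
            fill_value_policy=str(a["fill_value_policy"]),
        )
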