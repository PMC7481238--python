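"""National and local yield differentials of new versus existing cropland.

The national differential of a new-cropland cell is its relative deviation
from the frequency-weighted national average yield of existing (stable)
cropland of the same crop:

    diff_nat = (y_gc - y_nat) / y_nat

The local differential compares the cell to the mean prediction over existing
cropland within its enclosing 10 km x 10 km neighborhood block:

    diff_loc = (y_gc - y_neigh) / y_neigh

Both are unitless fractions; multiplying the whole surface by a constant
leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import check_aligned
from .yields import YieldSurface


def national_reference(
    surface: YieldSurface, stable_crop_mask: np.ndarray, frequency_weights: np.ndarray | None = None
) -> float:
    """Frequency-weighted national average yield over stable cropland.

    Weights default to 1 per qualifying pixel when per-year crop frequency
    rasters are not supplied.
    """
    check_aligned(surface.values, stable_crop_mask)
    if not stable_crop_mask.any():
        raise ValueError("empty stable-cropland mask")
    w = np.ones(stable_crop_mask.shape) if frequency_weights is None else frequency_weights
    check_aligned(surface.values, w)
    sel = stable_crop_mask & np.isfinite(surface.values)
    total_w = float(w[sel].sum())
    if total_w <= 0:
        raise ValueError("zero total weight over the stable-cropland mask")
    return float((surface.values[sel] * w[sel]).sum() / total_w)


def national_differential(
    surface: YieldSurface, y_nat: float, new_crop_mask: np.ndarray
) -> np.ndarray:
    """Per-pixel diff_nat over new cropland; NaN off-mask."""
    if y_nat <= 0:
        raise ValueError("national reference yield must be positive")
    check_aligned(surface.values, new_crop_mask)
    out = np.full(surface.values.shape, np.nan)
    sel = new_crop_mask & np.isfinite(surface.values)
    out[sel] = (surface.values[sel] - y_nat) / y_nat
    return out


@dataclass
class LocalDifferentialResult:
    diff_loc: np.ndarray  # per new-crop pixel, NaN elsewhere/undefined blocks
    block_mean_diff: np.ndarray  # per block grid (NaN where undefined)
    weighted_mean: float  # area-weighted national mean of the local differential
    neighborhood_size_m: float


def local_differential(
    surface: YieldSurface,
    stable_crop_mask: np.ndarray,
    new_crop_mask: np.ndarray,
    neighborhood_size_m: float = 10_000.0,
) -> LocalDifferentialResult:
    """diff_loc per new-crop pixel and its area-weighted national mean.

    Neighborhoods are fixed non-overlapping blocks anchored at the raster
    origin. y_neigh is the mean prediction over existing-crop pixels of the
    block, excluding new cropland; blocks lacking existing crop yield NaN.
    The summary weights each block's mean differential by its count of
    new-cropland pixels.
    """
    check_aligned(surface.values, stable_crop_mask, new_crop_mask)
    block_px = int(round(neighborhood_size_m / surface.pixel_size_m))
    if block_px < 1 or abs(block_px * surface.pixel_size_m - neighborhood_size_m) > 1e-6:
        raise ValueError("neighborhood size must be a positive multiple of the pixel size")
    rows, cols = surface.values.shape
    n_br = -(-rows // block_px)
    n_bc = -(-cols // block_px)
    diff = np.full((rows, cols), np.nan)
    block_means = np.full((n_br, n_bc), np.nan)
    block_weights = np.zeros((n_br, n_bc))
    finite = np.isfinite(surface.values)
    for br in range(n_br):
        for bc in range(n_bc):
            sl = (slice(br * block_px, min((br + 1) * block_px, rows)),
                  slice(bc * block_px, min((bc + 1) * block_px, cols)))
            stable = stable_crop_mask[sl] & finite[sl]
            new = new_crop_mask[sl] & finite[sl]
            if not new.any():
                continue
            block_weights[br, bc] = float(new.sum())
            if not stable.any():
                continue  # block lacks existing crop: differentials undefined
            y_neigh = float(surface.values[sl][stable].mean())
            d = (surface.values[sl] - y_neigh) / y_neigh
            tile = diff[sl]
            tile[new] = d[new]
            diff[sl] = tile
            block_means[br, bc] = float(d[new].mean())
    defined = np.isfinite(block_means) & (block_weights > 0)
    if not defined.any():
        raise ValueError("no neighborhood block contains both new and existing cropland")
    weighted_mean = float(
        (block_means[defined] * block_weights[defined]).sum() / block_weights[defined].sum()
    )
    return LocalDifferentialResult(
        diff_loc=diff,
        block_mean_diff=block_means,
        weighted_mean=weighted_mean,
        neighborhood_size_m=neighborhood_size_m,
    )


def differential_summary(diff: np.ndarray) -> dict[str, float]:
    """Mean, spatial SD, and below-reference share of a differential grid."""
    vals = diff[np.isfinite(diff)]
    if vals.size == 0:
        return {"mean": float("nan"), "sd_spatial": float("nan"), "fraction_below": float("nan")}
    return {
        "mean": float(vals.mean()),
        "sd_spatial": float(vals.std(ddof=0)),
        "fraction_below": float((vals < 0).mean()),
    }
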