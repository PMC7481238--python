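"""Habitat-impact accounting for converted land.

Three strands: milkweed stem losses from conversion of grasslands, wetlands
and shrublands (with separate stem densities for land previously enrolled in
the Conservation Reserve Program); duck breeding-pair nesting accessibility
from categorical pair-density maps (range midpoints, open-top category set to
a fixed constant); and long-term habitat — land never labeled cropland or
pasture/hay in any sparse-epoch product across a multi-decade record. A
fourth helper compares biophysical characteristics (slope, land capability,
hydric status, climate water deficit) of new versus existing cropland.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .legend import Legend
from .mmu import ACRE_M2
from .raster import check_aligned
from .transitions import TransitionClass, TransitionMap

SQMI_ACRES = 640.0
SQMI_M2 = SQMI_ACRES * ACRE_M2


class MissingStratumError(KeyError):
    """A converted cover/CRP stratum has no density table row."""


@dataclass
class MilkweedReport:
    stems_lost: float
    stems_lost_se: float
    converted_mean_density: float  # stems/acre on land prior to conversion
    existing_mean_density: float  # stems/acre on remaining natural land
    density_ratio: float  # converted / existing; NaN when undefined
    converted_acres: float
    per_stratum: pd.DataFrame  # cover, crp, acres, density, se, stems


def milkweed_loss(
    tmap: TransitionMap,
    crp_mask: np.ndarray,
    density_table: pd.DataFrame,
    legend: Legend,
    zone_raster: np.ndarray | None = None,
) -> MilkweedReport:
    """Milkweed stems lost to cropland conversion, with propagated SE.

    ``density_table`` rows: (cover, crp, stems_per_acre, se_per_acre), crp
    boolean. Stems lost sum density x acres over converted (to-crop) pixels by
    (cover, CRP, zone) stratum; the SE treats strata as independent and adds
    their (acres x se) contributions in quadrature. Also reports the mean
    pre-conversion density on converted land versus the mean density of
    remaining natural (stable noncrop) land, and their ratio.
    """
    check_aligned(tmap.transition, crp_mask)
    lookup = {
        (str(r.cover), bool(r.crp)): (float(r.stems_per_acre), float(r.se_per_acre))
        for r in density_table.itertuples(index=False)
    }
    pixel_acres = tmap.pixel_size_m**2 / ACRE_M2
    conv = tmap.transition == TransitionClass.TO_CROP
    zones = zone_raster if zone_raster is not None else np.zeros(tmap.shape, dtype=np.int32)
    check_aligned(tmap.transition, zones)

    strata = []
    for cover_code in np.unique(tmap.pre_cover[conv]):
        name = legend.names.get(int(cover_code), f"code_{int(cover_code)}")
        for crp_flag in (False, True):
            sel = conv & (tmap.pre_cover == cover_code) & (crp_mask.astype(bool) == crp_flag)
            if not sel.any():
                continue
            if (name, crp_flag) not in lookup:
                raise MissingStratumError(
                    f"no density row for cover {name!r} with crp={crp_flag}"
                )
            density, se = lookup[(name, crp_flag)]
            for z in np.unique(zones[sel]):
                acres = float((sel & (zones == z)).sum()) * pixel_acres
                strata.append(
                    {"cover": name, "crp": crp_flag, "zone": int(z), "acres": acres,
                     "stems_per_acre": density, "se_per_acre": se,
                     "stems": acres * density, "var": (acres * se) ** 2}
                )
    per_stratum = pd.DataFrame(strata)
    stems_lost = float(per_stratum["stems"].sum()) if len(per_stratum) else 0.0
    se_total = float(math.sqrt(per_stratum["var"].sum())) if len(per_stratum) else 0.0
    converted_acres = float(per_stratum["acres"].sum()) if len(per_stratum) else 0.0
    converted_mean = stems_lost / converted_acres if converted_acres > 0 else float("nan")

    existing_mean, ex_acres = _existing_density(tmap, crp_mask, lookup, legend, pixel_acres)
    ratio = (
        converted_mean / existing_mean
        if converted_acres > 0 and ex_acres > 0 and existing_mean > 0
        else float("nan")
    )
    if len(per_stratum):
        per_stratum = per_stratum.drop(columns="var")
    return MilkweedReport(
        stems_lost=stems_lost,
        stems_lost_se=se_total,
        converted_mean_density=converted_mean,
        existing_mean_density=existing_mean,
        density_ratio=ratio,
        converted_acres=converted_acres,
        per_stratum=per_stratum,
    )


def _existing_density(tmap, crp_mask, lookup, legend, pixel_acres):
    """Mean stems/acre over stable natural land, using its standing cover."""
    existing = tmap.transition == TransitionClass.STABLE_NONCROP
    if not existing.any():
        return float("nan"), 0.0
    cover = getattr(tmap, "current_cover", None)
    if cover is None:
        # stable pixels carry the sentinel in pre_cover; a standing-cover
        # raster must be attached by the caller for a real mean
        return float("nan"), 0.0
    stems = 0.0
    acres = 0.0
    for code in np.unique(cover[existing]):
        name = legend.names.get(int(code), f"code_{int(code)}")
        for crp_flag in (False, True):
            sel = existing & (cover == code) & (crp_mask.astype(bool) == crp_flag)
            n = float(sel.sum())
            if n == 0:
                continue
            if (name, crp_flag) not in lookup:
                raise MissingStratumError(
                    f"no density row for cover {name!r} with crp={crp_flag}"
                )
            stems += lookup[(name, crp_flag)][0] * n * pixel_acres
            acres += n * pixel_acres
    return (stems / acres if acres > 0 else float("nan")), acres


def attach_current_cover(tmap: TransitionMap, cover_raster: np.ndarray) -> TransitionMap:
    """Attach a standing-cover raster (e.g. final clean year) for density means."""
    check_aligned(tmap.transition, cover_raster)
    tmap.current_cover = cover_raster  # type: ignore[attr-defined]
    return tmap


# ---------------------------------------------------------------------------
# duck breeding-pair accessibility


@dataclass(frozen=True)
class PairCategory:
    low: float
    high: float | None  # None marks the open-top category

    def midpoint(self, open_top_value: float) -> float:
        if self.high is None:
            return open_top_value
        return 0.5 * (self.low + self.high)


def category_midpoints(
    categories: dict[int, PairCategory], open_top_value: float = 110.0
) -> dict[int, float]:
    """Midpoint density per category; the open-top class gets a constant.

    The closed range 60-80 pairs/sq. mi. maps to 70; the open-top class
    (>100 pairs/sq. mi.) is assigned 110 by default.
    """
    open_tops = [k for k, c in categories.items() if c.high is None]
    if len(open_tops) > 1:
        raise ValueError("exactly one open-top category allowed")
    return {k: c.midpoint(open_top_value) for k, c in categories.items()}


@dataclass
class DuckReport:
    mean_converted: float  # pairs/sq-mi accessible on converted land
    mean_stable_crop: float
    mean_unconverted: float  # remaining (stable noncrop) habitat
    total_opportunities: dict[str, float]  # stratum -> density x area (pairs)
    per_pixel_mean: dict[str, float]
    excluded_pixels: int  # pixels outside any category


def duck_accessibility(
    tmap: TransitionMap,
    category_raster: np.ndarray,
    categories: dict[int, PairCategory],
    open_top_value: float = 110.0,
) -> DuckReport:
    """Breeding-pair accessibility by land-transition stratum.

    Each category pixel takes its range midpoint (open-top: the configured
    constant). Means are reported for converted (to-crop), stable-crop, and
    unconverted-habitat (stable noncrop) strata; totals multiply density by
    stratum area in square miles. Pixels in no category are excluded and
    counted.
    """
    check_aligned(tmap.transition, category_raster)
    mids = category_midpoints(categories, open_top_value)
    density = np.full(category_raster.shape, np.nan)
    for cat, v in mids.items():
        density[category_raster == cat] = v
    excluded = int((~np.isfinite(density)).sum())

    sqmi_per_px = tmap.pixel_size_m**2 / SQMI_M2
    strata = {
        "converted": tmap.transition == TransitionClass.TO_CROP,
        "stable_crop": tmap.transition == TransitionClass.STABLE_CROP,
        "unconverted_habitat": tmap.transition == TransitionClass.STABLE_NONCROP,
    }
    means, totals, per_px = {}, {}, {}
    for name, sel in strata.items():
        sel = sel & np.isfinite(density)
        if sel.any():
            means[name] = float(density[sel].mean())
            totals[name] = float(density[sel].sum() * sqmi_per_px)
            per_px[name] = float(density[sel].mean() * sqmi_per_px)
        else:
            means[name] = float("nan")
            totals[name] = 0.0
            per_px[name] = float("nan")
    return DuckReport(
        mean_converted=means["converted"],
        mean_stable_crop=means["stable_crop"],
        mean_unconverted=means["unconverted_habitat"],
        total_opportunities=totals,
        per_pixel_mean=per_px,
        excluded_pixels=excluded,
    )


# ---------------------------------------------------------------------------
# long-term habitat


def longterm_mask(
    epoch_rasters: np.ndarray, cultivated_codes: tuple[int, ...] = (81, 82)
) -> np.ndarray:
    """True where no epoch ever labels the pixel cropland or pasture/hay.

    ``epoch_rasters`` is (n_epochs, rows, cols) of epoch legend codes; the
    default cultivated codes are the NLCD cultivated-crop (82) and
    pasture/hay (81) classes. Adding epochs can only shrink the mask.
    """
    if epoch_rasters.ndim != 3 or epoch_rasters.shape[0] < 2:
        raise ValueError("need at least 2 epoch rasters")
    ever = np.zeros(epoch_rasters.shape[1:], dtype=bool)
    for layer in epoch_rasters:
        ever |= np.isin(layer, cultivated_codes)
    return ~ever


def longterm_conversion_tally(
    tmap: TransitionMap, mask: np.ndarray, legend: Legend
) -> pd.DataFrame:
    """Converted long-term-habitat acres grouped by pre-conversion cover."""
    check_aligned(tmap.transition, mask)
    pixel_acres = tmap.pixel_size_m**2 / ACRE_M2
    sel = (tmap.transition == TransitionClass.TO_CROP) & mask
    rows = []
    for code in np.unique(tmap.pre_cover[sel]):
        n = int((sel & (tmap.pre_cover == code)).sum())
        rows.append(
            {"pre_cover": legend.names.get(int(code), f"code_{int(code)}"),
             "pixels": n, "acres": n * pixel_acres}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# biophysical characteristics of new vs existing cropland


def zonal_characteristics(
    tmap: TransitionMap,
    grids: dict[str, np.ndarray],
    hydric_name: str = "hydric",
) -> pd.DataFrame:
    """Means and spatial SDs of characteristics on new vs stable cropland.

    The grid named ``hydric_name`` (if present) is treated as a boolean flag
    and reported as the percentage of pixels flagged.
    """
    check_aligned(tmap.transition, *grids.values())
    strata = {
        "new_cropland": tmap.transition == TransitionClass.TO_CROP,
        "stable_cropland": tmap.transition == TransitionClass.STABLE_CROP,
    }
    rows = []
    for name, grid in grids.items():
        for stratum, sel in strata.items():
            vals = grid[sel]
            vals = vals[np.isfinite(vals.astype(float))]
            if name == hydric_name:
                rows.append({"characteristic": name, "stratum": stratum,
                             "mean": float("nan"), "sd_spatial": float("nan"),
                             "percent_flagged": float(100.0 * np.mean(vals > 0)) if vals.size else float("nan")})
            else:
                rows.append({"characteristic": name, "stratum": stratum,
                             "mean": float(vals.mean()) if vals.size else float("nan"),
                             "sd_spatial": float(vals.std(ddof=0)) if vals.size else float("nan"),
                             "percent_flagged": float("nan")})
    return pd.DataFrame(rows)
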