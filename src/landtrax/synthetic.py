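"""Synthetic land-cover scenes with known ground truth.

The generator emulates the statistical structure the conversion-detection
analysis assumes: a decade of annual crop/noncrop dynamics on a field mosaic,
with planted single-transition conversions and abandonments, rotational
(intermittent) fields, independent per-pixel salt-and-pepper mislabeling,
persistent sub-MMU speckle patches, sparse-epoch products sampled from the
annual truth, smooth covariate fields driving a known yield function, and
piecewise-constant habitat density surfaces.

All randomness flows from one seeded generator; per-operation substreams are
derived deterministically so regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .legend import CROP, NONCROP, Legend, default_legend
from .trajectory import LandcoverSeries
from .transitions import TransitionClass, YEAR_SENTINEL, COVER_SENTINEL


class SceneSizingError(ValueError):
    """The grid cannot host the requested number/size of fields."""


class PlacementError(ValueError):
    """A planted conversion year cannot satisfy the persistence window."""


@dataclass
class SceneConfig:
    grid_rows: int = 200
    grid_cols: int = 200
    pixel_size_m: float = 30.0
    years: tuple[int, ...] = tuple(range(2008, 2018))
    epoch_years: tuple[int, ...] = ()  # default: first two series years
    n_fields: int = 36
    field_size_range_px: tuple[int, int] = (100, 2500)
    conversion_fraction: float = 0.25
    abandonment_fraction: float = 0.10
    intermittent_fraction: float = 0.10
    noise_rate: float = 0.0
    speckle_patch_count: int = 0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.conversion_fraction, self.abandonment_fraction, self.intermittent_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("role fractions must lie in [0,1] and sum to at most 1")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if len(self.years) < 4:
            raise ValueError("need at least 4 annual years")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0,1)")
        if self.field_size_range_px[0] < 1 or self.field_size_range_px[1] < self.field_size_range_px[0]:
            raise ValueError("field sizes must be positive and ordered")
        if not self.epoch_years:
            self.epoch_years = tuple(self.years[:2])
        if not set(self.epoch_years) <= set(self.years):
            raise ValueError("epoch_years must be a subset of years")


@dataclass
class Field:
    r0: int
    r1: int
    c0: int
    c1: int
    role: str  # stable_crop | stable_noncrop | to_crop | to_noncrop | intermittent
    pre_code: int = 0
    post_code: int = 0
    switch_idx: int = -1
    pattern: tuple[int, ...] = ()  # binary per year, intermittent fields only

    @property
    def n_px(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)


@dataclass
class TruthScene:
    """Ground truth emitted alongside a synthetic series."""

    truth_transition: np.ndarray
    truth_year: np.ndarray
    truth_pre_cover: np.ndarray
    truth_post_cover: np.ndarray
    noise_mask: np.ndarray  # (n_years, rows, cols) bool: emitted != clean
    clean_rasters: np.ndarray  # pre-noise annual legend rasters
    fields: list[Field]
    density_truth: dict[str, np.ndarray] = dc_field(default_factory=dict)
    yield_fn_params: dict | None = None


def _lattice_fields(rows: int, cols: int, n_fields: int, min_area: int, rng) -> list[Field]:
    """Tile the grid into at least n_fields axis-aligned rectangles.

    Fields are the intersections of random row bands and column bands (a
    lattice). Every interior junction of a lattice is T- or cross-shaped, so
    no single neighboring field can occupy four of a corner pixel's eight
    neighbors: a clean lattice scene is a fixed point of the majority filter,
    which the exact-recovery guarantee relies on. Sides stay at or above
    max(3, sqrt(min_area)); the field count rounds up to fill the lattice.
    """
    min_side = max(3, math.isqrt(max(min_area, 1)))
    n_rows_max, n_cols_max = rows // min_side, cols // min_side
    if n_rows_max * n_cols_max < n_fields:
        raise SceneSizingError(
            f"grid {rows}x{cols} too small for {n_fields} fields with min side {min_side}"
        )
    nr = max(1, round(math.sqrt(n_fields * rows / cols)))
    nr = min(nr, n_rows_max)
    nc = -(-n_fields // nr)
    if nc > n_cols_max:
        nc = n_cols_max
        nr = -(-n_fields // nc)
    heights = np.full(nr, min_side) + rng.multinomial(rows - nr * min_side, [1 / nr] * nr)
    widths = np.full(nc, min_side) + rng.multinomial(cols - nc * min_side, [1 / nc] * nc)
    r_edges = np.concatenate([[0], np.cumsum(heights)])
    c_edges = np.concatenate([[0], np.cumsum(widths)])
    fields = [
        Field(int(r_edges[i]), int(r_edges[i + 1]), int(c_edges[j]), int(c_edges[j + 1]), role="")
        for i in range(nr)
        for j in range(nc)
    ]
    return fields, nr, nc


_CONV_PRE = ("grassland_pasture", "grassland_pasture", "shrubland", "wetlands", "forest")
_CONV_POST = ("corn", "soybeans", "wheat")
_ABAND_PRE = ("corn", "soybeans", "wheat")
_ABAND_POST = ("grassland_pasture", "shrubland")
_STABLE_CROP = ("corn", "soybeans", "wheat", "alfalfa")
_STABLE_NONCROP = ("grassland_pasture", "shrubland", "wetlands", "forest", "other_hay")


def generate_scene(
    config: SceneConfig, legend: Legend | None = None
) -> tuple[LandcoverSeries, LandcoverSeries, TruthScene]:
    """Generate (annual series, sparse-epoch series, truth) for one scene.

    Planted conversions obey the detection rule's persistence window: the old
    group holds for at least the two annual years (and all sampled epochs)
    before the switch, and the new group for at least the two years after.
    Intermittent fields switch binary group more than once and are cropped in
    at least two years. Truth rasters describe the clean series, before noise
    and speckle injection.
    """
    legend = legend or default_legend()
    rng = np.random.default_rng(config.seed)
    sub = {name: np.random.default_rng(s) for name, s in
           zip(("fields", "roles", "covers", "noise", "speckle"),
               rng.integers(0, 2**31 - 1, size=5))}

    years = list(config.years)
    n = len(years)
    rows, cols = config.grid_rows, config.grid_cols
    # admissible switch indices: two annual years each side, epochs strictly before
    max_epoch = max(config.epoch_years)
    epoch_idx_max = years.index(max_epoch)
    k_lo = max(2, epoch_idx_max + 1)
    k_hi = n - 2
    if k_lo > k_hi:
        raise PlacementError(
            f"no admissible conversion year: persistence window needs index in [{k_lo},{k_hi}]"
        )

    fields, nr, nc = _lattice_fields(
        rows, cols, config.n_fields, config.field_size_range_px[0], sub["fields"]
    )

    n_conv = round(config.conversion_fraction * len(fields))
    n_aband = round(config.abandonment_fraction * len(fields))
    n_inter = round(config.intermittent_fraction * len(fields))
    order = sub["roles"].permutation(len(fields))
    roles = ["to_crop"] * n_conv + ["to_noncrop"] * n_aband + ["intermittent"] * n_inter
    roles += ["stable"] * (len(fields) - len(roles))
    for idx, role in zip(order, roles):
        fields[idx].role = role

    # Binary sequences are placed so that no two diagonally adjacent lattice
    # cells share one: at every interior junction the corner pixel of a field
    # then never sees four same-code neighbors, so the clean scene is a fixed
    # point of the 8-neighbor majority filter and truth is exactly recoverable.
    # Stable crop/noncrop and intermittent phase stripe by column parity;
    # conversion switch years are deconflicted against diagonal neighbors.
    crng = sub["covers"]
    for i in range(nr):
        for j in range(nc):
            f = fields[i * nc + j]
            if f.role == "stable":
                f.role = "stable_crop" if j % 2 == 0 else "stable_noncrop"
            if f.role == "to_crop":
                f.pre_code = legend.code(crng.choice(_CONV_PRE))
                f.post_code = legend.code(crng.choice(_CONV_POST))
                f.switch_idx = int(crng.integers(k_lo, k_hi + 1))
            elif f.role == "to_noncrop":
                f.pre_code = legend.code(crng.choice(_ABAND_PRE))
                f.post_code = legend.code(crng.choice(_ABAND_POST))
                f.switch_idx = int(crng.integers(k_lo, k_hi + 1))
            elif f.role == "intermittent":
                f.pre_code = legend.code(crng.choice(_STABLE_CROP[:3]))
                f.post_code = legend.code("grassland_pasture")
                f.pattern = tuple((j + t) % 2 for t in range(n))
            elif f.role == "stable_crop":
                f.pre_code = f.post_code = legend.code(crng.choice(_STABLE_CROP))
            else:
                f.pre_code = f.post_code = legend.code(crng.choice(_STABLE_NONCROP))
            if f.role in ("to_crop", "to_noncrop"):
                taken = set()
                for di, dj in ((-1, -1), (-1, 1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc:
                        g = fields[ii * nc + jj]
                        if g.role == f.role:
                            taken.add(g.switch_idx)
                if f.switch_idx in taken:
                    options = [k for k in range(k_lo, k_hi + 1) if k not in taken]
                    if not options:
                        raise PlacementError(
                            "cannot deconflict conversion years among adjacent fields"
                        )
                    f.switch_idx = int(options[0])

    clean = np.zeros((n, rows, cols), dtype=np.int32)
    truth_transition = np.zeros((rows, cols), dtype=np.uint8)
    truth_year = np.full((rows, cols), YEAR_SENTINEL, dtype=np.int32)
    truth_pre = np.full((rows, cols), COVER_SENTINEL, dtype=np.int32)
    truth_post = np.full((rows, cols), COVER_SENTINEL, dtype=np.int32)

    for f in fields:
        sl = f.slices()
        if f.role == "stable_crop":
            truth_transition[sl] = TransitionClass.STABLE_CROP
            for t in range(n):
                clean[t][sl] = f.pre_code
        elif f.role == "stable_noncrop":
            truth_transition[sl] = TransitionClass.STABLE_NONCROP
            for t in range(n):
                clean[t][sl] = f.pre_code
        elif f.role in ("to_crop", "to_noncrop"):
            cls = TransitionClass.TO_CROP if f.role == "to_crop" else TransitionClass.TO_NONCROP
            truth_transition[sl] = cls
            truth_year[sl] = years[f.switch_idx]
            truth_pre[sl] = f.pre_code
            truth_post[sl] = f.post_code
            for t in range(n):
                clean[t][sl] = f.pre_code if t < f.switch_idx else f.post_code
        else:  # intermittent
            truth_transition[sl] = TransitionClass.INTERMITTENT
            crop_code, noncrop_code = f.pre_code, f.post_code
            for t in range(n):
                clean[t][sl] = crop_code if f.pattern[t] == CROP else noncrop_code

    emitted = clean.copy()
    noise_mask = np.zeros((n, rows, cols), dtype=bool)
    if config.noise_rate > 0:
        nrng = sub["noise"]
        crop_codes = np.array(legend.codes_in_group(CROP))
        noncrop_codes = np.array(legend.codes_in_group(NONCROP))
        flips = nrng.random((n, rows, cols)) < config.noise_rate
        for t in range(n):
            fl = flips[t]
            grp_is_crop = np.isin(clean[t], crop_codes)
            for opposite, src in ((noncrop_codes, fl & grp_is_crop), (crop_codes, fl & ~grp_is_crop)):
                idx = np.nonzero(src)
                if len(idx[0]):
                    emitted[t][idx] = opposite[nrng.integers(0, len(opposite), size=len(idx[0]))]
        noise_mask = emitted != clean

    if config.speckle_patch_count > 0:
        srng = sub["speckle"]
        crop_codes = legend.codes_in_group(CROP)
        noncrop_codes = legend.codes_in_group(NONCROP)
        for _ in range(config.speckle_patch_count):
            h = int(srng.integers(2, 5))
            w = int(srng.integers(2, 5))
            r = int(srng.integers(0, rows - h))
            c = int(srng.integers(0, cols - w))
            final = clean[-1, r, c]
            if legend.group(int(final)) == CROP:
                code = int(srng.choice(noncrop_codes))
            else:
                code = int(srng.choice(crop_codes))
            emitted[:, r : r + h, c : c + w] = code
        noise_mask = emitted != clean

    series = LandcoverSeries(years=years, rasters=emitted, legend=legend,
                             pixel_size_m=config.pixel_size_m)
    epoch_idx = [years.index(y) for y in config.epoch_years]
    epoch_series = LandcoverSeries(
        years=list(config.epoch_years),
        rasters=clean[epoch_idx].copy(),
        legend=legend,
        pixel_size_m=config.pixel_size_m,
    )
    truth = TruthScene(
        truth_transition=truth_transition,
        truth_year=truth_year,
        truth_pre_cover=truth_pre,
        truth_post_cover=truth_post,
        noise_mask=noise_mask,
        clean_rasters=clean,
        fields=fields,
    )
    return series, epoch_series, truth


# ---------------------------------------------------------------------------
# covariates and yields


@dataclass
class YieldFunction:
    """Known covariate -> yield mapping for synthetic training tables.

    ``kind='linear'``: yield = intercept + sum(coef_i * cov_i).
    ``kind='smooth'``: a smooth nonlinear surface (sines and products) with
    the same coefficient vector controlling each term's weight.
    ``crop_offsets`` shifts the intercept per crop. Additive Gaussian noise
    with ``noise_sd``.
    """

    covariates: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float = 100.0
    crop_offsets: dict[str, float] = dc_field(default_factory=dict)
    noise_sd: float = 0.0
    kind: str = "linear"

    def evaluate(self, values: np.ndarray, crop: str | None = None) -> np.ndarray:
        """Noiseless yield for covariate array of shape (..., n_covariates)."""
        values = np.asarray(values, dtype=float)
        coefs = np.asarray(self.coefficients)
        if self.kind == "linear":
            y = self.intercept + values @ coefs
        elif self.kind == "smooth":
            terms = np.sin(2.0 * np.pi * values) * coefs
            y = self.intercept + terms.sum(axis=-1) + 0.5 * values[..., 0] * values[..., -1] * abs(coefs[0])
        else:
            raise ValueError(f"unknown yield function kind {self.kind!r}")
        if crop is not None:
            y = y + self.crop_offsets.get(crop, 0.0)
        return y

    def params(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "crop_offsets": dict(self.crop_offsets),
            "noise_sd": self.noise_sd,
            "kind": self.kind,
        }


def generate_covariate_grids(
    shape: tuple[int, int], names: list[str], seed: int, n_bumps: int = 6
) -> dict[str, np.ndarray]:
    """Smooth covariate fields in [0, 1]: gradient plus Gaussian bumps."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    rr, cc = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij")
    grids = {}
    for name in names:
        g = rng.uniform(-1, 1) * rr + rng.uniform(-1, 1) * cc
        for _ in range(n_bumps):
            cy, cx = rng.uniform(0, 1, 2)
            width = rng.uniform(0.08, 0.3)
            g = g + rng.uniform(-1, 1) * np.exp(-(((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * width**2)))
        lo, hi = g.min(), g.max()
        grids[name] = (g - lo) / (hi - lo) if hi > lo else np.zeros(shape)
    return grids


def make_zone_raster(shape: tuple[int, int], n_zone_rows: int, n_zone_cols: int) -> np.ndarray:
    """Block-tiled zone ids (1-based), standing in for counties."""
    rows, cols = shape
    zr = np.minimum(np.arange(rows) * n_zone_rows // rows, n_zone_rows - 1)
    zc = np.minimum(np.arange(cols) * n_zone_cols // cols, n_zone_cols - 1)
    return (zr[:, None] * n_zone_cols + zc[None, :] + 1).astype(np.int32)


def generate_covariates_and_yields(
    config: SceneConfig,
    zone_raster: np.ndarray,
    yield_fn: YieldFunction,
    crops: tuple[str, ...] = ("corn",),
    crop_masks: dict[tuple[str, int], np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Emit smooth covariate grids and a zone x crop x year yield table.

    Each row's covariate columns hold the zonal means of the emitted grids
    (within the crop-year mask when ``crop_masks`` provides one), and its
    yield is the known function of those means plus seeded Gaussian noise.
    Empty zone-years are omitted.
    """
    if zone_raster.shape != (config.grid_rows, config.grid_cols):
        raise ValueError("zone raster misaligned with scene grid")
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(0, 2**31 - 1) + 7)
    grids = generate_covariate_grids(
        (config.grid_rows, config.grid_cols), list(yield_fn.covariates), seed=config.seed + 101
    )
    rows = []
    zones = [int(z) for z in np.unique(zone_raster)]
    for crop in crops:
        for year in config.years:
            for z in zones:
                mask = zone_raster == z
                if crop_masks is not None:
                    key = (crop, int(year))
                    if key not in crop_masks:
                        continue
                    mask = mask & crop_masks[key]
                if not mask.any():
                    continue
                means = {name: float(grids[name][mask].mean()) for name in yield_fn.covariates}
                vec = np.array([means[name] for name in yield_fn.covariates])
                y = float(yield_fn.evaluate(vec, crop=crop))
                if yield_fn.noise_sd > 0:
                    y += float(rng.normal(0.0, yield_fn.noise_sd))
                rows.append({"zone_id": z, "crop": crop, "year": int(year), "yield": y, **means})
    return grids, pd.DataFrame(rows)


def synthesize_yield_records(
    n: int, yield_fn: YieldFunction, seed: int, crop: str = "corn"
) -> pd.DataFrame:
    """Training records sampled uniformly over covariate space.

    Used for parameter-recovery checks of the yield model independent of any
    raster scene.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, len(yield_fn.covariates)))
    y = yield_fn.evaluate(X, crop=crop)
    if yield_fn.noise_sd > 0:
        y = y + rng.normal(0.0, yield_fn.noise_sd, size=n)
    df = pd.DataFrame(X, columns=list(yield_fn.covariates))
    df.insert(0, "zone_id", np.arange(n) % 97 + 1)
    df.insert(1, "crop", crop)
    df.insert(2, "year", 2008 + np.arange(n) % 10)
    df["yield"] = y
    return df[["zone_id", "crop", "year", "yield", *yield_fn.covariates]]


# ---------------------------------------------------------------------------
# habitat surfaces


class MissingDensityError(KeyError):
    """A cover class present in the scene has no density table entry."""


def generate_habitat_surfaces(
    cover_raster: np.ndarray,
    legend: Legend,
    tables: dict[str, dict[str, float]],
) -> dict[str, np.ndarray]:
    """Piecewise-constant habitat metric rasters, one per named metric.

    ``tables`` maps metric name -> {cover class name: value}. Every cover
    class present in the raster must appear in each metric's table.
    """
    surfaces = {}
    present = [int(c) for c in np.unique(cover_raster)]
    for metric, table in tables.items():
        out = np.zeros(cover_raster.shape, dtype=float)
        for code in present:
            name = legend.names.get(code)
            if name is None or name not in table:
                raise MissingDensityError(
                    f"metric {metric!r}: no density for cover class "
                    f"{name or code!r} present in the scene"
                )
            out[cover_raster == code] = table[name]
        surfaces[metric] = out
    return surfaces
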