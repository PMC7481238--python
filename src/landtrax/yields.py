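"""Representative-yield modeling: zonal training tables, random-forest fit,
and spatial prediction.

The model predicts *representative* (multiyear average expected) yields from
static biophysical covariates, not year-to-year realized yields: training
rows are zone x crop x year means of gridded covariates paired with zonal
yield averages, and predictions are interpreted only relatively, as
differentials between new and existing cropland.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .raster import check_aligned

RESERVED_COLUMNS = ("zone_id", "crop", "year", "yield")


@dataclass
class YieldModelSpec:
    """Random-forest hyperparameters and the holdout protocol.

    Defaults follow the tuned configuration used operationally: 250 trees,
    21 candidate variables per split, minimum node size 5, and a 30% random
    holdout for validation. When fewer than ``vars_per_split`` covariates are
    available, the value is clamped with a warning.
    """

    n_trees: int = 250
    vars_per_split: int = 21
    min_node_size: int = 5
    holdout_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if min(self.n_trees, self.vars_per_split, self.min_node_size) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0,1)")


@dataclass
class ValidationReport:
    rmse: float
    r2: float
    n_train: int
    n_holdout: int
    spec: YieldModelSpec
    covariates: list[str]
    mtry_used: int
    mtry_clamped: bool


@dataclass
class FittedYieldModel:
    crop: str
    forest: RandomForestRegressor
    covariates: list[str]
    report: ValidationReport
    y_train_range: tuple[float, float]

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [c for c in self.covariates if c not in table.columns]
            if missing:
                raise ValueError(f"missing covariate columns: {missing}")
            X = table[self.covariates].to_numpy()
        else:
            X = np.asarray(table)
            if X.shape[1] != len(self.covariates):
                raise ValueError("covariate count mismatch")
        return self.forest.predict(X)


@dataclass
class YieldSurface:
    """Per-pixel representative yield for one crop over a validity mask."""

    crop: str
    values: np.ndarray  # float, NaN off-mask
    valid_mask: np.ndarray
    pixel_size_m: float = 30.0

    def __post_init__(self):
        check_aligned(self.values, self.valid_mask)
        on = self.values[self.valid_mask]
        if on.size and not np.isfinite(on).all():
            raise ValueError("non-finite predictions inside the valid mask")


def tabulate_zonal(
    grids: dict[str, np.ndarray],
    zone_raster: np.ndarray,
    mask: np.ndarray | None = None,
    stats: dict[str, str] | None = None,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Zonal statistics of covariate grids, one row per zone.

    ``stats`` maps covariate name -> one of mean/sum/min/max (default mean).
    NaN cells inside the mask are excluded; zones whose finite coverage under
    the mask falls below ``min_coverage`` (or that are empty) are omitted.
    """
    arrays = list(grids.values()) + [zone_raster] + ([mask] if mask is not None else [])
    check_aligned(*arrays)
    stats = stats or {}
    rows = []
    sel_all = np.ones(zone_raster.shape, bool) if mask is None else mask.astype(bool)
    for z in np.unique(zone_raster):
        sel = sel_all & (zone_raster == z)
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        row = {"zone_id": int(z)}
        keep = True
        for name, grid in grids.items():
            vals = grid[sel]
            finite = vals[np.isfinite(vals)]
            if finite.size < min_coverage * n_sel or finite.size == 0:
                keep = False
                break
            stat = stats.get(name, "mean")
            row[name] = float({"mean": np.mean, "sum": np.sum, "min": np.min, "max": np.max}[stat](finite))
        if keep:
            rows.append(row)
    return pd.DataFrame(rows)


def holdout_split(n: int, holdout_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/holdout index split with |holdout| = round(f*n)."""
    n_hold = int(round(holdout_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_hold:]), np.sort(perm[:n_hold])


def fit_yield_model(
    records: pd.DataFrame, spec: YieldModelSpec, crop: str | None = None
) -> FittedYieldModel:
    """Fit one crop's random-forest yield model with a random holdout.

    Covariates are every column outside (zone_id, crop, year, yield). Refitting
    with the same records and seed reproduces identical predictions.
    """
    if crop is not None and "crop" in records.columns:
        records = records[records["crop"] == crop]
    crop = crop or (str(records["crop"].iloc[0]) if "crop" in records.columns else "crop")
    covariates = [c for c in records.columns if c not in RESERVED_COLUMNS]
    if not covariates:
        raise ValueError("no covariate columns in records")
    all_nan = [c for c in covariates if records[c].isna().all()]
    if all_nan:
        raise ValueError(f"covariate columns with all-missing values: {all_nan}")
    n = len(records)
    train_idx, hold_idx = holdout_split(n, spec.holdout_fraction, spec.seed)
    if len(train_idx) < 50:
        raise ValueError(f"need >= 50 training records after holdout, got {len(train_idx)}")

    mtry = spec.vars_per_split
    clamped = mtry > len(covariates)
    if clamped:
        warnings.warn(
            f"vars_per_split={mtry} exceeds {len(covariates)} covariates; clamping",
            stacklevel=2,
        )
        mtry = len(covariates)

    X = records[covariates].to_numpy()
    y = records["yield"].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=mtry,
        min_samples_leaf=spec.min_node_size,
        random_state=spec.seed,
        n_jobs=1,
    )
    forest.fit(X[train_idx], y[train_idx])
    pred = forest.predict(X[hold_idx])
    resid = y[hold_idx] - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y[hold_idx] - y[hold_idx].mean()) ** 2))
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else float("nan")
    report = ValidationReport(
        rmse=rmse,
        r2=r2,
        n_train=len(train_idx),
        n_holdout=len(hold_idx),
        spec=spec,
        covariates=covariates,
        mtry_used=mtry,
        mtry_clamped=clamped,
    )
    y_tr = y[train_idx]
    return FittedYieldModel(
        crop=crop,
        forest=forest,
        covariates=covariates,
        report=report,
        y_train_range=(float(y_tr.min()), float(y_tr.max())),
    )


def predict_surface(
    model: FittedYieldModel,
    grids: dict[str, np.ndarray],
    valid_mask: np.ndarray,
    pixel_size_m: float = 30.0,
) -> YieldSurface:
    """Map the fitted model over covariate grids within a validity mask."""
    missing = [c for c in model.covariates if c not in grids]
    if missing:
        raise ValueError(f"covariate grids missing: {missing}")
    check_aligned(*grids.values(), valid_mask)
    values = np.full(valid_mask.shape, np.nan)
    idx = np.nonzero(valid_mask)
    if len(idx[0]):
        X = np.column_stack([grids[c][idx] for c in model.covariates])
        values[idx] = model.forest.predict(X)
    return YieldSurface(crop=model.crop, values=values, valid_mask=valid_mask.astype(bool),
                        pixel_size_m=pixel_size_m)


def bilinear_resample(grid: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling utility for coarse covariate grids.

    Cell-center aligned; the module otherwise requires pre-aligned grids.
    """
    from scipy.ndimage import map_coordinates

    rows, cols = grid.shape
    out_r, out_c = out_shape
    rr = (np.arange(out_r) + 0.5) * rows / out_r - 0.5
    cc = (np.arange(out_c) + 0.5) * cols / out_c - 0.5
    coords = np.meshgrid(np.clip(rr, 0, rows - 1), np.clip(cc, 0, cols - 1), indexing="ij")
    return map_coordinates(grid.astype(float), coords, order=1, mode="nearest")
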